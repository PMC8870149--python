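"""Coupled tumor growth–mechanics–fluid–drug pipeline and readout metrics.

Each growth step advances, in order: quasi-steady oxygen → growth rate and
stress-directed anisotropy multipliers → growth stretches → mechanical
equilibrium (updating the deformed configuration) → vessel compression and
functional vascular density → interstitial fluid pressure → cell density.
Between the injection and readout times a drug sub-loop (1-minute steps by
default) advances the free/bound/internalized drug fields on the frozen
within-step geometry.

The virtual patient supplies heterogeneous stiffness (storage/loss moduli on
a voxel grid, inverted to an elastic shear modulus) and a cell-diffusivity
tensor field; the constant-modulus control replaces the stiffness by its
volume average over each region, so the means are matched by construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .config import SECONDS_PER_DAY, SimulationConfig
from .drug import DrugState, starling_flux, step_drug, vascular_concentration, wall_transport
from .fields import (FieldGeneratorSpec, TumorSeedSpec, VoxelField,
                     embed_tumor_data, generate_dti_field,
                     generate_modulus_field, interpolate_to_mesh)
from .growth import GrowthState, anisotropy_multipliers, growth_rate, step_growth_stretches
from .material import reconstruct_shear_modulus
from .mechanics import solve_displacement
from .meshing import Mesh, ball_mesh
from .transport import (lumped_mass, nodal_average, scalar_quadrature,
                        solve_ifp, steady_oxygen, step_cells)
from .vasculature import functional_density, vessel_compression

__all__ = [
    "PatientFields", "CoupledState", "RunResult", "generate_patient",
    "material_on_mesh", "run_simulation", "region_stats", "dice_coefficient",
    "fraction_above", "shape_asymmetry", "field_asymmetry", "sphericity",
    "voxelize_tumor", "cell_mask", "interior_tumor_mask",
]


@dataclasses.dataclass
class PatientFields:
    """Voxel fields of one virtual patient."""

    modulus: VoxelField        # channels storage_modulus_Pa, loss_modulus_Pa
    dti: VoxelField            # channel dti_mm2_per_day
    tumor_modulus: VoxelField  # "patient tumor" stiffness map for the seed
    tumor_bbox: np.ndarray     # (3, 2) world box of the tumor map to embed


@dataclasses.dataclass
class CoupledState:
    """Snapshot of all coupled fields at one time."""

    time: float
    growth: GrowthState          # per-hex growth stretches
    u: np.ndarray                # (n_nodes, 3) displacement
    coords: np.ndarray           # deformed nodal coordinates
    sigma_bulk: np.ndarray       # per-hex tr(σ_s), Pa
    sigma_diag: np.ndarray       # per-hex normal stresses, Pa
    s_v: np.ndarray              # per-hex functional vascular density, 1/mm
    p_i: np.ndarray              # nodal IFP, Pa
    v_f: np.ndarray              # per-hex Darcy velocity, mm/day
    t_cel: np.ndarray            # nodal cell density
    c_ox: np.ndarray             # nodal oxygen
    drug: DrugState | None
    newton_iters: int = 0


@dataclasses.dataclass
class RunResult:
    config: SimulationConfig
    mesh: Mesh
    g_hex: np.ndarray
    final: CoupledState
    series: pd.DataFrame
    summary: dict


def generate_patient(config: SimulationConfig) -> PatientFields:
    """Synthesize the stiffness and DTI voxel fields for one virtual patient.

    The grid covers the host ball with a margin; the heterogeneous field is
    always generated (the constant-modulus control averages it downstream, so
    the two cases share identical means by construction).
    """
    p = config.patient
    r = config.geometry.host_radius + 2.0 * p.voxel_spacing
    n = int(np.ceil(2.0 * r / p.voxel_spacing)) + 1
    grid = VoxelField(origin=np.full(3, -r), spacing=np.full(3, p.voxel_spacing),
                      dims=(n, n, n))
    spec = FieldGeneratorSpec(
        target_mean=p.host_storage_mean, target_sd=p.host_storage_sd,
        correlation_length=p.correlation_length,
        loss_to_storage_ratio=p.loss_ratio, seed=p.seed, clip_floor=p.clip_floor)
    modulus = generate_modulus_field(spec, grid)
    dti = generate_dti_field(p.dti_base, p.dti_anisotropy, p.seed + 1, grid,
                             correlation_length=p.correlation_length)
    # "patient tumor" stiffness map on a dedicated fine grid; its full extent
    # is later squeezed affinely into the seed sphere's circumscribing cube
    half = 1.5 * config.geometry.tumor_radius
    n_t = int(np.ceil(2.0 * half)) + 1  # 1 mm spacing
    t_grid = VoxelField(origin=np.full(3, -half), spacing=np.ones(3),
                        dims=(n_t, n_t, n_t))
    t_spec = FieldGeneratorSpec(
        target_mean=p.tumor_storage, target_sd=p.tumor_storage_sd,
        correlation_length=p.correlation_length,
        loss_to_storage_ratio=p.loss_ratio, seed=p.seed + 2,
        clip_floor=p.clip_floor)
    tumor_modulus = generate_modulus_field(t_spec, t_grid)
    bbox = np.array([[-half, half]] * 3)
    return PatientFields(modulus=modulus, dti=dti,
                         tumor_modulus=tumor_modulus, tumor_bbox=bbox)


def material_on_mesh(config: SimulationConfig, mesh: Mesh, patient: PatientFields):
    """Per-hex shear modulus and per-hex cell diffusivity tensors.

    Host hexes sample the (inverted) elastography stiffness at their
    centroids; tumor hexes sample the "patient tumor" stiffness map embedded
    into the seed sphere.  With ``patient.heterogeneous`` False each region
    is replaced by its volume-weighted average (the constant-modulus
    control), so the region means match by construction.
    """
    p = config.patient
    omega = 2.0 * np.pi * p.mre_frequency_hz
    cent = mesh.nodes[mesh.hexes].mean(axis=1)
    gs = interpolate_to_mesh(patient.modulus, "storage_modulus_Pa", cent)
    gl = interpolate_to_mesh(patient.modulus, "loss_modulus_Pa", cent)
    g_hex, _ = reconstruct_shear_modulus(gs, gl, omega)
    tum = mesh.region == 1
    seed_spec = TumorSeedSpec(radius=config.geometry.tumor_radius)
    gs_t = embed_tumor_data(patient.tumor_modulus, "storage_modulus_Pa",
                            patient.tumor_bbox, seed_spec, cent[tum])
    gl_t = embed_tumor_data(patient.tumor_modulus, "loss_modulus_Pa",
                            patient.tumor_bbox, seed_spec, cent[tum])
    g_tum, _ = reconstruct_shear_modulus(gs_t, gl_t, omega)
    g_hex[tum] = g_tum
    if not p.heterogeneous:
        from .mechanics import hex_quadrature
        vol = hex_quadrature(mesh.nodes, mesh.hexes)["volume"]
        for reg in (0, 1):
            m = mesh.region == reg
            g_hex[m] = np.average(g_hex[m], weights=vol[m])
    dti_hex = interpolate_to_mesh(patient.dti, "dti_mm2_per_day", cent)
    full = np.empty((mesh.n_hexes, 3, 3))
    # lower-triangular channel order (xx, yy, zz, xy, xz, yz) per fields._TRI
    from .fields import _TRI
    for c, (i, j) in enumerate(_TRI):
        full[:, i, j] = dti_hex[:, c]
        full[:, j, i] = dti_hex[:, c]
    return g_hex, full


def _hex_mean_of_nodal(mesh: Mesh, values_node: np.ndarray) -> np.ndarray:
    return values_node[mesh.hexes].mean(axis=1)


def run_simulation(config: SimulationConfig,
                   patient: PatientFields | None = None,
                   start_state: CoupledState | None = None,
                   mesh: Mesh | None = None,
                   progress: callable = None) -> RunResult:
    """Run the coupled pipeline; deterministic given config and seeds.

    ``start_state`` allows continuing a previous run (e.g. growing once to the
    injection day, then branching the drug sweep off the shared grown state).
    """
    config.validate()
    geo = config.geometry
    if mesh is None:
        mesh = ball_mesh(geo.tumor_radius, geo.host_radius, geo.n_tumor_shells,
                         geo.n_host_shells, geo.grading_ratio)
    if patient is None:
        patient = generate_patient(config)
    g_hex, dti_hex = material_on_mesh(config, mesh, patient)
    k_hex = np.full(mesh.n_hexes, config.material.k_bulk)

    d = config.drug
    d0_mm2_s = d.stokes_einstein_d0()
    l_p, per_mm_s, sigma_f = wall_transport(d.gamma, d.pore_radius_nm, d.eta_pa_s,
                                            d.l_vw_um, d0_mm2_s, d.lambda_ratio)
    per_day = per_mm_s * SECONDS_PER_DAY
    d_f_day = d.d_f_factor * d0_mm2_s * SECONDS_PER_DAY
    dt_drug = d.dt_minutes / (24.0 * 60.0)

    tumor_nodes = mesh.tumor_node_mask()
    ox = config.oxygen
    fl = config.fluid
    va = config.vasculature
    gr = config.growth

    if start_state is None:
        state = CoupledState(
            time=0.0, growth=GrowthState.identity(mesh.n_hexes),
            u=np.zeros((mesh.n_nodes, 3)), coords=mesh.nodes.copy(),
            sigma_bulk=np.zeros(mesh.n_hexes), sigma_diag=np.zeros((mesh.n_hexes, 3)),
            s_v=np.full(mesh.n_hexes, va.s_v0), p_i=np.zeros(mesh.n_nodes),
            v_f=np.zeros((mesh.n_hexes, 3)),
            t_cel=np.where(tumor_nodes, 1.0, 0.0),
            c_ox=np.full(mesh.n_nodes, ox.c_iox), drug=None)
    else:
        state = dataclasses.replace(start_state)
    if state.drug is None:
        state = dataclasses.replace(state, drug=DrugState.zero(mesh.n_nodes))

    n_steps = int(round((gr.duration - state.time) / gr.dt)) if gr.duration > state.time else 0
    mech_cache: dict = {}
    rows = [_series_row(config, mesh, g_hex, state)]
    next_checkpoint = state.time + config.checkpoint_days

    for step in range(n_steps):
        t = state.time
        try:
            state = _advance(config, mesh, g_hex, k_hex, dti_hex, state,
                             tumor_nodes, l_p, per_day, sigma_f, d_f_day,
                             dt_drug, mech_cache)
        except Exception as exc:  # annotate with stage context
            raise RuntimeError(f"step {step} (t = {t:g} d) failed: {exc}") from exc
        if state.time >= next_checkpoint - 1e-9 or step == n_steps - 1:
            rows.append(_series_row(config, mesh, g_hex, state))
            next_checkpoint += config.checkpoint_days
        if progress is not None:
            progress(step, n_steps, state)

    series = pd.DataFrame(rows)
    summary = summarize(config, mesh, g_hex, state)
    return RunResult(config=config, mesh=mesh, g_hex=g_hex, final=state,
                     series=series, summary=summary)


def _advance(config, mesh, g_hex, k_hex, dti_hex, state, tumor_nodes,
             l_p, per_day, sigma_f, d_f_day, dt_drug, mech_cache) -> CoupledState:
    gr, va, fl, ox, d = (config.growth, config.vasculature, config.fluid,
                         config.oxygen, config.drug)
    dt = gr.dt
    coords = state.coords

    # 1. quasi-steady oxygen on the current geometry
    sv_node = nodal_average(mesh, coords, state.s_v)
    c_ox = steady_oxygen(mesh, coords, sv_node, state.t_cel, ox.d_ox, ox.per_ox,
                         ox.c_iox, ox.a_ox, ox.k_ox, c0=state.c_ox)

    # 2.–4. growth kinetics from oxygen, cells, and the current stress state
    r_g = growth_rate(_hex_mean_of_nodal(mesh, c_ox),
                      _hex_mean_of_nodal(mesh, state.t_cel), gr.k1, gr.k2)
    gamma = anisotropy_multipliers(state.sigma_diag, gr.anisotropy,
                                   config.material.k_bulk)
    growth = step_growth_stretches(state.growth, r_g, gamma, dt)

    # 5. mechanical equilibrium
    mech = solve_displacement(mesh, g_hex, k_hex, growth.lambda_g,
                              p_i_nodes=state.p_i, u0=state.u,
                              isochoric=config.material.isochoric,
                              cache=mech_cache)
    coords = mesh.nodes + mech.u

    # 6. vessel compression
    s_v = functional_density(vessel_compression(mech.sigma_bulk, va.sigma_half),
                             va.s_v0)

    # 7. interstitial fluid pressure (per-second units; time cancels)
    lymph_hex = np.where(mesh.region == 0, fl.lymph_coeff, 0.0)
    fluid = solve_ifp(mesh, coords, s_v, l_p, fl.p_v, fl.k_th,
                      lymph=lymph_hex, p_vl=fl.p_vl)
    v_f_day = fluid.v_f * SECONDS_PER_DAY

    # 8. cancer cell density
    t_cel = step_cells(mesh, coords, state.t_cel, dti_hex, c_ox, tumor_nodes,
                       gr.k1, gr.k2, gr.rho_cell, dt, cache={})

    # 9. drug sub-loop over the overlap of this step with [injection, readout]
    drug = state.drug
    t0, t1 = state.time, state.time + dt
    lo, hi = max(t0, d.t_injection), min(t1, d.t_readout)
    if drug is not None and lo < hi:
        sv_node = nodal_average(mesh, coords, s_v)
        cache: dict = {}
        n_sub = max(1, int(round((hi - lo) / dt_drug)))
        h = (hi - lo) / n_sub
        for i in range(n_sub):
            tau = lo + i * h
            c_iv = vascular_concentration(tau, d.t_injection, d.k_d)
            q = starling_flux(per_day, sv_node, c_iv, drug.c_f,
                              l_p * SECONDS_PER_DAY, fl.p_v, fluid.p_i, sigma_f)
            drug = step_drug(mesh, coords, drug, v_f_day, q, d_f_day,
                             d.kon_ce_phi, d.k_off, d.k_int, h, cache=cache)

    diag = np.stack([mech.sigma[:, 0, 0], mech.sigma[:, 1, 1], mech.sigma[:, 2, 2]],
                    axis=-1)
    return CoupledState(
        time=t1, growth=growth, u=mech.u, coords=coords,
        sigma_bulk=mech.sigma_bulk, sigma_diag=diag, s_v=s_v, p_i=fluid.p_i,
        v_f=v_f_day, t_cel=t_cel, c_ox=c_ox, drug=drug,
        newton_iters=mech.newton_iters)


# -- readout metrics -------------------------------------------------------

def region_stats(values, mask, weights):
    """Volume-weighted mean and population SD of ``values`` over ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    v = np.asarray(values, dtype=float)[mask]
    w = np.asarray(weights, dtype=float)[mask]
    mean = np.average(v, weights=w)
    sd = float(np.sqrt(np.average((v - mean) ** 2, weights=w)))
    return float(mean), sd


def dice_coefficient(mask_a, mask_b, weights):
    """Volume-weighted Sørensen–Dice overlap 2|A∩B|/(|A|+|B|)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    w = np.asarray(weights, dtype=float)
    va, vb = w[a].sum(), w[b].sum()
    if va + vb == 0:
        raise ValueError("both masks empty")
    return float(2.0 * w[a & b].sum() / (va + vb))


def fraction_above(values, mask, threshold, weights):
    """Volume fraction of the masked region with values strictly above threshold."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    v = np.asarray(values, dtype=float)[mask]
    w = np.asarray(weights, dtype=float)[mask]
    return float(w[v > threshold].sum() / w.sum())


def interior_tumor_mask(mesh: Mesh, layers: int = 1):
    """Tumor-interior element and node masks, peeling ``layers`` element rings
    at the tumor/host interface.

    The solid stress jumps across the material interface; on coarse meshes the
    interface-adjacent elements carry the dominant angular discretization
    error, which propagates into vessel-compression statistics.  Interior
    statistics exclude that layer.  Returns ``(hex_mask, node_mask)``; the
    node mask keeps only nodes not shared with any excluded element.
    """
    mask = mesh.region == 1
    for _ in range(layers):
        outside_nodes = np.unique(mesh.hexes[~mask])
        touches = np.isin(mesh.hexes, outside_nodes).any(axis=1)
        mask = mask & ~touches
    if not mask.any():
        raise ValueError("no interior tumor elements left after peeling")
    inner_nodes = np.unique(mesh.hexes[mask])
    boundary_nodes = np.unique(mesh.hexes[~mask])
    node_mask = np.zeros(mesh.n_nodes, dtype=bool)
    node_mask[np.setdiff1d(inner_nodes, boundary_nodes)] = True
    if not node_mask.any():
        node_mask[inner_nodes] = True
    return mask, node_mask


def cell_mask(t_cel, threshold: float = 0.5) -> np.ndarray:
    """Cell-density isocontour tumor mask; monotone non-increasing in threshold."""
    return np.asarray(t_cel, dtype=float) > threshold


def _tumor_surface_tris(mesh: Mesh) -> np.ndarray:
    """Triangles of the material tumor/host interface (node index triples)."""
    faces = {}
    for tet, reg in zip(mesh.tets, mesh.tet_region):
        for skip in range(4):
            tri = tuple(sorted(np.delete(tet, skip)))
            faces.setdefault(tri, []).append(reg)
    return np.array([tri for tri, regs in faces.items()
                     if len(regs) == 2 and regs[0] != regs[1]], dtype=int)


def sphericity(mesh: Mesh, coords: np.ndarray) -> float:
    """π^(1/3)(6V)^(2/3)/A of the deformed material tumor region (≤ 1)."""
    tris = _tumor_surface_tris(mesh)
    p = coords[tris]
    area = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1).sum()
    vol = scalar_quadrature(mesh, coords)["volume"]
    v = vol[mesh.region == 1].sum()
    return float(np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / area)


def shape_asymmetry(mesh: Mesh, coords: np.ndarray) -> float:
    """Relative spread SD(r)/mean(r) of the deformed tumor-surface radius."""
    tris = _tumor_surface_tris(mesh)
    ids = np.unique(tris)
    r = np.linalg.norm(coords[ids], axis=1)
    return float(r.std() / r.mean())


def field_asymmetry(values, radii, weights, n_bins: int = 8) -> float:
    """Volume-weighted relative deviation of a field from its radial average.

    Bins the samples by radius (equal-count bins), subtracts the per-shell
    mean, and returns the RMS residual over the global mean — zero for any
    radially symmetric field, regardless of its profile.
    """
    v = np.asarray(values, dtype=float)
    r = np.asarray(radii, dtype=float)
    w = np.asarray(weights, dtype=float)
    edges = np.quantile(r, np.linspace(0.0, 1.0, n_bins + 1))
    edges[-1] += 1e-9
    bins = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, n_bins - 1)
    num = np.bincount(bins, weights=w * v, minlength=n_bins)
    den = np.bincount(bins, weights=w, minlength=n_bins)
    shell_mean = num / np.maximum(den, 1e-300)
    resid = v - shell_mean[bins]
    rms = np.sqrt(np.average(resid ** 2, weights=w))
    gmean = abs(np.average(v, weights=w))
    return float(rms / max(gmean, 1e-300))


def voxelize_tumor(mesh: Mesh, coords: np.ndarray, spacing: float = 0.5,
                   half_extent: float = 16.0) -> np.ndarray:
    """Boolean voxelization of the deformed material tumor region.

    Rasterizes the deformed tumor tetrahedra onto a fixed cubic lattice
    (points spaced ``spacing`` mm in [−half_extent, half_extent]³), marking
    lattice points covered by any tumor tet.  Two runs voxelized on the same
    lattice can be compared with ``dice_coefficient``.
    """
    axis = np.arange(-half_extent, half_extent + spacing / 2, spacing)
    n = len(axis)
    out = np.zeros((n, n, n), dtype=bool)
    tum = mesh.tets[mesh.tet_region == 1]
    verts = coords[tum]  # (m, 4, 3)
    for v in verts:
        lo = np.maximum(np.floor((v.min(axis=0) + half_extent) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((v.max(axis=0) + half_extent) / spacing).astype(int) + 1, n)
        if np.any(lo >= hi):
            continue
        gx, gy, gz = np.meshgrid(*(axis[lo[a]:hi[a]] for a in range(3)), indexing="ij")
        pts = np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
        mat = (v[1:] - v[0]).T
        try:
            bary = np.linalg.solve(mat, (pts - v[0]).T).T
        except np.linalg.LinAlgError:
            continue
        inside = (bary >= -1e-12).all(axis=1) & (bary.sum(axis=1) <= 1.0 + 1e-12)
        blk = out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        blk |= inside.reshape(blk.shape)
    return out


def _series_row(config, mesh, g_hex, state: CoupledState) -> dict:
    quad = scalar_quadrature(mesh, state.coords)
    vol = quad["volume"]
    tum = mesh.region == 1
    nv = lumped_mass(mesh, state.coords, quad=quad)
    tn = mesh.tumor_node_mask()
    row = {
        "time_days": state.time,
        "tumor_volume_mm3": float(vol[tum].sum()),
        "tumor_bulk_stress_pa": region_stats(state.sigma_bulk, tum, vol)[0],
        "tumor_sv_per_mm": region_stats(state.s_v, tum, vol)[0],
        "tumor_g_pa": region_stats(g_hex, tum, vol)[0],
        "tumor_p_i_pa": region_stats(state.p_i, tn, nv)[0],
        "tumor_c_ox": region_stats(state.c_ox, tn, nv)[0],
        "tumor_t_cel": region_stats(state.t_cel, tn, nv)[0],
        "newton_iters": state.newton_iters,
    }
    if state.drug is not None:
        row["tumor_c_int"] = region_stats(state.drug.c_int, tn, nv)[0]
        row["tumor_c_f"] = region_stats(state.drug.c_f, tn, nv)[0]
    return row


def summarize(config, mesh, g_hex, state: CoupledState) -> dict:
    """Readout statistics of the final state (volume-weighted, tumor region)."""
    quad = scalar_quadrature(mesh, state.coords)
    vol = quad["volume"]
    tum = mesh.region == 1
    nv = lumped_mass(mesh, state.coords, quad=quad)
    tn = mesh.tumor_node_mask()
    r_node = np.linalg.norm(state.coords, axis=1)
    sv_mean, sv_sd = region_stats(state.s_v, tum, vol)
    sb_mean, sb_sd = region_stats(state.sigma_bulk, tum, vol)
    pi_mean, pi_sd = region_stats(state.p_i, tn, nv)
    out = {
        "time_days": state.time,
        "tumor_volume_mm3": float(vol[tum].sum()),
        "tumor_bulk_stress_mean_pa": sb_mean, "tumor_bulk_stress_sd_pa": sb_sd,
        "tumor_sv_mean_per_mm": sv_mean, "tumor_sv_sd_per_mm": sv_sd,
        "tumor_p_i_mean_pa": pi_mean, "tumor_p_i_sd_pa": pi_sd,
        "tumor_sphericity": sphericity(mesh, state.coords),
        "tumor_shape_asymmetry": shape_asymmetry(mesh, state.coords),
    }
    if state.drug is not None and np.any(state.drug.c_int > 0):
        ci_mean, ci_sd = region_stats(state.drug.c_int, tn, nv)
        out["tumor_c_int_mean"] = ci_mean
        out["tumor_c_int_sd"] = ci_sd
        out["tumor_c_int_asymmetry"] = field_asymmetry(
            state.drug.c_int[tn], r_node[tn], nv[tn])
        out["tumor_c_int_fraction_above_half_mean"] = fraction_above(
            state.drug.c_int, tn, 0.5 * ci_mean, nv)
    return out
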