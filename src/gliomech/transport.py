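"""Interstitial fluid pressure, cancer-cell density, and oxygen transport.

Scalar transport runs on the same trilinear hexahedra as the mechanics
solver (2×2×2 Gauss), assembled on the *deformed* nodal coordinates so fluid
and species move through the grown configuration.  Hexahedra are used rather
than the derived tetrahedra because the Kuhn split of strongly curved
spherified-cube cells produces sliver tetrahedra that can invert under an
otherwise healthy deformation; the hexahedral Jacobians stay positive
wherever the mechanics solve is valid.

Time integration follows a split scheme: diffusion is backward-Euler implicit
(unconditionally stable, exactly mass-conservative because the stiffness
matrix has zero column sums), reactions are pointwise semi-implicit updates
that preserve positivity and bounds, and convection is an explicit
conservative weak-form term with a CFL guard.

Units: lengths mm; pressures Pa; the steady IFP problem is homogeneous in the
time unit (seconds cancel between k_th and L_P·S_v), while the transient
cell, oxygen, and drug steps use per-day rate constants throughout.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mechanics import _GP1, _SIGNS, hex_quadrature

__all__ = [
    "TransportError", "FluidState", "scalar_quadrature", "diffusion_matrix",
    "lumped_mass", "convection_matrix", "nodal_average", "solve_ifp",
    "darcy_velocity", "step_cells", "step_oxygen", "steady_oxygen",
]


class TransportError(RuntimeError):
    """Singular system or invalid transport input."""


@dataclasses.dataclass
class FluidState:
    """Steady interstitial fluid solution on the (deformed) mesh."""

    p_i: np.ndarray        # (n_nodes,) Pa
    v_f: np.ndarray        # (n_hexes, 3) Darcy velocity, mm per time unit of k_th
    k_th: float            # hydraulic conductivity, mm²/(Pa·time)


def _gauss_shape_values() -> np.ndarray:
    """Trilinear shape values N[q, b] at the 2×2×2 Gauss points."""
    gps = np.array([[sx * _GP1, sy * _GP1, sz * _GP1]
                    for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
    out = np.empty((8, 8))
    for q, xi in enumerate(gps):
        out[q] = np.prod(1.0 + _SIGNS * xi, axis=1) / 8.0
    return out


_N_GP = _gauss_shape_values()


def scalar_quadrature(mesh, coords) -> dict:
    """Physical gradients/weights for scalar FEM on the hexes at ``coords``.

    Returns the ``hex_quadrature`` dict plus the element volumes; raises if
    any hexahedral Gauss-point Jacobian is non-positive.
    """
    return hex_quadrature(np.asarray(coords, dtype=float), mesh.hexes)


def diffusion_matrix(mesh, coords, d_elem, quad=None) -> sp.csr_matrix:
    """Stiffness ∫ ∇N_a · D ∇N_b dV for scalar or tensor per-hex D.

    ``d_elem`` is (m,) isotropic or (m, 3, 3) symmetric positive semidefinite;
    a non-symmetric or indefinite tensor raises.  Row and column sums are zero
    (no-flux natural boundary), so implicit diffusion conserves mass exactly.
    """
    quad = scalar_quadrature(mesh, coords) if quad is None else quad
    grads, w = quad["grads"], quad["w"]  # (m, 8gp, 8, 3), (m, 8gp)
    d = np.asarray(d_elem, dtype=float)
    if d.ndim <= 1:
        d = np.broadcast_to(d, (mesh.n_hexes,))
        ke = np.einsum("eq,eqai,eqbi->eab", w * d[:, None], grads, grads,
                       optimize=True)
    else:
        if d.shape[-2:] != (3, 3):
            raise TransportError("diffusivity must be scalar per element or (m, 3, 3)")
        if not np.allclose(d, d.swapaxes(-1, -2), rtol=0.0,
                           atol=1e-10 * max(np.abs(d).max(), 1.0)):
            raise TransportError("diffusion tensor must be symmetric")
        ev = np.linalg.eigvalsh(d)
        if np.any(ev < -1e-10 * max(np.abs(ev).max(), 1.0)):
            raise TransportError("diffusion tensor must be positive semidefinite")
        flux = np.einsum("eij,eqaj->eqai", d, grads)
        ke = np.einsum("eq,eqai,eqbi->eab", w, flux, grads, optimize=True)
    rows = np.repeat(mesh.hexes, 8, axis=1).ravel()
    cols = np.tile(mesh.hexes, (1, 8)).ravel()
    n = mesh.n_nodes
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def lumped_mass(mesh, coords, quad=None) -> np.ndarray:
    """Row-sum lumped nodal volumes Σ_q w_q N_b(ξ_q), shape (n_nodes,)."""
    quad = scalar_quadrature(mesh, coords) if quad is None else quad
    contrib = quad["w"] @ _N_GP  # (m, 8): per-element nodal volume shares
    mv = np.zeros(mesh.n_nodes)
    np.add.at(mv, mesh.hexes.ravel(), contrib.ravel())
    return mv


def nodal_average(mesh, coords, values_hex, quad=None) -> np.ndarray:
    """Volume-weighted nodal average of a per-hex field (consistent lumping)."""
    quad = scalar_quadrature(mesh, coords) if quad is None else quad
    contrib = quad["w"] @ _N_GP  # (m, 8)
    v = np.asarray(values_hex, dtype=float)
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    np.add.at(num, mesh.hexes.ravel(), (contrib * v[:, None]).ravel())
    np.add.at(den, mesh.hexes.ravel(), contrib.ravel())
    return num / den


def convection_matrix(mesh, coords, v_elem, quad=None) -> sp.csr_matrix:
    """Conservative weak-form convection operator C with (C c)_a ≈ ∫ N_a ∇·(v c).

    Uses −∫ c v·∇N_a dV with per-hex velocity; column sums vanish (Σ_a ∇N_a
    = 0), so total mass is conserved; boundary outflow is neglected (the far
    field carries negligible flux).
    """
    quad = scalar_quadrature(mesh, coords) if quad is None else quad
    grads, w = quad["grads"], quad["w"]
    v = np.asarray(v_elem, dtype=float)
    vdg = np.einsum("eqai,ei->eqa", grads, v)       # v·∇N_a per gp
    ke = -np.einsum("eq,eqa,qb->eab", w, vdg, _N_GP, optimize=True)
    rows = np.repeat(mesh.hexes, 8, axis=1).ravel()
    cols = np.tile(mesh.hexes, (1, 8)).ravel()
    n = mesh.n_nodes
    return sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def solve_ifp(
    mesh,
    coords,
    sv: np.ndarray,
    l_p: float,
    p_v: float,
    k_th: float,
    lymph: np.ndarray | None = None,
    p_vl: float = 0.0,
    pin_far_field: bool = True,
) -> FluidState:
    """Steady interstitial fluid pressure −∇·(k_th ∇p) = L_P S_v (p_v − p) − λ_l (p − p_vl).

    ``sv`` is the functional vascular density (1/mm), either per node or per
    hex (per-hex coefficients keep the tumor/host interface sharp);
    ``lymph`` holds the lymphatic drainage coefficient L_Pl·S_vl (zero inside
    the tumor — lymphatics are absent there) in the same 1/(Pa·time) family
    as L_P·S_v.  The outer surface is pinned to the far-field gauge p = 0
    when ``pin_far_field``; without pinning a system with all-zero reaction
    terms is singular and raises.  Returns the nodal pressure and the per-hex
    Darcy velocity v_f = −k_th ∇p at the element centroid.
    """
    if k_th <= 0:
        raise TransportError("k_th must be positive")
    sv = np.asarray(sv, dtype=float)
    if np.any(sv < 0):
        raise TransportError("vascular density must be non-negative")
    n = mesh.n_nodes
    react = l_p * sv.copy()
    rhs_coeff = l_p * sv * p_v
    if lymph is not None:
        lym = np.asarray(lymph, dtype=float)
        react = react + lym
        rhs_coeff = rhs_coeff + lym * p_vl
    if not pin_far_field and np.all(react == 0.0):
        raise TransportError("all-zero sources with no far-field pinning: singular system")
    quad = scalar_quadrature(mesh, coords)
    a = diffusion_matrix(mesh, coords, k_th, quad=quad)
    if react.shape[0] == mesh.n_hexes and mesh.n_hexes != n:
        # per-element coefficients: lump each element's reaction integral onto
        # its vertices, keeping region interfaces sharp instead of smearing
        contrib = quad["w"] @ _N_GP  # (m, 8)
        diag = np.zeros(n)
        b = np.zeros(n)
        np.add.at(diag, mesh.hexes.ravel(), (contrib * react[:, None]).ravel())
        np.add.at(b, mesh.hexes.ravel(), (contrib * rhs_coeff[:, None]).ravel())
        a = a + sp.diags(diag)
    else:
        mv = lumped_mass(mesh, coords, quad=quad)
        a = a + sp.diags(mv * react)
        b = mv * rhs_coeff
    if pin_far_field:
        fixed = mesh.outer_nodes
        free = np.setdiff1d(np.arange(n), fixed)
        a_ff = a.tocsr()[free][:, free].tocsc()
        p = np.zeros(n)
        p[free] = spla.splu(a_ff).solve(b[free])
    else:
        p = spla.splu(a.tocsc()).solve(b)
    return FluidState(p_i=p, v_f=darcy_velocity(mesh, coords, p, k_th, quad=quad),
                      k_th=k_th)


def darcy_velocity(mesh, coords, p_i, k_th, quad=None) -> np.ndarray:
    """Per-hex Darcy velocity v_f = −k_th ∇p_i (volume-averaged over the cell)."""
    quad = scalar_quadrature(mesh, coords) if quad is None else quad
    grads, w = quad["grads"], quad["w"]
    p = np.asarray(p_i, dtype=float)[mesh.hexes]  # (m, 8)
    grad_p = np.einsum("eq,eqai,ea->ei", w, grads, p) / quad["volume"][:, None]
    return -k_th * grad_p


def _implicit_diffusion(mesh, coords, field, d_elem, dt, cache, key):
    """Backward-Euler diffusion step (M + dt K) c_new = M c, with factor reuse.

    The cache is valid for fixed (coords, d_elem, dt); callers must supply a
    fresh cache when the geometry changes.
    """
    if cache is None:
        cache = {}
    if cache.get(key + ":dt") != dt or key + ":factor" not in cache:
        quad = scalar_quadrature(mesh, coords)
        mv = lumped_mass(mesh, coords, quad=quad)
        k = diffusion_matrix(mesh, coords, d_elem, quad=quad)
        cache[key + ":mv"] = mv
        cache[key + ":factor"] = spla.splu((sp.diags(mv) + dt * k).tocsc())
        cache[key + ":dt"] = dt
    mv = cache[key + ":mv"]
    return cache[key + ":factor"].solve(mv * field)


def step_cells(
    mesh,
    coords,
    t_cel: np.ndarray,
    d_tensor: np.ndarray,
    c_ox: np.ndarray,
    tumor_nodes: np.ndarray,
    k1: float,
    k2: float,
    rho_cell: float,
    dt: float,
    cache: dict | None = None,
) -> np.ndarray:
    """Advance the normalized cell density one step of ∂T/∂t = ∇·(D_T ∇T) + R.

    R = r_g = k1 c_ox/(k2 + c_ox) T inside the tumor (``tumor_nodes`` boolean
    mask) and ρ_cell·T in the host.  Exact pointwise exponential reaction,
    implicit diffusion; the result is clipped at zero (trilinear diffusion on
    curved hexes can undershoot by a discretization-level amount).
    """
    if dt <= 0:
        raise TransportError("dt must be positive")
    t = np.asarray(t_cel, dtype=float)
    if np.any(t < 0):
        raise TransportError("cell density must be non-negative")
    c = np.asarray(c_ox, dtype=float)
    growth = np.where(tumor_nodes, k1 * c / (k2 + c), rho_cell)
    t_star = t * np.exp(growth * dt)
    if np.isscalar(d_tensor) and d_tensor == 0:
        return t_star
    out = _implicit_diffusion(mesh, coords, t_star, d_tensor, dt, cache, "cells")
    return np.maximum(out, 0.0)


def step_oxygen(
    mesh,
    coords,
    c_ox: np.ndarray,
    v_f: np.ndarray | None,
    sv_nodes: np.ndarray,
    t_cel: np.ndarray,
    d_ox: float,
    per_ox: float,
    c_iox: float,
    a_ox: float,
    k_ox: float,
    dt: float,
    cache: dict | None = None,
) -> np.ndarray:
    """One transient oxygen step: supply Per·S_v (c_iox − c), Michaelis uptake,
    conservative convection (explicit, CFL-guarded), implicit diffusion.

    The pointwise reaction update is semi-implicit, so starting in
    [0, c_iox] the reaction stage stays in [0, c_iox].
    """
    if dt <= 0:
        raise TransportError("dt must be positive")
    c = np.asarray(c_ox, dtype=float)
    sv = np.asarray(sv_nodes, dtype=float)
    t = np.asarray(t_cel, dtype=float)
    supply = per_ox * sv
    uptake = a_ox * t / (c + k_ox)
    c = (c + dt * supply * c_iox) / (1.0 + dt * (supply + uptake))
    if v_f is not None and np.any(np.asarray(v_f) != 0.0):
        quad = scalar_quadrature(mesh, coords)
        h = quad["volume"] ** (1.0 / 3.0)
        vmax = np.abs(np.asarray(v_f)).max()
        if vmax * dt > 0.5 * h.min():
            raise TransportError(
                f"convection CFL violated: |v| dt = {vmax * dt:.3e} mm exceeds half "
                f"the smallest element size {h.min():.3e} mm")
        mv = lumped_mass(mesh, coords, quad=quad)
        conv = convection_matrix(mesh, coords, v_f, quad=quad)
        c = c - dt * (conv @ c) / mv
    if d_ox > 0:
        c = _implicit_diffusion(mesh, coords, c, d_ox, dt, cache, "oxygen")
    return c


def steady_oxygen(
    mesh,
    coords,
    sv_nodes: np.ndarray,
    t_cel: np.ndarray,
    d_ox: float,
    per_ox: float,
    c_iox: float,
    a_ox: float,
    k_ox: float,
    c0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 60,
) -> np.ndarray:
    """Quasi-steady oxygen field by Picard iteration on the Michaelis term.

    Solves ∇·(D∇c) + Per S_v (c_iox − c) − A_ox T c/(c + k_ox) = 0 with
    no-flux boundaries; convection is neglected here (oxygen Péclet numbers
    are tiny at interstitial velocities).  Returns the converged nodal field.
    """
    sv = np.asarray(sv_nodes, dtype=float)
    t = np.asarray(t_cel, dtype=float)
    c = np.full(mesh.n_nodes, c_iox) if c0 is None else np.array(c0, dtype=float)
    quad = scalar_quadrature(mesh, coords)
    mv = lumped_mass(mesh, coords, quad=quad)
    k = diffusion_matrix(mesh, coords, d_ox, quad=quad)
    supply = per_ox * sv
    for _ in range(max_iter):
        upt = a_ox * t / (c + k_ox)
        a = (k + sp.diags(mv * (supply + upt))).tocsc()
        c_new = spla.splu(a).solve(mv * supply * c_iox)
        c_new = np.clip(c_new, 0.0, c_iox)
        delta = np.abs(c_new - c).max()
        c = c_new
        if delta <= tol * max(c_iox, 1e-30):
            return c
    raise TransportError("steady oxygen Picard iteration did not converge")
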