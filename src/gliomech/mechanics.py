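"""Quasi-static finite-strain stress balance  ∇·(σ_s − p_i I) = 0.

Total-Lagrangian trilinear hexahedral finite elements on the spherified-cube
mesh.  Brain tissue is nearly incompressible (k ≫ G), so the volumetric part
of the energy — and the interstitial-pressure load — use a mean-dilatation
(B-bar) treatment: the elastic dilatation is replaced by its element average
and the resulting element-constant pressure acts through the fully integrated
∫ J F⁻ᵀ : ∇N dV operator, while the deviatoric part uses the full 2×2×2 Gauss
rule.  This avoids the volumetric locking a pure displacement formulation
suffers on nearly incompressible material.  The growth tensor Fg is held
per element, F is measured from the initial configuration, Fe = F·Fg⁻¹.
Newton's method uses an analytic consistent tangent, a backtracking line
search guarded against element inversion, factorization reuse across steps
(modified Newton), and automatic ramping of (Fg − I) if a full-step solve
fails.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = ["MechanicalSolution", "SolverError", "solve_displacement", "bulk_stress",
           "hex_quadrature"]

_EYE = np.eye(3)
# vertex sign pattern, bit order x + 2y + 4z
_SIGNS = np.array([[(b >> a) & 1 for a in range(3)] for b in range(8)]) * 2 - 1
_GP1 = 1.0 / np.sqrt(3.0)


class SolverError(RuntimeError):
    """Newton failed to converge or an element inverted irrecoverably."""


@dataclasses.dataclass
class MechanicalSolution:
    """Displacement and per-hex stress state of one equilibrium solve."""

    u: np.ndarray           # (n_nodes, 3) mm
    F: np.ndarray           # (n_hexes, 3, 3) centroid deformation gradient
    Fe: np.ndarray          # (n_hexes, 3, 3) centroid elastic part
    sigma: np.ndarray       # (n_hexes, 3, 3) solid Cauchy stress, Pa
    sigma_bulk: np.ndarray  # (n_hexes,) tr(σ_s), Pa; negative = compression
    sigma_tot: np.ndarray   # (n_hexes, 3, 3) σ_s − p_i I, Pa
    newton_iters: int
    residual_norm: float


def bulk_stress(sigma: np.ndarray) -> np.ndarray:
    """Bulk solid stress: the trace of σ_s (negative sign denotes compression)."""
    return np.einsum("...ii->...", np.asarray(sigma, dtype=float))


def _shape_gradients_ref(xi: np.ndarray) -> np.ndarray:
    """dN_b/dξ_α at reference point xi, shape (8, 3)."""
    s = _SIGNS
    out = np.empty((8, 3))
    for b in range(8):
        f = 1.0 + s[b] * xi
        out[b, 0] = s[b, 0] * f[1] * f[2] / 8.0
        out[b, 1] = s[b, 1] * f[0] * f[2] / 8.0
        out[b, 2] = s[b, 2] * f[0] * f[1] / 8.0
    return out


def hex_quadrature(nodes: np.ndarray, hexes: np.ndarray):
    """Physical shape-function gradients and weights for 2×2×2 Gauss + centroid.

    Returns dict with ``grads`` (m, 8gp, 8, 3), ``w`` (m, 8gp),
    ``grads_c`` (m, 8, 3), ``w_c`` (m,) — w_c is the element volume.
    """
    xh = nodes[hexes]  # (m, 8, 3)
    gps = np.array([[sx * _GP1, sy * _GP1, sz * _GP1]
                    for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)])
    m = hexes.shape[0]
    grads = np.empty((m, 8, 8, 3))
    w = np.empty((m, 8))
    for q, xi in enumerate(gps):
        dref = _shape_gradients_ref(xi)  # (8, 3)
        jac = np.einsum("ebi,ba->eia", xh, dref)  # (m, 3ref->3phys? rows i, cols alpha)
        det = np.linalg.det(jac)
        if np.any(det <= 0):
            raise ValueError("non-positive hexahedron Jacobian")
        jinv = np.linalg.inv(jac)
        grads[:, q] = np.einsum("ba,eai->ebi", dref, jinv)
        w[:, q] = det  # unit gauss weight
    dref_c = _shape_gradients_ref(np.zeros(3))
    jac_c = np.einsum("ebi,ba->eia", xh, dref_c)
    det_c = np.linalg.det(jac_c)
    if np.any(det_c <= 0):
        raise ValueError("non-positive hexahedron centroid Jacobian")
    grads_c = np.einsum("ba,eai->ebi", dref_c, np.linalg.inv(jac_c))
    return {"grads": grads, "w": w, "grads_c": grads_c, "w_c": 8.0 * det_c,
            "volume": w.sum(axis=1)}


# -- constitutive pieces (per-point, vectorized) ---------------------------

def _dev_stress_tangent(fe, g, want_tangent, isochoric=True):
    """Deviatoric first Piola P = ∂W_dev/∂Fe, its tangent dP/dFe, det Fe, Fe⁻¹."""
    je = np.linalg.det(fe)
    if np.any(je <= 0):
        return None, None, None, None
    fi = np.linalg.inv(fe)
    fit = fi.swapaxes(-1, -2)
    g_ = g[..., None, None]
    if not isochoric:
        p = g_ * fe
        a = np.einsum("e,ik,JL->eiJkL", g, _EYE, _EYE) if want_tangent else None
        return p, a, je, fi
    i1 = np.einsum("...ij,...ij->...", fe, fe)
    jm23 = je ** (-2.0 / 3.0)
    dev = fe - (i1 / 3.0)[..., None, None] * fit
    p = g_ * jm23[..., None, None] * dev
    a = None
    if want_tangent:
        gj = g * jm23
        a = (
            -(2.0 / 3.0) * np.einsum("e,eiJ,ekL->eiJkL", gj, dev, fit)
            + np.einsum("e,ik,JL->eiJkL", gj, _EYE, _EYE)
            - (2.0 / 3.0) * np.einsum("e,ekL,eiJ->eiJkL", gj, fe, fit)
            + np.einsum("e,eJk,eLi->eiJkL", gj * i1 / 3.0, fi, fi)
        )
    return p, a, je, fi


def solve_displacement(
    mesh,
    g_elem: np.ndarray,
    k_elem: np.ndarray,
    lambda_g: np.ndarray,
    p_i_nodes: np.ndarray | None = None,
    u0: np.ndarray | None = None,
    boundary: str = "fixed",
    isochoric: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-6,
    max_iter: int = 50,
    max_ramp: int = 16,
    cache: dict | None = None,
) -> MechanicalSolution:
    """Solve the stress balance for the displacement field.

    Parameters
    ----------
    g_elem, k_elem : per-hex shear and bulk moduli, Pa (scalars broadcast).
    lambda_g : (n_hexes, 3) diagonal growth stretches (>= 1).
    p_i_nodes : interstitial fluid pressure per node, Pa (optional).
    boundary : "fixed" pins the outer surface (u = 0, the model BC); "free"
        pins rigid-body modes only (verification geometries).
    cache : optional dict persisting quadrature data and the factorized
        tangent between calls (modified Newton across growth steps).
    """
    m = mesh.n_hexes
    lambda_g = np.atleast_2d(np.asarray(lambda_g, dtype=float))
    if lambda_g.shape == (1, 3):
        lambda_g = np.broadcast_to(lambda_g, (m, 3)).copy()
    if np.any(lambda_g < 1.0 - 1e-12):
        raise ValueError("growth stretches must be >= 1")
    g_elem = np.broadcast_to(np.asarray(g_elem, dtype=float), (m,))
    k_elem = np.broadcast_to(np.asarray(k_elem, dtype=float), (m,))
    if cache is None:
        cache = {}
    if "quad" not in cache:
        cache["quad"] = hex_quadrature(mesh.nodes, mesh.hexes)
    quad = cache["quad"]
    grads, w, grads_c, w_c = quad["grads"], quad["w"], quad["grads_c"], quad["w_c"]
    n_dof = 3 * mesh.n_nodes

    p_elem = np.zeros(m)
    if p_i_nodes is not None:
        p_elem = np.asarray(p_i_nodes, dtype=float)[mesh.hexes].mean(axis=1)

    fixed = _fixed_dofs(mesh, boundary)
    free_mask = np.ones(n_dof, dtype=bool)
    free_mask[fixed] = False
    free = np.flatnonzero(free_mask)

    u = np.zeros((mesh.n_nodes, 3)) if u0 is None else np.array(u0, dtype=float)

    edof = (3 * mesh.hexes[:, :, None] + np.arange(3)[None, None, :]).reshape(m, 24)
    rows = np.repeat(edof, 24, axis=1).ravel()
    cols = np.tile(edof, (1, 24)).ravel()

    vol_e = quad["volume"]

    def elem_fields(u_nodes, lam, want_tangent):
        """Element residuals (m, 8, 3) and optional tangents (m, 24, 24)."""
        ue = u_nodes[mesh.hexes]  # (m, 8, 3)
        jg = np.prod(lam, axis=1)
        r_e = np.zeros((m, 8, 3))
        k_e = np.zeros((m, 24, 24)) if want_tangent else None
        scale_j = jg[:, None, None] / lam[:, None, :]  # maps P(Fe) -> P_tot columns
        # mean-dilatation accumulators: element-mean J, the 24-vector
        # v = ∫ (J F⁻ᵀ) : ∇N dV and the geometric kernel of d(J F⁻ᵀ)
        jbar = np.zeros(m)
        vvec = np.zeros((m, 8, 3))
        m_geo = np.zeros((m, 24, 24)) if want_tangent else None
        for q in range(8):
            gq = grads[:, q]
            f = _EYE + np.einsum("ebi,ebJ->eiJ", ue, gq)
            fe = f / lam[:, None, :]
            p_dev, a_dev, je, fi_e = _dev_stress_tangent(fe, g_elem, want_tangent, isochoric)
            if p_dev is None:
                return None, None
            p_tot = scale_j * p_dev
            r_e += w[:, q, None, None] * np.einsum("eiJ,ebJ->ebi", p_tot, gq)
            # volumetric kinematics in total quantities: F⁻¹ = Fg⁻¹ Fe⁻¹, J = Jg Je
            fi = fi_e / lam[:, :, None]
            j_q = jg * je
            wq = w[:, q]
            jbar += wq * j_q
            d_q = j_q[:, None, None] * fi.swapaxes(-1, -2)  # J F⁻ᵀ
            vvec += wq[:, None, None] * np.einsum("eiJ,ebJ->ebi", d_q, gq)
            if want_tangent:
                a_tot = a_dev * (jg[:, None, None, None, None]
                                 / (lam[:, None, :, None, None] * lam[:, None, None, None, :]))
                k_e += np.einsum("e,eiJkL,eaJ,ebL->eaibk", wq, a_tot, gq, gq,
                                 optimize=True).reshape(m, 24, 24)
                fit = fi.swapaxes(-1, -2)
                # d(J F⁻ᵀ)/dF = J (F⁻ᵀ ⊗ F⁻ᵀ − F⁻¹ ⊙ F⁻¹), contracted with ∇N
                ga = np.einsum("eiJ,ebJ->ebi", fit, gq)  # (m, 8, 3)
                m_geo += (wq[:, None, None] * j_q[:, None, None]
                          * np.einsum("eai,ebk->eaibk", ga, ga).reshape(m, 24, 24))
                m_geo -= (wq[:, None, None] * j_q[:, None, None]
                          * np.einsum("eJk,eLi,eaJ,ebL->eaibk", fi, fi, gq, gq,
                                      optimize=True).reshape(m, 24, 24))
        jbar_e = jbar / (vol_e * jg)  # element-mean elastic dilatation
        if np.any(jbar_e <= 0):
            return None, None
        c_tot = k_elem * (jbar_e - 1.0) - p_elem
        r_e += c_tot[:, None, None] * vvec
        if want_tangent:
            v24 = vvec.reshape(m, 24)
            k_e += c_tot[:, None, None] * m_geo
            k_e += (k_elem / (vol_e * jg))[:, None, None] * np.einsum(
                "ea,eb->eab", v24, v24)
        return r_e, k_e

    def assemble_residual(u_flat, lam):
        r_e, _ = elem_fields(u_flat.reshape(-1, 3), lam, False)
        if r_e is None:
            return None
        r = np.zeros(n_dof)
        np.add.at(r, edof.ravel(), r_e.reshape(m, 24).ravel())
        return r

    def assemble_tangent(u_flat, lam):
        r_e, k_e = elem_fields(u_flat.reshape(-1, 3), lam, True)
        if k_e is None:
            raise SolverError("inverted element during tangent assembly")
        k_mat = sp.coo_matrix((k_e.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsc()
        return k_mat[free][:, free]

    total_iters = 0
    rnorm = 0.0
    n_ramp = 1
    while True:
        try:
            u_ramp = u.copy()
            for step in range(1, n_ramp + 1):
                lam = 1.0 + (lambda_g - 1.0) * (step / n_ramp)
                u_ramp, iters, rnorm = _newton(
                    u_ramp, lam, assemble_residual, assemble_tangent,
                    free, rtol, atol, max_iter, cache)
                total_iters += iters
            u = u_ramp
            break
        except SolverError:
            cache.pop("factor", None)
            if n_ramp >= max_ramp:
                raise
            n_ramp *= 2

    # postprocess: deviatoric Cauchy averaged over gauss points, volumetric
    # from the element-mean dilatation (consistent with the integration rule)
    ue = u[mesh.hexes]
    jg = np.prod(lambda_g, axis=1)
    sigma = np.zeros((m, 3, 3))
    jbar = np.zeros(m)
    for q in range(8):
        f = _EYE + np.einsum("ebi,ebJ->eiJ", ue, grads[:, q])
        fe = f / lambda_g[:, None, :]
        p_dev, _, je, _ = _dev_stress_tangent(fe, g_elem, False, isochoric)
        sigma += np.einsum("eiJ,ekJ->eik", p_dev, fe) / je[:, None, None] / 8.0
        jbar += quad["w"][:, q] * jg * je
    jbar_e = jbar / (quad["volume"] * jg)
    sigma += (k_elem * (jbar_e - 1.0))[:, None, None] * _EYE
    sigma = 0.5 * (sigma + sigma.swapaxes(-1, -2))
    f_c = _EYE + np.einsum("ebi,ebJ->eiJ", ue, grads_c)
    fe_c = f_c / lambda_g[:, None, :]
    sig_tot = sigma - p_elem[:, None, None] * _EYE
    return MechanicalSolution(
        u=u, F=f_c, Fe=fe_c, sigma=sigma, sigma_bulk=bulk_stress(sigma),
        sigma_tot=sig_tot, newton_iters=total_iters, residual_norm=rnorm)


def _fixed_dofs(mesh, boundary: str) -> np.ndarray:
    if boundary == "fixed":
        dofs = [(3 * mesh.outer_nodes[:, None] + np.arange(3)).ravel()]
        # symmetry planes (octant meshes): zero normal displacement
        for axis, ids in enumerate(getattr(mesh, "symmetry_planes", (None,) * 3)):
            if ids is not None and len(ids):
                dofs.append(3 * np.asarray(ids) + axis)
        return np.unique(np.concatenate(dofs))
    if boundary != "free":
        raise ValueError("boundary must be 'fixed' or 'free'")
    # pin rigid-body modes only (6 constraints)
    r = np.linalg.norm(mesh.nodes, axis=1)
    center = int(np.argmin(r))
    on_x = mesh.nodes[:, 0] > 0.9 * r.max()
    ix = int(np.where(on_x)[0][np.argmin(np.abs(mesh.nodes[on_x, 1]) + np.abs(mesh.nodes[on_x, 2]))])
    on_y = mesh.nodes[:, 1] > 0.9 * r.max()
    iy = int(np.where(on_y)[0][np.argmin(np.abs(mesh.nodes[on_y, 0]) + np.abs(mesh.nodes[on_y, 2]))])
    return np.array([3 * center, 3 * center + 1, 3 * center + 2,
                     3 * ix + 1, 3 * ix + 2, 3 * iy + 2])


def _newton(u, lam, assemble_residual, assemble_tangent, free, rtol, atol,
            max_iter, cache):
    """Damped (modified) Newton with factorization reuse and refresh-on-stall."""
    u_flat = u.ravel().copy()
    r = assemble_residual(u_flat, lam)
    if r is None:
        raise SolverError("inverted element at initial guess")
    rnorm0 = np.linalg.norm(r[free])
    rnorm = rnorm0
    tol = max(rtol * rnorm0, atol)
    it = 0
    fresh = False
    while rnorm > tol:
        if it >= max_iter:
            raise SolverError(f"Newton did not converge: residual {rnorm:.3e} after {it} iterations")
        if "factor" not in cache:
            cache["factor"] = spla.splu(assemble_tangent(u_flat, lam))
            fresh = True
        du = cache["factor"].solve(-r[free])
        if not np.all(np.isfinite(du)):
            raise SolverError("singular tangent")
        alpha, ok, rn_try = 1.0, False, rnorm
        for _ in range(25):
            u_try = u_flat.copy()
            u_try[free] += alpha * du
            r_try = assemble_residual(u_try, lam)
            if r_try is not None:
                rn_try = np.linalg.norm(r_try[free])
                if rn_try < rnorm * (1.0 - 1e-4 * alpha) or rn_try < tol:
                    ok = True
                    break
            alpha *= 0.5
        if not ok:
            if fresh:
                raise SolverError(f"line search failed at residual {rnorm:.3e}")
            cache.pop("factor", None)  # stale factorization: refresh, retry
            continue
        reduction = rn_try / rnorm if rnorm > 0 else 0.0
        u_flat, r, rnorm = u_try, r_try, rn_try
        it += 1
        if not fresh and reduction > 0.5:
            cache.pop("factor", None)  # stale and slow: refresh next iteration
        fresh = False
    return u_flat.reshape(-1, 3), it, rnorm
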