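"""Independent 1D spherically-symmetric reference solvers.

These finite-difference solvers share nothing with the 3D finite-element path:
the constitutive response is re-derived here in principal stretches and the
discretizations are one-dimensional.  They exist to cross-check the 3D solvers
on spherically symmetric configurations (confined growth of a concentric-sphere
tumor; interstitial fluid pressure of a uniformly leaky sphere).
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded

__all__ = ["radial_growth_profile", "radial_ifp_profile"]


def _w_partials(a, b, g, k):
    """W(a,b) for principal elastic stretches (a, b, b) and its partials.

    W = G/2 (Je^{-2/3} I1 - 3) + k/2 (Je - 1)^2, Je = a b^2, I1 = a^2 + 2 b^2.
    Returns (W, dW/da, dW/db) with b counted twice in dW/db.
    """
    je = a * b * b
    i1 = a * a + 2.0 * b * b
    jm23 = je ** (-2.0 / 3.0)
    jm53 = je ** (-5.0 / 3.0)
    w = 0.5 * g * (jm23 * i1 - 3.0) + 0.5 * k * (je - 1.0) ** 2
    dw_da = 0.5 * g * (-(2.0 / 3.0) * jm53 * b * b * i1 + jm23 * 2.0 * a) + k * (je - 1.0) * b * b
    dw_db = 0.5 * g * (-(2.0 / 3.0) * jm53 * 2.0 * a * b * i1 + jm23 * 4.0 * b) + k * (je - 1.0) * 2.0 * a * b
    return w, dw_da, dw_db


def radial_growth_profile(
    tumor_radius: float,
    host_radius: float,
    lambda_g_tumor: float,
    g_tumor: float,
    g_host: float,
    k_tumor: float,
    k_host: float,
    n_cells: int = 800,
    fixed_outer: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
):
    """Equilibrium of a uniformly growing tumor sphere inside a host shell.

    Minimizes the total strain energy E = ∫ Jg W(Fe) 4πR² dR over the deformed
    radius map r(R) by damped Newton on the energy gradient (tridiagonal
    Jacobian via 3-coloring finite differences).  ``lambda_g_tumor`` is either
    the isotropic growth stretch inside the seed (1 in the host) or a callable
    λg(R) for smooth radial growth profiles; r(0)=0 and either
    r(R_out)=R_out (fixed) or a traction-free outer surface.

    Returns dict with cell-center reference radii ``R_mid``, deformed radii
    ``r_mid``, radial/hoop Cauchy stresses and ``bulk`` (their trace sum).
    """
    # grid refined near the interface
    n_t = n_cells // 2
    r_grid = np.concatenate([
        np.linspace(0.0, tumor_radius, n_t + 1),
        tumor_radius + (host_radius - tumor_radius)
        * (np.linspace(0.0, 1.0, n_cells - n_t + 1)[1:]) ** 1.5,
    ])
    nn = len(r_grid)
    dr = np.diff(r_grid)
    r_mid = 0.5 * (r_grid[1:] + r_grid[:-1])
    if callable(lambda_g_tumor):
        lam_g = lambda_g_tumor(r_mid)
    else:
        lam_g = np.where(r_mid < tumor_radius, lambda_g_tumor, 1.0)
    g_c = np.where(r_mid < tumor_radius, g_tumor, g_host)
    k_c = np.where(r_mid < tumor_radius, k_tumor, k_host)
    wgt = 4.0 * np.pi * r_mid ** 2 * dr * lam_g ** 3  # Jg dV

    free = np.arange(1, nn if not fixed_outer else nn - 1)

    def stretches(r_nodes):
        a = np.diff(r_nodes) / (dr * lam_g)               # radial
        b = 0.5 * (r_nodes[1:] + r_nodes[:-1]) / (r_mid * lam_g)  # hoop
        return a, b

    def grad(r_nodes):
        a, b = stretches(r_nodes)
        if np.any(a <= 0) or np.any(b <= 0):
            return None
        _, dwa, dwb = _w_partials(a, b, g_c, k_c)
        # dE/dr_i: cell left of node i contributes +dwa/(dr λg), right cell −;
        # both contribute dwb/(2 r_mid λg)
        ga = wgt * dwa / (dr * lam_g)
        gb = wgt * dwb * 0.5 / (r_mid * lam_g)
        out = np.zeros(nn)
        out[1:] += ga + gb
        out[:-1] += -ga + gb
        return out

    r_nodes = r_grid.copy()  # initial guess: identity map
    # gentle pre-inflation of tumor part for robustness
    for it in range(max_iter):
        g_vec = grad(r_nodes)
        if g_vec is None:
            raise RuntimeError("oracle: invalid state")
        gn = np.linalg.norm(g_vec[free])
        scale = np.abs(wgt * g_c).sum() / host_radius
        if gn < tol * scale:
            break
        # tridiagonal FD Jacobian by 3-coloring; restrict to free unknowns
        # (couplings to fixed nodes drop since their increment is zero)
        h = 1e-7 * host_radius
        jac = _banded_jacobian(grad, r_nodes, nn, h)
        rhs = -g_vec[free]
        ab = np.zeros((3, len(free)))
        ab[0, 1:] = jac[0, free[1:]]
        ab[1, :] = jac[1, free]
        ab[2, :-1] = jac[2, free[:-1]]
        du = solve_banded((1, 1), ab, rhs)
        alpha = 1.0
        for _ in range(40):
            trial = r_nodes.copy()
            trial[free] += alpha * du
            g_try = grad(trial)
            if g_try is not None and np.linalg.norm(g_try[free]) < gn:
                break
            alpha *= 0.5
        else:
            if gn < 1e-7 * scale:  # at the FD-Jacobian accuracy floor
                break
            raise RuntimeError("oracle: line search failed")
        r_nodes = trial
    else:
        raise RuntimeError("oracle: Newton did not converge")

    a, b = stretches(r_nodes)
    w, dwa, dwb = _w_partials(a, b, g_c, k_c)
    je = a * b * b
    sig_rr = a * dwa / je
    sig_tt = b * dwb / (2.0 * je)  # each of the two hoop directions
    return {
        "R_mid": r_mid,
        "r_mid": 0.5 * (r_nodes[1:] + r_nodes[:-1]),
        "r_nodes": r_nodes,
        "sigma_rr": sig_rr,
        "sigma_tt": sig_tt,
        "bulk": sig_rr + 2.0 * sig_tt,
        "region": (r_mid < tumor_radius).astype(int),
    }


def _banded_jacobian(grad, r_nodes, nn, h):
    """Tridiagonal Jacobian of the gradient by 3-colored central differences.

    Returns array (3, nn): [superdiag shifted, diag, subdiag shifted] in
    solve_banded layout for the full node set.
    """
    jac = np.zeros((3, nn))
    for color in range(3):
        pert = np.zeros(nn)
        idx = np.arange(color, nn, 3)
        pert[idx] = h
        gp = grad(r_nodes + pert)
        gm = grad(r_nodes - pert)
        col = (gp - gm) / (2.0 * h)
        for i in idx:
            jac[1, i] = col[i]
            if i + 1 < nn:
                jac[2, i] = col[i + 1]   # subdiagonal entry J[i+1, i]
            if i - 1 >= 0:
                jac[0, i] = col[i - 1]   # superdiagonal entry J[i-1, i]
    return jac


def radial_ifp_profile(
    tumor_radius: float,
    host_radius: float,
    k_th: float,
    source_coeff_tumor: float,
    source_value_tumor: float,
    source_coeff_host: float,
    source_value_host: float,
    n_cells: int = 20000,
):
    """Steady radial reaction–diffusion for the interstitial fluid pressure.

    Solves −k_th (1/r²)(r² p')' = c(r) (p_eq(r) − p) with p'(0) = 0 and
    p(R_out) = 0 on a fine uniform grid, where c = L_P S_v (+ lymphatic term)
    and c·p_eq is the corresponding source.  Conservative FD, tridiagonal.
    """
    r = np.linspace(0.0, host_radius, n_cells + 1)
    dr = r[1] - r[0]
    r_mid = 0.5 * (r[1:] + r[:-1])
    c = np.where(r_mid < tumor_radius, source_coeff_tumor, source_coeff_host)
    s = np.where(r_mid < tumor_radius,
                 source_coeff_tumor * source_value_tumor,
                 source_coeff_host * source_value_host)
    # unknowns p at cell centers; faces at r[1:-1]
    n = n_cells
    face_r2 = r[1:-1] ** 2
    kf = k_th * face_r2 / dr
    lower = np.zeros(n)
    diag = np.zeros(n)
    upper = np.zeros(n)
    rhs = s * r_mid ** 2 * dr
    diag += c * r_mid ** 2 * dr
    diag[:-1] += kf
    diag[1:] += kf
    upper[1:] = -kf
    lower[:-1] = -kf
    # outer Dirichlet p=0 at r=R: ghost via face at R with half-cell distance
    k_out = k_th * host_radius ** 2 / (dr / 2.0)
    diag[-1] += k_out
    ab = np.zeros((3, n))
    ab[0] = upper
    ab[1] = diag
    ab[2] = lower
    p = solve_banded((1, 1), ab, rhs)
    return {"r_mid": r_mid, "p": p}
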