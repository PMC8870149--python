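"""Transvascular drug delivery: pore hindrance, wall coefficients, bolus,
Starling flux, and the free/bound/internalized drug fields.

Drug crosses the vessel wall through cylindrical pores.  The steric partition
coefficient F = (1−λ)² and the Bungay–Brenner hydrodynamic resistance
functions K_t, K_s (series in the drug-radius/pore-radius ratio λ) give the
diffusive hindrance H = 6πF/K_t and the convective hindrance
w = F(2−F)K_s/(2K_t); the reflection coefficient is σ_f = 1 − w.  The wall
hydraulic conductivity is L_p = γ r₀²/(8 η L_vw) and the permeability
Per = γ H D₀ / L_vw for pore area fraction γ and wall thickness L_vw.

In tissue the free drug c_f convects/diffuses, exchanges with the plasma by
the Starling flux, binds reversibly to cells (c_b) and is internalized
(c_int); all concentrations are normalized to the injected plasma level.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .transport import (TransportError, convection_matrix, lumped_mass,
                        scalar_quadrature, _implicit_diffusion)

__all__ = [
    "BUNGAY_BRENNER_A", "BUNGAY_BRENNER_B", "hindrance_factors",
    "wall_transport", "vascular_concentration", "starling_flux",
    "DrugState", "step_drug",
]

# Bungay & Brenner (1973) coefficients for the centerline hydrodynamic
# resistance of a sphere in a cylindrical pore: a_n enter K_t, b_n enter K_s.
BUNGAY_BRENNER_A = (-73.0 / 60.0, 77293.0 / 50400.0,
                    -22.5083, -5.6117, -0.3363, -1.216, 1.647)
BUNGAY_BRENNER_B = (7.0 / 60.0, -2227.0 / 50400.0,
                    4.0180, -3.9788, -1.9215, 4.392, 5.006)


def _resistance(lam: float, coeff) -> float:
    """K(λ) = (9π²√2/4)(1−λ)^(−5/2)[1 + Σ₁² cₙ(1−λ)ⁿ] + Σ₀⁴ c₍ₙ₊₃₎ λⁿ."""
    eps = 1.0 - lam
    lead = (9.0 * np.pi ** 2 * np.sqrt(2.0) / 4.0) * eps ** (-2.5) * (
        1.0 + coeff[0] * eps + coeff[1] * eps ** 2)
    poly = sum(coeff[n + 2] * lam ** n for n in range(5))
    return lead + poly


def hindrance_factors(lambda_ratio: float):
    """Steric and hydrodynamic pore-hindrance factors for λ = r_drug/r_pore.

    Returns (F_part, K_t, K_s, H, w, sigma_f).  At λ = 0 the particle is
    unhindered (F = H = w = 1, σf = 0); at λ = 1 it is fully excluded
    (F = H = w = 0, σf = 1, the resistances diverge).
    """
    lam = float(lambda_ratio)
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda_ratio must lie in [0, 1]")
    f_part = (1.0 - lam) ** 2
    if lam == 1.0:
        return 0.0, np.inf, np.inf, 0.0, 0.0, 1.0
    k_t = _resistance(lam, BUNGAY_BRENNER_A)
    k_s = _resistance(lam, BUNGAY_BRENNER_B)
    h = 6.0 * np.pi * f_part / k_t
    w = f_part * (2.0 - f_part) * k_s / (2.0 * k_t)
    return f_part, k_t, k_s, h, w, 1.0 - w


def wall_transport(gamma: float, r0_nm: float, eta_pa_s: float,
                   l_vw_um: float, d0_mm2_s: float, lambda_ratio: float):
    """Vessel-wall transport coefficients from pore geometry.

    L_p = γ r₀²/(8 η L_vw) in mm/(Pa·s); Per = γ H D₀/L_vw in mm/s with D₀ in
    mm²/s; σf = 1 − w.  Pore radius in nm, wall thickness in µm.
    """
    if min(gamma, r0_nm, eta_pa_s, l_vw_um, d0_mm2_s) <= 0:
        raise ValueError("all physical wall parameters must be positive")
    r0_mm = r0_nm * 1e-6
    l_vw_mm = l_vw_um * 1e-3
    l_p = gamma * r0_mm ** 2 / (8.0 * eta_pa_s * l_vw_mm)
    _, _, _, h, w, sigma_f = hindrance_factors(lambda_ratio)
    per = gamma * h * d0_mm2_s / l_vw_mm
    return l_p, per, sigma_f


def vascular_concentration(t: float, t0: float, k_d: float):
    """Bolus plasma concentration C_iv = exp(−(t−t0)/k_d), 0 before injection."""
    if k_d <= 0:
        raise ValueError("k_d must be positive")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= t0, np.exp(-(t - t0) / k_d), 0.0)
    return out if out.ndim else float(out)


def starling_flux(per, s_v, c_iv, c_f, l_p, p_v, p_i, sigma_f):
    """Transvascular drug source Q = Per·S_v (C_iv − c_f) + L_p·S_v (p_v − p_i)(1 − σf) C_iv."""
    s_v = np.asarray(s_v, dtype=float)
    if np.any(s_v < 0):
        raise ValueError("S_v must be non-negative")
    diff = per * s_v * (np.asarray(c_iv) - np.asarray(c_f))
    conv = l_p * s_v * (np.asarray(p_v) - np.asarray(p_i)) * (1.0 - sigma_f) * np.asarray(c_iv)
    return diff + conv


@dataclasses.dataclass
class DrugState:
    """Nodal free / bound / internalized drug fields (normalized units)."""

    c_f: np.ndarray
    c_b: np.ndarray
    c_int: np.ndarray

    @classmethod
    def zero(cls, n: int) -> "DrugState":
        return cls(np.zeros(n), np.zeros(n), np.zeros(n))

    @property
    def total(self) -> np.ndarray:
        return self.c_f + self.c_b + self.c_int


def step_drug(
    mesh,
    coords,
    state: DrugState,
    v_f: np.ndarray | None,
    q_sta: np.ndarray | None,
    d_f: float,
    kon_ce_phi: float,
    k_off: float,
    k_int: float,
    dt: float,
    cache: dict | None = None,
) -> DrugState:
    """Advance the three drug fields by one step of length dt (days).

    Order: vascular source (explicit) → binding/unbinding/internalization
    (pairwise transfers, so c_f + c_b + c_int is conserved exactly by
    construction; sub-stepped if dt·rates approaches 1) → explicit
    conservative convection → implicit diffusion of c_f (exactly mass
    conservative).  Non-negativity is preserved by the sub-step guard.
    """
    if dt <= 0:
        raise TransportError("dt must be positive")
    if min(kon_ce_phi, k_off, k_int) < 0:
        raise TransportError("rate constants must be non-negative")
    if cache is None:
        cache = {}
    c_f = np.array(state.c_f, dtype=float)
    c_b = np.array(state.c_b, dtype=float)
    c_int = np.array(state.c_int, dtype=float)
    if q_sta is not None:
        c_f = np.maximum(c_f + dt * np.asarray(q_sta, dtype=float), 0.0)
    # pairwise reaction transfers; sub-step so no pool can be overdrawn
    n_sub = max(1, int(np.ceil(dt * max(kon_ce_phi, k_off + k_int) / 0.2)))
    h = dt / n_sub
    for _ in range(n_sub):
        t_bind = h * kon_ce_phi * c_f
        t_unbind = h * k_off * c_b
        t_intern = h * k_int * c_b
        c_f += t_unbind - t_bind
        c_b += t_bind - t_unbind - t_intern
        c_int += t_intern
    if v_f is not None and np.any(np.asarray(v_f) != 0.0):
        quad = scalar_quadrature(mesh, coords)
        hmin = quad["volume"].min() ** (1.0 / 3.0)
        vmax = np.abs(np.asarray(v_f)).max()
        if vmax * dt > 0.5 * hmin:
            raise TransportError(
                f"drug convection CFL violated: |v| dt = {vmax * dt:.3e} mm vs "
                f"element size {hmin:.3e} mm")
        if "drug:mv" not in cache:
            cache["drug:mv"] = lumped_mass(mesh, coords, quad=quad)
        if "drug:conv" not in cache:
            cache["drug:conv"] = convection_matrix(mesh, coords, v_f, quad=quad)
        c_f = c_f - dt * (cache["drug:conv"] @ c_f) / cache["drug:mv"]
    if d_f > 0:
        c_f = _implicit_diffusion(mesh, coords, c_f, d_f, dt, cache, "drug")
    return DrugState(c_f=c_f, c_b=c_b, c_int=c_int)
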