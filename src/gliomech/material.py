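"""Constitutive model: MRE modulus inversion and neo-Hookean stress response.

The elastography experiment reports the storage modulus G'(ω) and loss modulus
G''(ω) of a single-relaxation (Maxwell-type) solid,

    G'(ω)  = G (ωτ)^2 / (1 + (ωτ)^2),
    G''(ω) = G  ωτ    / (1 + (ωτ)^2),

which invert uniquely to the elastic shear modulus G = G' + G''^2/G' and the
characteristic decay time τ = (G'/G'') / ω.  Only the elastic branch enters the
mechanics; τ is carried along for completeness.

The solid Cauchy stress follows a compressible neo-Hookean strain energy per
unit volume of the stress-free grown configuration,

    W = G/2 (Ī1 − 3) + k/2 (Je − 1)^2,      Ī1 = Je^{−2/3} I1,

with σ_s = Je^{−1} (∂W/∂Fe) Fe^T.  Using the isochoric invariant Ī1 makes the
reference state exactly stress-free; the "raw" variant W = G/2 (I1 − 3) + ...
is retained behind ``isochoric=False`` for comparison.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "reconstruct_shear_modulus",
    "storage_loss_moduli",
    "strain_energy",
    "piola_stress_elastic",
    "cauchy_stress",
]


def reconstruct_shear_modulus(g_storage, g_loss, omega):
    """Invert the storage/loss moduli to (G, tau_m).

    Parameters are scalars or broadcastable arrays; G_storage must be > 0,
    G_loss >= 0, omega > 0.  G_loss == 0 is the purely elastic limit: G equals
    G_storage and tau_m is +inf.
    """
    gp = np.asarray(g_storage, dtype=float)
    gpp = np.asarray(g_loss, dtype=float)
    if np.any(gp <= 0):
        raise ValueError("storage modulus must be positive")
    if np.any(gpp < 0):
        raise ValueError("loss modulus must be non-negative")
    if np.any(np.asarray(omega) <= 0):
        raise ValueError("radial frequency must be positive")
    g = gp + np.divide(gpp * gpp, gp)
    with np.errstate(divide="ignore"):
        tau = np.where(gpp > 0, np.divide(gp, np.where(gpp > 0, gpp, 1.0)) / omega, np.inf)
    if np.ndim(g_storage) == 0 and np.ndim(g_loss) == 0:
        return float(g), float(tau)
    return g, tau


def storage_loss_moduli(g, tau_m, omega):
    """Forward map (G, tau_m, omega) -> (G', G'')."""
    wt = np.asarray(omega, dtype=float) * np.asarray(tau_m, dtype=float)
    g = np.asarray(g, dtype=float)
    wt2 = wt * wt
    denom = 1.0 + wt2
    gp = np.where(np.isinf(wt), g, g * wt2 / denom)
    gpp = np.where(np.isinf(wt), 0.0, g * wt / denom)
    return gp, gpp


def _dets(fe: np.ndarray) -> np.ndarray:
    return np.linalg.det(fe)


def strain_energy(fe: np.ndarray, g, k, isochoric: bool = True) -> np.ndarray:
    """Strain energy density W(Fe) in Pa (per unit grown volume).

    ``fe`` has shape (..., 3, 3); ``g`` and ``k`` broadcast over the leading axes.
    """
    fe = np.asarray(fe, dtype=float)
    je = _dets(fe)
    if np.any(je <= 0):
        raise ValueError("det Fe must be positive (inverted element)")
    i1 = np.einsum("...ij,...ij->...", fe, fe)
    g = np.asarray(g, dtype=float)
    k = np.asarray(k, dtype=float)
    if isochoric:
        i1_bar = je ** (-2.0 / 3.0) * i1
        return 0.5 * g * (i1_bar - 3.0) + 0.5 * k * (je - 1.0) ** 2
    return 0.5 * g * (i1 - 3.0) + 0.5 * k * (je - 1.0) ** 2


def piola_stress_elastic(fe: np.ndarray, g, k, isochoric: bool = True) -> np.ndarray:
    """∂W/∂Fe, shape (..., 3, 3) — first Piola stress wrt the grown configuration."""
    fe = np.asarray(fe, dtype=float)
    je = _dets(fe)
    if np.any(je <= 0):
        raise ValueError("det Fe must be positive (inverted element)")
    fe_inv_t = np.linalg.inv(fe).swapaxes(-1, -2)
    g = np.asarray(g, dtype=float)[..., None, None]
    k = np.asarray(k, dtype=float)[..., None, None]
    je_ = je[..., None, None]
    if isochoric:
        i1 = np.einsum("...ij,...ij->...", fe, fe)[..., None, None]
        dev = fe - (i1 / 3.0) * fe_inv_t
        p_shear = g * je_ ** (-2.0 / 3.0) * dev
    else:
        p_shear = g * fe
    p_vol = k * (je_ - 1.0) * je_ * fe_inv_t
    return p_shear + p_vol


def cauchy_stress(fe: np.ndarray, g, k, isochoric: bool = True):
    """Solid Cauchy stress σ_s = Je^{-1} (∂W/∂Fe) Fe^T.

    Returns a dict with keys ``sigma`` (..., 3, 3, symmetrized), ``W``, ``Je``,
    ``I1``.  Raises on det Fe <= 0.
    """
    fe = np.asarray(fe, dtype=float)
    je = _dets(fe)
    if np.any(je <= 0):
        raise ValueError("det Fe must be positive (inverted element)")
    p = piola_stress_elastic(fe, g, k, isochoric=isochoric)
    sigma = np.einsum("...ij,...kj->...ik", p, fe) / je[..., None, None]
    sigma = 0.5 * (sigma + sigma.swapaxes(-1, -2))
    i1 = np.einsum("...ij,...ij->...", fe, fe)
    w = strain_energy(fe, g, k, isochoric=isochoric)
    return {"sigma": sigma, "W": w, "Je": je, "I1": i1}
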