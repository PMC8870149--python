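"""Inelastic growth kinematics: F = Fe · Fg with diagonal Fg = diag(λgx, λgy, λgz).

The per-axis growth stretch ratios obey dλga/dt = Γa · rg · λga, where the mass
growth rate rg is oxygen-limited (Michaelis–Menten in c_ox, proportional to the
normalized cell density) and the anisotropy multipliers Γa distribute growth
across the laboratory axes by a normalized exponential of the Cauchy normal
stresses: compressed directions grow less.  A is the anisotropy degree (A = 0
recovers isotropic growth, Σa Γa = 1 always).
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["GrowthState", "growth_rate", "anisotropy_multipliers", "step_growth_stretches"]


@dataclasses.dataclass
class GrowthState:
    """Per-point growth stretch ratios, shape (n, 3); λga >= 1 (growth only)."""

    lambda_g: np.ndarray

    def __post_init__(self) -> None:
        self.lambda_g = np.atleast_2d(np.asarray(self.lambda_g, dtype=float))

    @classmethod
    def identity(cls, n: int) -> "GrowthState":
        return cls(np.ones((n, 3)))

    @property
    def det_fg(self) -> np.ndarray:
        return np.prod(self.lambda_g, axis=-1)

    def fg_matrices(self) -> np.ndarray:
        n = self.lambda_g.shape[0]
        fg = np.zeros((n, 3, 3))
        fg[:, 0, 0] = self.lambda_g[:, 0]
        fg[:, 1, 1] = self.lambda_g[:, 1]
        fg[:, 2, 2] = self.lambda_g[:, 2]
        return fg


def growth_rate(c_ox, t_cel, k1: float, k2: float):
    """Oxygen-limited mass growth rate rg = k1 c_ox/(k2 + c_ox) T_cel  [1/day]."""
    c = np.asarray(c_ox, dtype=float)
    t = np.asarray(t_cel, dtype=float)
    if np.any(c < 0) or np.any(t < 0):
        raise ValueError("oxygen concentration and cell density must be non-negative")
    if k1 < 0 or k2 <= 0:
        raise ValueError("k1 must be >= 0 and k2 > 0")
    return k1 * c / (k2 + c) * t


def anisotropy_multipliers(sigma_diag, a: float, k: float):
    """Normalized-exponential growth multipliers Γa = exp(A σaa/k) / ΓΣ.

    ``sigma_diag`` holds the three Cauchy normal stresses (lab frame), shape
    (..., 3).  Computed with max-subtraction so |A σ/k| up to many hundreds
    stays overflow-safe; Σa Γa = 1 to round-off.
    """
    if k <= 0:
        raise ValueError("bulk modulus k must be positive")
    if a < 0:
        raise ValueError("anisotropy degree A must be non-negative")
    s = np.asarray(sigma_diag, dtype=float)
    z = a * s / k
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def step_growth_stretches(state: GrowthState, r_g, gamma, dt: float) -> GrowthState:
    """Exact exponential update λga <- λga · exp(Γa rg dt) at frozen (Γ, rg).

    ``r_g`` broadcasts over points; ``gamma`` has shape (..., 3).  For Γ = 1/3
    this reproduces the isotropic law d(det Fg)/dt = rg det Fg exactly, and for
    any Γ the volume factor det Fg gains exp(rg dt) per step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    r = np.asarray(r_g, dtype=float)
    if np.any(r < 0):
        raise ValueError("growth rate must be non-negative")
    g = np.asarray(gamma, dtype=float)
    lam = state.lambda_g * np.exp(g * r[..., None] * dt)
    return GrowthState(np.maximum(lam, 1.0))
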