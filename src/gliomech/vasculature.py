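"""Stress-induced vessel compression and functional vascular density.

Growth-generated compressive bulk solid stress squeezes intratumoral vessels;
the functional vascular density scales with the diameter ratio,
S_v = (d/d₀)·S_v0.  The stress→diameter law is pluggable; the default is a
single-parameter exponential half-compression law
d/d₀ = exp(−ln2 · max(0, −σ_bulk)/σ_half): monotone, bounded in (0, 1], equal
to 1/2 at one half-compression stress σ_half of compression, and exactly 1
wherever the bulk stress is tensile or zero.
"""

from __future__ import annotations

import numpy as np

__all__ = ["vessel_compression", "functional_density", "linear_collapse_law"]

_LN2 = float(np.log(2.0))


def vessel_compression(sigma_bulk, sigma_half: float, law=None):
    """Vessel diameter ratio d/d₀ ∈ [0, 1] from bulk solid stress (Pa).

    Only compressive (negative) bulk stress compresses vessels.  ``law`` may
    replace the default exponential with any callable mapping the non-negative
    compressive magnitude (Pa) and σ_half to a ratio in [0, 1].
    """
    if sigma_half <= 0:
        raise ValueError("sigma_half must be positive")
    compression = np.maximum(0.0, -np.asarray(sigma_bulk, dtype=float))
    if law is None:
        ratio = np.exp(-_LN2 * compression / sigma_half)
    else:
        ratio = np.asarray(law(compression, sigma_half), dtype=float)
        if np.any(ratio < 0) or np.any(ratio > 1):
            raise ValueError("compression law must return ratios in [0, 1]")
    return ratio


def linear_collapse_law(compression, sigma_half):
    """Alternative piecewise-linear law: full collapse at 2 σ_half."""
    return np.clip(1.0 - 0.5 * np.asarray(compression, dtype=float) / sigma_half, 0.0, 1.0)


def functional_density(d_ratio, s_v0):
    """Functional vascular density S_v = (d/d₀)·S_v0 (exact product)."""
    d = np.asarray(d_ratio, dtype=float)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("d_ratio must lie in [0, 1]")
    s0 = np.asarray(s_v0, dtype=float)
    if np.any(s0 < 0):
        raise ValueError("S_v0 must be non-negative")
    return d * s0
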