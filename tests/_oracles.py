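"""Independent extended-precision oracles used by the test suite.

These re-derive published quantities with sympy at high precision so the
package implementation can be checked against an independent evaluation
rather than against itself.
"""

import sympy as sp

# Hydrodynamic resistance series coefficients (identical published constants;
# the *evaluation* here is an independent 50-digit implementation, including
# the leading (9 pi^2 sqrt(2) / 4)(1 - lam)^(-5/2) singular factor).
_A = (sp.Rational(-73, 60), sp.Rational(77293, 50400),
      sp.Rational(-225083, 10000), sp.Rational(-56117, 10000),
      sp.Rational(-3363, 10000), sp.Rational(-1216, 1000),
      sp.Rational(1647, 1000))
_B = (sp.Rational(7, 60), sp.Rational(-2227, 50400),
      sp.Rational(40180, 10000), sp.Rational(-39788, 10000),
      sp.Rational(-19215, 10000), sp.Rational(4392, 1000),
      sp.Rational(5006, 1000))

_PREC = 50


def _resistance_exact(lam, coeff):
    lam = sp.Rational(lam) if not isinstance(lam, sp.Basic) else lam
    eps = 1 - lam
    lead = (sp.Rational(9, 4) * sp.pi ** 2 * sp.sqrt(2) * eps ** sp.Rational(-5, 2)
            * (1 + coeff[0] * eps + coeff[1] * eps ** 2))
    poly = sum(coeff[n + 2] * lam ** n for n in range(5))
    return lead + poly


def hindrance_exact(lam):
    """(H, w, sigma_f) at drug/pore radius ratio lam, as 50-digit floats."""
    lam = sp.Rational(str(lam))
    f = (1 - lam) ** 2
    kt = _resistance_exact(lam, _A)
    ks = _resistance_exact(lam, _B)
    h = 6 * sp.pi * f / kt
    w = f * (2 - f) * ks / (2 * kt)
    return (float(sp.N(h, _PREC)), float(sp.N(w, _PREC)),
            float(sp.N(1 - w, _PREC)))
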