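"""Linear stability analysis: Jacobians, Routh-Hurwitz predicates, oracles.

Because the delayed FT channel enters the equilibrium equations at its
steady value, stability of the full model is delay-independent and is
decided by the spectrum of the ordinary 6x6 Jacobian.  The FT row is
autonomous and linear, so the characteristic polynomial factors as
``(lambda + d6) * P(lambda)`` with ``P`` a quintic; the quintic
coefficients are obtained numerically by deflating the factored root
``lambda = -d6`` and fed to the Routh-Hurwitz predicate.  An eigenvalue
oracle cross-checks every verdict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BoundViolationError, DomainError
from .kinetics import InputSignals, MotifParams, ParameterSet

#: Any Routh-Hurwitz expression within this distance of zero (relative to
#: its own scale) is classed as marginal rather than strictly decided.
MARGINAL_BAND = 1e-9


@dataclass
class StabilityReport:
    """Characteristic coefficients, condition truth values and verdict."""

    coefficients: tuple[float, ...]
    conditions: dict
    eigenvalues: np.ndarray | None
    verdict: str  # 'stable' | 'unstable' | 'marginal'
    steady_state: np.ndarray | None = None


def jacobian_full(x, p: ParameterSet, inputs: InputSignals) -> np.ndarray:
    """Analytic 6x6 Jacobian of the full model at a (steady) state.

    The delayed FT argument is evaluated at its equilibrium value, which
    is exact for the delay-independent stability question treated here.
    Row/column order is AP1, LFY, SOC1, FD, AGL24, FT.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (6,):
        raise DomainError("state must have 6 components")
    b, K, d, n = p.beta, p.K, p.d, p.n
    x7, x8, _, _ = inputs(0.0)
    x1, x2, x3, x4, x5, x6 = x

    def dgam(xv, Kj, m=1):
        # d/dx [x^m / (x^m + K^m)] = m K^m x^(m-1) / (x^m + K^m)^2
        return m * Kj**m * xv ** (m - 1) / (xv**m + Kj**m) ** 2

    k_m = (K[10] / (x7 + K[10])) * (K[11] / (x8 + K[11]))
    J = np.zeros((6, 6))
    J[0, 0] = -d[0]
    J[0, 1] = b[0] * dgam(x2, K[0], n)
    J[0, 3] = b[1] * dgam(x4, K[1])
    J[0, 5] = b[2] * dgam(x6, K[2])
    J[1, 0] = b[3] * dgam(x1, K[3])
    J[1, 1] = -d[1]
    J[1, 2] = b[4] * dgam(x3, K[4])
    J[1, 4] = b[5] * dgam(x5, K[5])
    J[2, 2] = b[6] * dgam(x3, K[6]) * k_m - d[2]
    J[2, 3] = b[8] * dgam(x4, K[8]) * (x6 / (x6 + K[9])) * k_m
    J[2, 4] = b[7] * dgam(x5, K[7]) * k_m
    J[2, 5] = b[8] * (x4 / (x4 + K[8])) * dgam(x6, K[9]) * k_m
    J[3, 1] = b[9] * dgam(x2, K[12])
    J[3, 3] = -d[3]
    J[4, 2] = b[10] * dgam(x3, K[13])
    J[4, 4] = -d[4]
    J[5, 5] = -d[5]
    return J


def characteristic_quintic(J: np.ndarray, d6: float, tol=1e-9) -> tuple[float, ...]:
    """Coefficients (a1..a5) of the quintic factor of ``det(lambda I - J)``.

    The degree-6 characteristic polynomial is deflated by its structural
    root ``lambda = -d6``; a deflation remainder above ``tol`` (relative)
    signals that the supplied matrix lacks the autonomous FT row.
    """
    coeffs = np.poly(J)  # monic, degree 6, descending powers
    quotient, remainder = np.polydiv(coeffs, np.array([1.0, d6]))
    scale = np.max(np.abs(coeffs))
    if abs(remainder[0]) > tol * max(scale, 1.0):
        raise DomainError("characteristic polynomial has no (lambda + d6) factor")
    return tuple(quotient[1:])  # drop the leading 1


def _verdict_from_margins(margins: list[float], scale: float) -> str:
    """stable iff every margin > 0; marginal if any sits in the tie band."""
    band = MARGINAL_BAND * max(scale, 1.0)
    if any(m < -band for m in margins):
        return "unstable"
    if any(abs(m) <= band for m in margins):
        return "marginal"
    return "stable"


def routh_hurwitz_quintic(a: tuple[float, ...] | list[float]) -> StabilityReport:
    """Routh-Hurwitz verdict for a monic quintic with coefficients a1..a5.

    Conditions: all ``a_i > 0``;
    ``a1 a2 a3 + a1 a5 > a3^2 + a1^2 a4``; and
    ``(a1 a4 - a5)(a1 a2 a3 + a1 a5 - a3^2 - a1^2 a4) > a5 (a1 a2 - a3)^2``.
    """
    a1, a2, a3, a4, a5 = (float(v) for v in a)
    h1 = a1 * a2 * a3 + a1 * a5 - a3**2 - a1**2 * a4
    h2 = (a1 * a4 - a5) * h1 - a5 * (a1 * a2 - a3) ** 2
    conditions = {
        "a_i_positive": all(v > 0 for v in (a1, a2, a3, a4, a5)),
        "second_hurwitz": h1 > 0,
        "third_hurwitz": h2 > 0,
    }
    scale = max(abs(v) for v in (a1, a2, a3, a4, a5, h1, h2))
    verdict = _verdict_from_margins([a1, a2, a3, a4, a5, h1, h2], scale)
    return StabilityReport(coefficients=(a1, a2, a3, a4, a5), conditions=conditions,
                           eigenvalues=None, verdict=verdict)


def routh_hurwitz_cubic(a: tuple[float, ...] | list[float]) -> StabilityReport:
    """Routh-Hurwitz verdict for a monic cubic: ``a_i > 0`` and ``a1 a2 > a3``."""
    a1, a2, a3 = (float(v) for v in a)
    h1 = a1 * a2 - a3
    conditions = {
        "a_i_positive": all(v > 0 for v in (a1, a2, a3)),
        "hurwitz": h1 > 0,
    }
    scale = max(abs(v) for v in (a1, a2, a3, h1))
    verdict = _verdict_from_margins([a1, a2, a3, h1], scale)
    return StabilityReport(coefficients=(a1, a2, a3), conditions=conditions,
                           eigenvalues=None, verdict=verdict)


def spectral_verdict(eigenvalues, band=1e-8) -> str:
    """Oracle verdict from the sign of the largest real part."""
    top = float(np.max(np.real(eigenvalues)))
    if top > band:
        return "unstable"
    if top < -band:
        return "stable"
    return "marginal"


def full_model_stability(steady_state, p: ParameterSet,
                         inputs: InputSignals) -> StabilityReport:
    """Routh-Hurwitz report for a full-model equilibrium, with eigen oracle."""
    x = np.asarray(getattr(steady_state, "x", steady_state), dtype=float)
    J = jacobian_full(x, p, inputs)
    a = characteristic_quintic(J, p.d[5])
    report = routh_hurwitz_quintic(a)
    report.eigenvalues = np.linalg.eigvals(J)
    report.steady_state = x
    return report


def motif_stability(x2: float, mp: MotifParams) -> str:
    """Stability of a motif equilibrium from its LFY level.

    The trivial state is always stable (eigenvalues -d1, -d2).  A positive
    equilibrium is stable iff
    ``x2^(n-1) > n d1 d2 K1^n K4 / (beta1 beta4 F1 F2)`` (strictly),
    marginal at equality (the saddle-node), and must respect the
    existence bound ``x2 < beta4 F1 / d2``.
    """
    if x2 < 0:
        raise DomainError("x2 must be non-negative")
    if x2 == 0:
        return "stable"
    if x2 >= mp.x2_upper_bound:
        raise BoundViolationError(
            f"x2 = {x2:g} violates the bound x2 < {mp.x2_upper_bound:g}")
    lhs = x2 ** (mp.n - 1)
    rhs = (mp.n * mp.d1 * mp.d2 * mp.K1**mp.n * mp.K4
           / (mp.beta1 * mp.beta4 * mp.F1 * mp.F2))
    margin = lhs - rhs
    band = MARGINAL_BAND * max(abs(lhs), abs(rhs), 1.0)
    if margin > band:
        return "stable"
    if margin < -band:
        return "unstable"
    return "marginal"


def jacobian_motif(x, mp: MotifParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of the AP1-LFY motif."""
    x1, x2 = x
    n = mp.n
    J = np.array([
        [-mp.d1,
         n * mp.beta1 * mp.K1**n * mp.F2 * x2 ** (n - 1) / (x2**n + mp.K1**n) ** 2],
        [mp.beta4 * mp.K4 * mp.F1 / (x1 + mp.K4) ** 2, -mp.d2],
    ])
    return J
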