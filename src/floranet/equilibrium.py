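"""Steady-state solvers for the full network and the AP1-LFY motif.

The full six-gene system at constant inputs has its FT level fixed directly
by the leaf inputs (``x6 = u``), FD and AGL24 slaved to LFY and SOC1, and
the remaining coupling reduced here to a scalar problem in the SOC1 level:
for a trial SOC1 value the LFY balance is solved (AP1 is explicit in LFY),
and the SOC1 production-degradation residual is bracketed on a dense
logarithmic grid and polished with Brent's method.  Every candidate is
verified against the full right-hand side, so no symbolic elimination of
the underlying 17th-degree polynomial is needed.

The two-gene motif admits a closed-form reduction: positive equilibria of
LFY are roots of the cubic ``(w1 + w2 F2) x2^3 - w3 F1 F2 x2^2 + w4 = 0``
(Descartes: zero or two positive roots), from which AP1, FD and AGL24
follow by explicit equilibrium relations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import BoundViolationError, ModeError
from .kinetics import InputSignals, MotifParams, ParameterSet
from .models import full_rhs

logger = logging.getLogger(__name__)

#: |discriminant| below this fraction of omega4^2 is reported as a double root.
DOUBLE_ROOT_TOL = 1e-6


@dataclass
class SteadyState:
    """An equilibrium candidate with its full-system residual."""

    x: np.ndarray
    residual: float
    positive: bool
    multiplicity: str = "simple"

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)


@dataclass
class CubicAnalysis:
    """Coefficients, discriminant and root census of the motif cubic."""

    a: float          # omega1 + omega2*F2   (cubic term)
    b: float          # -omega3*F1*F2        (quadratic term)
    c: float          # 0                    (linear term)
    d: float          # omega4               (constant term)
    discriminant: float
    roots: np.ndarray             # all real roots, ascending
    positive_roots: np.ndarray    # the 0 or 2 positive ones, ascending
    multiplicity: str             # 'simple' | 'double' | 'none'
    F1: float
    F2: float


def steady_input_constants(p: ParameterSet, inputs: InputSignals):
    """(u, kappa11*kappa12) — the two input-dependent equilibrium constants."""
    x7, x8, x9, x10 = inputs.constants()
    k_m = (p.K[10] / (x7 + p.K[10])) * (p.K[11] / (x8 + p.K[11]))
    u = p.beta[11] * (p.K[14] / (x9 + p.K[14])) * (p.K[15] / (x10 + p.K[15])) / p.d[5]
    return u, k_m


def solve_full_steady_state(p: ParameterSet, inputs: InputSignals,
                            grid=(1e-6, 1e6, 2000), residual_tol=1e-8):
    """All non-negative equilibria of the full model at constant inputs.

    ``grid`` is ``(lo, hi, points)`` for the logarithmic SOC1 bracketing
    grid.  Returns a list of :class:`SteadyState`, each with relative
    full-system residual below ``residual_tol``; an empty list (with a
    diagnostic log record) if no bracket is found.
    """
    if not inputs.is_constant:
        raise ModeError("steady states are defined for constant inputs only")
    b, K, d = p.beta, p.K, p.d
    u, k_m = steady_input_constants(p, inputs)

    def x4_of_x2(x2):
        return b[9] * x2 / (x2 + K[12]) / d[3]

    def x5_of_x3(x3):
        return b[10] * x3 / (x3 + K[13]) / d[4]

    def x1_of_x2(x2):
        x2n = x2**p.n
        x4 = x4_of_x2(x2)
        return (b[0] * x2n / (x2n + K[0] ** p.n) + b[1] * x4 / (x4 + K[1])
                + b[2] * u / (u + K[2])) / d[0]

    x2_hi = (b[3] + b[4] + b[5]) / d[1] + 1.0

    def x2_of_x3(x3):
        # LFY balance at fixed SOC1; the net flux is negative at 0 and
        # positive at x2_hi, so a root always exists.
        x5 = x5_of_x3(x3)
        const = b[4] * x3 / (x3 + K[4]) + b[5] * x5 / (x5 + K[5])

        def h(x2):
            x1 = x1_of_x2(x2)
            return d[1] * x2 - b[3] * x1 / (x1 + K[3]) - const

        return brentq(h, 0.0, x2_hi, xtol=1e-13, rtol=8.9e-16)

    def soc1_residual(x3):
        x2 = x2_of_x3(x3)
        x4 = x4_of_x2(x2)
        x5 = x5_of_x3(x3)
        production = (b[6] * x3 / (x3 + K[6]) + b[7] * x5 / (x5 + K[7])
                      + b[8] * (x4 / (x4 + K[8])) * (u / (u + K[9]))) * k_m
        return d[2] * x3 - production

    lo, hi, n_pts = grid
    x3_grid = np.logspace(np.log10(lo), np.log10(hi), int(n_pts))
    vals = np.array([soc1_residual(x3) for x3 in x3_grid])
    states = []
    for i in range(len(x3_grid) - 1):
        if np.sign(vals[i]) * np.sign(vals[i + 1]) < 0:
            x3 = brentq(soc1_residual, x3_grid[i], x3_grid[i + 1], xtol=1e-12)
            x2 = x2_of_x3(x3)
            x = np.array([x1_of_x2(x2), x2, x3, x4_of_x2(x2), x5_of_x3(x3), u])
            rhs = full_rhs(0.0, x, x[5], p, inputs)
            rel = float(np.linalg.norm(rhs) / max(np.linalg.norm(x), 1.0))
            if rel < residual_tol:
                states.append(SteadyState(x=x, residual=rel, positive=bool(np.all(x > 0))))
    if not states:
        logger.warning("no SOC1 bracket found on (%g, %g); no equilibrium returned", lo, hi)
    return states


def motif_cubic(mp: MotifParams) -> CubicAnalysis:
    """Root analysis of the motif steady-state cubic (cooperativity 3).

    The discriminant ``w4*(4*(w3*F1*F2)^3 - 27*(w1 + w2*F2)^2*w4)`` is
    non-negative exactly when two positive equilibria exist (counting a
    saddle-node double root once each).
    """
    if mp.n != 3:
        raise ModeError("the cubic analysis requires Hill cooperativity n = 3")
    a = mp.omega1 + mp.omega2 * mp.F2
    bq = -mp.omega3 * mp.F1 * mp.F2
    dd = mp.omega4
    disc = discriminant(mp)
    # the two discriminant terms set its natural magnitude; a zero crossing
    # is only meaningful relative to that scale
    disc_scale = mp.omega4 * (4 * (mp.omega3 * mp.F1 * mp.F2) ** 3
                              + 27 * a**2 * mp.omega4)
    roots = np.roots([a, bq, 0.0, dd])
    order = np.argsort(roots.real)
    if abs(disc) < DOUBLE_ROOT_TOL * disc_scale:
        # saddle-node: the (near-)coincident pair has the largest real
        # parts, whether it is two close reals or a tight conjugate pair
        double = float(np.mean(roots.real[order][1:]))
        real = np.array([roots.real[order][0], double, double])
        positive = np.array([double, double])
        multiplicity = "double"
    else:
        real = np.sort(roots.real[np.abs(roots.imag) <= 1e-9 * np.max(np.abs(roots))])
        positive = real[real > 0]
        multiplicity = "simple" if len(positive) == 2 else "none"
    return CubicAnalysis(a=a, b=bq, c=0.0, d=dd, discriminant=disc, roots=real,
                         positive_roots=positive, multiplicity=multiplicity,
                         F1=mp.F1, F2=mp.F2)


def discriminant(mp: MotifParams) -> float:
    """Cubic discriminant (up to the conventional positive factor)."""
    w1, w2, w3, w4 = mp.omega1, mp.omega2, mp.omega3, mp.omega4
    return w4 * (4 * (w3 * mp.F1 * mp.F2) ** 3 - 27 * (w1 + w2 * mp.F2) ** 2 * w4)


def map_equilibrium_relations(x2: float, mp: MotifParams,
                              p: ParameterSet | None = None,
                              x3: float | None = None) -> dict:
    """Companion equilibrium components from an LFY level.

    AP1 is recovered by inverting the LFY balance of the motif,
    ``x1 = d2*x2*K4 / (beta4*F1 - d2*x2)``, valid under the existence
    bound ``x2 < beta4*F1/d2``.  Given the registry ``p``, the slaved FD
    level follows from LFY; given additionally a SOC1 level ``x3``, the
    slaved AGL24 level follows from SOC1.
    """
    out = {}
    if x2 == 0:
        out["x1"] = 0.0
    else:
        denom = mp.beta4 * mp.F1 - mp.d2 * x2
        if denom <= 0:
            raise BoundViolationError(
                f"x2 = {x2:g} violates the bound x2 < beta4*F1/d2 = {mp.x2_upper_bound:g}")
        out["x1"] = mp.d2 * x2 * mp.K4 / denom
    if p is not None:
        out["x4"] = p.beta[9] * x2 / (x2 + p.K[12]) / p.d[3]
        if x3 is not None:
            out["x5"] = p.beta[10] * x3 / (x3 + p.K[13]) / p.d[4]
    return out
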