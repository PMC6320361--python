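"""Saddle-node analysis and flowering predictions for the AP1-LFY motif.

The motif's positive equilibria exist exactly where the steady-state cubic
has a positive discriminant; the discriminant's zero in the FT / FT-FD
action constants (F1, F2) locates the saddle-node at which the stable
"flowering" state and the unstable threshold state are born.  Three
one-parameter scenarios are analysed: action on AP1 only (F1 = 1), action
on LFY only (F2 = 1), and equal action on both (F1 = F2).

"Flowering" of a trajectory is scored by AP1 first reaching a fixed
fraction (default 50%) of the upper stable equilibrium; the 1.25 nM
initial-LFY threshold reported by :func:`flowering_threshold` is
insensitive to that convention because sub-threshold trajectories collapse
to the trivial state instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .equilibrium import discriminant, map_equilibrium_relations, motif_cubic
from .errors import BoundViolationError, BracketError, ConfigurationError, DomainError
from .kinetics import MINUTES_PER_DAY, MotifParams
from .models import motif_rhs
from .stability import motif_stability

SCENARIOS = ("subsystem1", "subsystem2", "subsystem3")

#: Relative closeness (with an absolute floor in nM) deciding that an
#: endpoint has reached a steady state.
BASIN_EPS_REL = 0.01
BASIN_EPS_FLOOR = 0.01


@dataclass
class BifurcationResult:
    """Critical F value at which the positive equilibria appear."""

    scenario: str
    critical_F: float
    bracket: tuple[float, float]
    tolerance: float
    multiplicity: str


@dataclass
class PhasePortrait:
    """Nullclines, classified equilibria and basin-labelled trajectories."""

    nullclines: dict
    steady_states: list
    trajectories: list


def find_critical_F(scenario: str, mp: MotifParams,
                    bracket=(1e-4, 10.0), tol=1e-7) -> BifurcationResult:
    """Solve the discriminant condition for the scenario's free F constant.

    ``subsystem1`` fixes F1 = 1 and solves for F2; ``subsystem2`` fixes
    F2 = 1 and solves for F1; ``subsystem3`` ties F1 = F2 = F.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")

    def disc_of(F):
        if scenario == "subsystem1":
            m = mp.with_F(F1=1.0, F2=F)
        elif scenario == "subsystem2":
            m = mp.with_F(F1=F, F2=1.0)
        else:
            m = mp.with_F(F1=F, F2=F)
        return discriminant(m)

    lo, hi = bracket
    if disc_of(lo) * disc_of(hi) > 0:
        raise BracketError(f"discriminant does not change sign on ({lo:g}, {hi:g})")
    # plain bisection to the requested absolute tolerance in F
    flo = disc_of(lo)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        fmid = disc_of(mid)
        if fmid == 0:
            lo = hi = mid
            break
        if flo * fmid < 0:
            hi = mid
        else:
            lo, flo = mid, fmid
    crit = 0.5 * (lo + hi)
    return BifurcationResult(scenario=scenario, critical_F=crit,
                             bracket=bracket, tolerance=tol, multiplicity="double")


def nullclines(mp: MotifParams, x2: np.ndarray) -> dict:
    """The two sides of the LFY equilibrium relation, sampled over ``x2``.

    ``lhs`` is the AP1-mediated production curve
    ``(beta1 F2 / d1) * x2^n/(x2^n + K1^n)``; ``rhs`` is the decay-balance
    curve ``d2 K4 x2 / (beta4 F1 - d2 x2)``, defined below the existence
    bound.  Intersections are the motif's positive equilibria; the sampled
    range is truncated (with a warning in the result) if it exceeds the
    bound.
    """
    x2 = np.asarray(x2, dtype=float)
    bound = mp.x2_upper_bound
    truncated = bool(np.any(x2 >= bound))
    x2 = x2[x2 < bound]
    lhs = mp.beta1 * mp.F2 / mp.d1 * x2**mp.n / (x2**mp.n + mp.K1**mp.n)
    rhs = mp.d2 * mp.K4 * x2 / (mp.beta4 * mp.F1 - mp.d2 * x2)
    diff = lhs - rhs
    intersections = []
    for i in range(len(x2) - 1):
        if np.sign(diff[i]) * np.sign(diff[i + 1]) < 0:
            f = lambda v: (mp.beta1 * mp.F2 / mp.d1 * v**mp.n / (v**mp.n + mp.K1**mp.n)
                           - mp.d2 * mp.K4 * v / (mp.beta4 * mp.F1 - mp.d2 * v))
            intersections.append(brentq(f, x2[i], x2[i + 1], xtol=1e-10))
    return {"x2": x2, "lhs": lhs, "rhs": rhs,
            "intersections": np.array(intersections), "truncated": truncated}


def classified_states(mp: MotifParams) -> list:
    """All motif equilibria (trivial first) with stability labels."""
    out = [((0.0, 0.0), "stable")]
    analysis = motif_cubic(mp)
    for x2 in analysis.positive_roots:
        x1 = map_equilibrium_relations(float(x2), mp)["x1"]
        out.append(((x1, float(x2)), motif_stability(float(x2), mp)))
    return out


def stable_flowering_state(mp: MotifParams):
    """The upper (stable, positive) equilibrium, or None when absent."""
    best = None
    for (x1, x2), verdict in classified_states(mp):
        if verdict == "stable" and x2 > 0 and (best is None or x2 > best[1]):
            best = (x1, x2)
    return best


def _integrate(mp, initial, horizon_days, events=None):
    return solve_ivp(motif_rhs, (0.0, horizon_days * MINUTES_PER_DAY),
                     np.asarray(initial, dtype=float), args=(mp,),
                     method="LSODA", rtol=1e-8, atol=1e-10, events=events)


def flowering_time(initial, mp: MotifParams, horizon_days=100.0,
                   threshold_frac=0.5):
    """Days until AP1 first reaches ``threshold_frac`` of the stable state.

    Returns ``None`` (no flowering) when AP1 never reaches the threshold
    within the horizon.  A configuration without a positive stable state
    cannot flower at all and is rejected.
    """
    if horizon_days <= 0:
        raise DomainError("horizon must be positive")
    target = stable_flowering_state(mp)
    if target is None:
        raise ConfigurationError("no positive stable state exists at these F values")
    threshold = threshold_frac * target[0]

    def crossing(t, x, *_):
        return x[0] - threshold

    crossing.terminal = True
    crossing.direction = 1
    sol = _integrate(mp, initial, horizon_days, events=crossing)
    if sol.t_events[0].size == 0:
        return None
    return float(sol.t_events[0][0]) / MINUTES_PER_DAY


def flowering_threshold(mp: MotifParams, ap1_init=0.24,
                        lfy_grid=None, horizon_days=100.0,
                        threshold_frac=0.5):
    """Smallest initial LFY on a grid for which flowering occurs.

    The default grid spans 1.20-1.30 nM in 0.01 nM steps, with the initial
    AP1 just above its own threshold.  Returns ``(lfy_threshold, results)``
    where ``results`` maps each grid value to its flowering time (days) or
    ``None``; ``lfy_threshold`` is ``None`` if nothing on the grid flowers.
    """
    if lfy_grid is None:
        lfy_grid = np.round(np.arange(1.20, 1.301, 0.01), 10)
    results = {}
    threshold = None
    for lfy0 in lfy_grid:
        ft = flowering_time((ap1_init, float(lfy0)), mp, horizon_days, threshold_frac)
        results[float(lfy0)] = ft
        if ft is not None and threshold is None:
            threshold = float(lfy0)
    return threshold, results


def classify_basin(initial, mp: MotifParams, horizon_days=100.0) -> str:
    """Label of the attractor the trajectory reaches: trivial | flowering.

    The endpoint must land within 1% (relative, 0.01 nM floor) of a stable
    state; otherwise the point is reported ``unresolved`` rather than
    guessed.
    """
    sol = _integrate(mp, initial, horizon_days)
    end = sol.y[:, -1]
    labels = []
    for (x1, x2), verdict in classified_states(mp):
        if verdict != "stable":
            continue
        ref = np.array([x1, x2])
        tol = np.maximum(BASIN_EPS_REL * np.abs(ref), BASIN_EPS_FLOOR)
        if np.all(np.abs(end - ref) <= tol):
            labels.append("trivial" if x2 == 0 else "flowering")
    if len(labels) == 1:
        return labels[0]
    return "unresolved"


def saddle_point(mp: MotifParams):
    """The unstable positive equilibrium (threshold state), or None."""
    for (x1, x2), verdict in classified_states(mp):
        if verdict == "unstable":
            return (x1, x2)
    return None
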