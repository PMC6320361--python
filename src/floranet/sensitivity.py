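"""Local parameter sensitivity of the full flowering model.

Normalised sensitivities ``S_q = (q / y) * dy/dq`` are estimated by
central finite differences at a configurable relative perturbation
(default 1%), for a scalar output functional of the parameter set — by
default the steady-state AP1 level, the quantity that marks commitment to
flowering.  Parameters whose perturbation destroys the positive
equilibrium are flagged instead of ranked.

Flowering has two complementary scalar signatures: *how much* AP1 the
committed state carries (the equilibrium level) and *how fast* the
commitment happens (the onset time at which AP1 first reaches half its
equilibrium).  They respond to disjoint parameter groups — the level is
set by the AP1 balance (d1, beta1; the LFY input Hill term is saturated
at equilibrium, hiding K1), while the onset time is shaped by the
unsaturated transient (K1 and the LFY production constants beta4, K4,
beta5, K5; d1 cancels from the timing because it rescales the trajectory
and its target alike).  :func:`flowering_sensitivity` therefore ranks
parameters by their largest influence across both outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .equilibrium import solve_full_steady_state
from .errors import ConfigurationError
from .kinetics import MINUTES_PER_DAY, InputSignals, ParameterSet
from .models import full_rhs

#: Default initial state (AP1, LFY, SOC1, FD, AGL24, FT in nM) for
#: transient functionals: the post-germination expression levels.
GERMINATION_STATE = (0.00056, 0.68, 33.3, 0.431, 27.69, 0.00056)

#: All kinetic constants eligible for ranking (the delay does not enter
#: the equilibrium problem).
KINETIC_NAMES = tuple(
    [f"beta{i}" for i in range(1, 13)]
    + [f"K{i}" for i in range(1, 17)]
    + [f"d{i}" for i in range(1, 7)]
)


@dataclass
class SensitivityReport:
    """Per-parameter normalised sensitivities with a |S| ranking."""

    table: pd.DataFrame          # columns: parameter, sensitivity, rank
    flagged: list[str]           # parameters where the output was lost
    perturbation: float
    output_name: str

    def top(self, k: int) -> list[str]:
        return list(self.table.sort_values("rank")["parameter"].head(k))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def steady_state_ap1(p: ParameterSet, inputs: InputSignals) -> float:
    """Default output functional: AP1 at the positive equilibrium."""
    states = [s for s in solve_full_steady_state(p, inputs) if s.positive]
    if not states:
        raise ConfigurationError("no positive steady state")
    return float(max(states, key=lambda s: s.x[0]).x[0])


def flowering_onset_time(p: ParameterSet, inputs: InputSignals,
                         initial=GERMINATION_STATE) -> float:
    """Days until AP1 first reaches half its equilibrium level.

    Integrated without the transport delay: the delay shifts the onset by
    a parameter-independent constant and cancels from local sensitivities.
    """
    target = 0.5 * steady_state_ap1(p, inputs)

    def rhs(t, x):
        return full_rhs(t, x, x[5], p, inputs)

    def crossing(t, x):
        return x[0] - target

    crossing.terminal = True
    crossing.direction = 1
    sol = solve_ivp(rhs, (0.0, 100.0 * MINUTES_PER_DAY),
                    np.asarray(initial, dtype=float), method="LSODA",
                    rtol=1e-8, atol=1e-10, events=crossing)
    if sol.t_events[0].size == 0:
        raise ConfigurationError("AP1 never reaches half its equilibrium level")
    return float(sol.t_events[0][0]) / MINUTES_PER_DAY


def local_sensitivity(p: ParameterSet, inputs: InputSignals, output=None,
                      rel_perturbation: float = 0.01,
                      parameters=KINETIC_NAMES) -> SensitivityReport:
    """Central-difference normalised sensitivities of ``output`` at ``p``."""
    if output is None:
        output = steady_state_ap1
        output_name = "steady_state_AP1"
    else:
        output_name = getattr(output, "__name__", "custom")
    base = output(p, inputs)
    rows = []
    flagged = []
    values = p.to_dict()
    for name in parameters:
        q = values[name]
        dq = rel_perturbation * q
        try:
            y_hi = output(p.with_values(**{name: q + dq}), inputs)
            y_lo = output(p.with_values(**{name: q - dq}), inputs)
        except Exception:
            flagged.append(name)
            continue
        sens = (q / base) * (y_hi - y_lo) / (2 * dq)
        rows.append((name, sens))
    table = pd.DataFrame(rows, columns=["parameter", "sensitivity"])
    table["rank"] = table["sensitivity"].abs().rank(ascending=False, method="first").astype(int)
    table = table.sort_values("rank").reset_index(drop=True)
    return SensitivityReport(table=table, flagged=flagged,
                             perturbation=rel_perturbation, output_name=output_name)


def flowering_sensitivity(p: ParameterSet, inputs: InputSignals,
                          rel_perturbation: float = 0.01,
                          parameters=KINETIC_NAMES) -> SensitivityReport:
    """Joint ranking over the equilibrium AP1 level and the onset time.

    Each parameter is scored by its largest normalised sensitivity across
    the two flowering signatures; see the module docstring for why a
    single functional cannot surface both parameter groups.
    """
    level = local_sensitivity(p, inputs, output=None,
                              rel_perturbation=rel_perturbation,
                              parameters=parameters)
    timing = local_sensitivity(p, inputs, output=flowering_onset_time,
                               rel_perturbation=rel_perturbation,
                               parameters=parameters)
    merged = level.table.merge(timing.table, on="parameter",
                               suffixes=("_level", "_onset"))
    merged["sensitivity"] = np.maximum(merged["sensitivity_level"].abs(),
                                       merged["sensitivity_onset"].abs())
    merged["rank"] = merged["sensitivity"].rank(ascending=False, method="first").astype(int)
    table = merged[["parameter", "sensitivity", "sensitivity_level",
                    "sensitivity_onset", "rank"]].sort_values("rank").reset_index(drop=True)
    return SensitivityReport(table=table, flagged=sorted(set(level.flagged + timing.flagged)),
                             perturbation=rel_perturbation,
                             output_name="flowering_level_and_onset")
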