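"""Right-hand sides and fixed-step integrators for the flowering network.

Three nested model levels share this module:

* the full six-variable delay model (AP1, LFY, SOC1, FD, AGL24, FT) in which
  FT is produced in the leaves and acts on AP1 and SOC1 after a transport
  delay;
* the reduced three-variable model (AP1, LFY, SOC1) obtained by decoupling
  FD, AGL24 and FT at their quasi-steady values;
* the two-gene AP1-LFY motif with lumped FT / FT-FD action constants F1, F2.

The delay model is integrated by the method of steps: classical Runge-Kutta
inside each segment, with the delayed FT channel read from the stored
trajectory by linear interpolation (a constant pre-history equal to the
initial state is assumed).  With zero delay the integrator reduces exactly
to an ordinary RK4 ODE solve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DivergenceError, DomainError
from .kinetics import (
    MINUTES_PER_DAY,
    DerivedConstants,
    InputSignals,
    MotifParams,
    ParameterSet,
)

#: State ordering of the full model.
FULL_VARIABLES = ("AP1", "LFY", "SOC1", "FD", "AGL24", "FT")
REDUCED_VARIABLES = ("AP1", "LFY", "SOC1")
MOTIF_VARIABLES = ("AP1", "LFY")

#: Index of the delayed channel (FT) in the full state vector.
DELAYED_INDEX = 5

#: Divergence guard (nM): concentrations beyond this abort the integration.
STATE_CEILING = 1e9


def full_rhs(t, x, x6_delayed, p: ParameterSet, inputs: InputSignals):
    """Rates (nM/min) of the six-gene delay model.

    ``x6_delayed`` is the FT concentration a transport delay ago; it feeds
    the AP1 and SOC1 production terms.  The external inputs are evaluated
    at the (undelayed) time ``t``.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (6,):
        raise DomainError(f"full model state must have 6 components, got {x.shape}")
    b, K, d = p.beta, p.K, p.d
    x7, x8, x9, x10 = inputs(t)
    x1, x2, x3, x4, x5, x6 = x
    # Hill terms written out inline: this is the innermost loop of the
    # method-of-steps integrator.
    x2n = x2**p.n
    xdn = x6_delayed
    return np.array([
        b[0] * x2n / (x2n + K[0] ** p.n) + b[1] * x4 / (x4 + K[1])
        + b[2] * xdn / (xdn + K[2]) - d[0] * x1,
        b[3] * x1 / (x1 + K[3]) + b[4] * x3 / (x3 + K[4]) + b[5] * x5 / (x5 + K[5])
        - d[1] * x2,
        (b[6] * x3 / (x3 + K[6]) + b[7] * x5 / (x5 + K[7])
         + b[8] * (x4 / (x4 + K[8])) * (xdn / (xdn + K[9])))
        * (K[10] / (x7 + K[10])) * (K[11] / (x8 + K[11])) - d[2] * x3,
        b[9] * x2 / (x2 + K[12]) - d[3] * x4,
        b[10] * x3 / (x3 + K[13]) - d[4] * x5,
        b[11] * (K[14] / (x9 + K[14])) * (K[15] / (x10 + K[15])) - d[5] * x6,
    ])


def reduced_rhs(t, x, c: DerivedConstants, p: ParameterSet):
    """Rates (nM/min) of the reduced three-gene model (AP1, LFY, SOC1)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (3,):
        raise DomainError(f"reduced model state must have 3 components, got {x.shape}")
    x1, x2, x3 = x
    V, S = c.V, c.S
    return np.array([
        V[0] * x2**3 / (x2**3 + S[0] ** 3) + V[1] * x2 / (S[1] * x2 + S[2]) + c.U1 - p.d[0] * x1,
        V[2] * x1 / (x1 + S[3]) + V[3] * x3 / (x3 + S[4]) + V[4] * x3 / (S[5] * x3 + S[6])
        - p.d[1] * x2,
        c.U2 * V[5] * x2 / (S[7] * x2 + S[8]) + V[6] * x3 / (x3 + S[9])
        + V[7] * x3 / (S[10] * x3 + S[11]) - p.d[2] * x3,
    ])


def motif_rhs(t, x, mp: MotifParams):
    """Rates (nM/min) of the two-gene AP1-LFY motif."""
    x1, x2 = x
    x2n = x2**mp.n
    return np.array([
        mp.beta1 * x2n / (x2n + mp.K1**mp.n) * mp.F2 - mp.d1 * x1,
        mp.beta4 * x1 / (x1 + mp.K4) * mp.F1 - mp.d2 * x2,
    ])


@dataclass
class Trajectory:
    """A simulated time course: time grid (min) and state matrix (grid x vars)."""

    t: np.ndarray
    y: np.ndarray
    variables: tuple[str, ...]
    model: str
    params_id: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise DomainError("time grid must be strictly increasing")
        if self.y.shape[0] != self.t.shape[0]:
            raise DomainError("state matrix rows must match the time grid")

    @property
    def endpoint(self) -> np.ndarray:
        return self.y[-1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.y, columns=list(self.variables))
        frame.insert(0, "time_min", self.t)
        frame.insert(1, "day", self.t / MINUTES_PER_DAY)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _guard(t, x):
    if not np.all(np.isfinite(x)) or np.any(np.abs(x) > STATE_CEILING):
        raise DivergenceError(t)


def integrate_dde(rhs, history, delta, horizon, step=1.0, p=None, inputs=None,
                  delayed_index=DELAYED_INDEX, model="full"):
    """Method-of-steps RK4 integration of a single-delay system.

    ``rhs(t, x, x_delayed, p, inputs)`` must accept the delayed channel as a
    scalar.  ``history`` is the constant pre-history (and initial state) on
    ``[-delta, 0]``.  ``delta``, ``horizon`` and ``step`` are in minutes;
    ``step`` must not exceed ``delta`` unless ``delta`` is zero, so that all
    stage look-backs fall inside the already-computed grid.  With zero delay
    the delayed channel is read from the current stage state and the scheme
    is plain RK4.
    """
    if delta < 0 or step <= 0 or horizon <= 0:
        raise DomainError("delta >= 0, step > 0 and horizon > 0 required")
    if delta > 0 and step > delta:
        raise DomainError("method of steps requires step <= delta")
    x0 = np.asarray(history, dtype=float)
    n_steps = int(np.ceil(horizon / step))
    t_grid = np.empty(n_steps + 1)
    y = np.empty((n_steps + 1, x0.size))
    t_grid[0] = 0.0
    y[0] = x0

    def delayed_value(tau, i_done):
        # Constant history before t=0; linear interpolation on the stored
        # grid, located in O(1) because the grid is uniform.
        if tau <= 0:
            return x0[delayed_index]
        i0 = min(int(tau / step), i_done - 1)
        t0, t1 = t_grid[i0], t_grid[i0 + 1]
        if tau > t1:  # final shortened step
            i0 += 1
            t0, t1 = t_grid[i0], t_grid[i0 + 1]
        w = (tau - t0) / (t1 - t0)
        col = y[:, delayed_index]
        return (1 - w) * col[i0] + w * col[i0 + 1]

    def f(t, x, i_done):
        if delta == 0:
            xd = x[delayed_index]
        else:
            xd = delayed_value(t - delta, i_done)
        return rhs(t, x, xd, p, inputs)

    t = 0.0
    x = x0.copy()
    for i in range(n_steps):
        h = min(step, horizon - t)
        k1 = f(t, x, i)
        k2 = f(t + h / 2, x + h / 2 * k1, i)
        k3 = f(t + h / 2, x + h / 2 * k2, i)
        k4 = f(t + h, x + h * k3, i)
        x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t + h
        _guard(t, x)
        t_grid[i + 1] = t
        y[i + 1] = x
    variables = FULL_VARIABLES if x0.size == 6 else tuple(f"x{i+1}" for i in range(x0.size))
    return Trajectory(t_grid, y, variables, model=model)


def integrate_full(p: ParameterSet, inputs: InputSignals, initial,
                   horizon_days: float, step=1.0, delta_days=None) -> Trajectory:
    """Integrate the full six-gene model from a constant pre-history."""
    delta = (p.delta_days if delta_days is None else delta_days) * MINUTES_PER_DAY
    return integrate_dde(full_rhs, initial, delta, horizon_days * MINUTES_PER_DAY,
                         step=step, p=p, inputs=inputs, model="full")


def integrate_ode(rhs, initial, horizon, step=1.0, args=(), variables=None,
                  model="ode") -> Trajectory:
    """Plain fixed-step RK4 for the delay-free models."""
    if step <= 0 or horizon <= 0:
        raise DomainError("step > 0 and horizon > 0 required")
    x = np.asarray(initial, dtype=float)
    n_steps = int(np.ceil(horizon / step))
    t_grid = np.empty(n_steps + 1)
    y = np.empty((n_steps + 1, x.size))
    t_grid[0] = 0.0
    y[0] = x
    t = 0.0
    for i in range(n_steps):
        h = min(step, horizon - t)
        k1 = rhs(t, x, *args)
        k2 = rhs(t + h / 2, x + h / 2 * k1, *args)
        k3 = rhs(t + h / 2, x + h / 2 * k2, *args)
        k4 = rhs(t + h, x + h * k3, *args)
        x = x + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t = t + h
        _guard(t, x)
        t_grid[i + 1] = t
        y[i + 1] = x
    if variables is None:
        variables = tuple(f"x{i+1}" for i in range(x.size))
    return Trajectory(t_grid, y, tuple(variables), model=model)


def integrate_reduced(p: ParameterSet, c: DerivedConstants, initial,
                      horizon_days: float, step=1.0) -> Trajectory:
    """Integrate the reduced three-gene model."""
    return integrate_ode(reduced_rhs, initial, horizon_days * MINUTES_PER_DAY,
                         step=step, args=(c, p), variables=REDUCED_VARIABLES,
                         model="reduced")


def integrate_motif(mp: MotifParams, initial, horizon_days: float, step=1.0) -> Trajectory:
    """Integrate the two-gene motif."""
    return integrate_ode(motif_rhs, initial, horizon_days * MINUTES_PER_DAY,
                         step=step, args=(mp,), variables=MOTIF_VARIABLES,
                         model="motif")
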