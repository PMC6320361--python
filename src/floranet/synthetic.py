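"""Generators standing in for the study's experimental inputs.

The source analysis drove the network with SVP/FLC expression time courses
linearly interpolated from experiment, and explored kinetic constants
inside broad biologically admissible ranges.  This module emulates both:
piecewise-linear non-negative input signals (or constant levels, the mode
all equilibrium work assumes), and random parameter draws.  Draws are
log-uniform because the admissible ranges span several decades; a uniform
draw would almost never visit the lower decades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .kinetics import PARAMETER_RANGES, InputSignals, ParameterSet


def _default_value_ranges() -> dict:
    # Centred on the reconstructed constant levels of the shipped fixture:
    # meristem SVP/FLC are low, leaf SVP/FLC two orders of magnitude higher.
    base = InputSignals.default().constants()
    return {name: (0.0, 2.0 * level)
            for name, level in zip(InputSignals.CHANNELS, base)}


@dataclass
class GeneratorSpec:
    """Configuration of the synthetic input/parameter generators."""

    seed: int = 0
    mode: str = "constant"            # 'constant' | 'piecewise-linear'
    knots: int = 8
    horizon_days: float = 100.0
    value_ranges: dict = field(default_factory=_default_value_ranges)

    def __post_init__(self):
        if self.mode not in ("constant", "piecewise-linear"):
            raise ConfigurationError("mode must be 'constant' or 'piecewise-linear'")
        if self.knots < 1:
            raise ConfigurationError("need at least one knot")
        for name in InputSignals.CHANNELS:
            if name not in self.value_ranges:
                raise ConfigurationError(f"missing value range for {name}")
            lo, hi = self.value_ranges[name]
            if lo < 0 or hi < lo:
                raise ConfigurationError(f"empty or negative range for {name}")


def generate_inputs(spec: GeneratorSpec) -> InputSignals:
    """Draw the four input signals according to ``spec``.

    Constant mode (or a single knot) yields fixed levels drawn uniformly
    within each channel's range; piecewise-linear mode yields values drawn
    at equally spaced knot times over the horizon, linearly interpolated in
    between, hence non-negative everywhere by construction.
    """
    rng = np.random.default_rng(spec.seed)
    channels = {}
    horizon_min = spec.horizon_days * 1440.0
    for name in InputSignals.CHANNELS:
        lo, hi = spec.value_ranges[name]
        if spec.mode == "constant" or spec.knots == 1:
            channels[name] = float(rng.uniform(lo, hi))
        else:
            t = np.linspace(0.0, horizon_min, spec.knots)
            v = rng.uniform(lo, hi, size=spec.knots)
            channels[name] = (t, v)
    return InputSignals(channels)


def draw_parameters(spec: GeneratorSpec) -> ParameterSet:
    """Log-uniform draw of a full kinetic parameter set (cooperativity 3).

    Rates and abundances are drawn log-uniformly within the admissible
    ranges; the delay, whose range includes zero, is drawn uniformly.
    """
    rng = np.random.default_rng(spec.seed)

    def log_uniform(lo, hi, size):
        return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))

    beta = log_uniform(*PARAMETER_RANGES["beta"], 12)
    K = log_uniform(*PARAMETER_RANGES["K"], 16)
    d = log_uniform(*PARAMETER_RANGES["d"], 6)
    delta = float(rng.uniform(*PARAMETER_RANGES["delta"]))
    return ParameterSet(tuple(beta), tuple(K), tuple(d), delta_days=delta, n=3)
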