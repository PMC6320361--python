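"""Hill kinetics primitives and the model parameter registry.

The six-gene flowering network couples the floral meristem identity genes
AP1 and LFY to SOC1, FD, AGL24 and FT through saturating Hill activation
terms ``x^n / (x^n + K^n)`` and inhibition terms ``K / (x + K)``.  This
module holds those primitives, the kinetic-constant registry (maximum
transcription rates ``beta1..beta12`` in nM/min, half-max abundances
``K1..K16`` in nM, degradation rates ``d1..d6`` in 1/min, the FT transport
delay and the Hill cooperativity ``n``), the four external input signals
(SVP and FLC expression in meristem and leaves), and the constants of the
reduced three-gene model obtained by decoupling FD, AGL24 and FT.

All rates are per minute internally; the delay is stated in days at the
registry surface and converted with :data:`MINUTES_PER_DAY` at the model
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError, ModeError

MINUTES_PER_DAY = 1440.0

#: Biologically admissible ranges (units as in the registry).
PARAMETER_RANGES = {
    "beta": (0.001, 200.0),
    "K": (0.001, 2000.0),
    "d": (0.001, 1.0),
    "delta": (0.0, 1.0),
}


def hill_activation(x, K, n: int = 1):
    """Saturating activation ``x^n / (x^n + K^n)``.

    Parameters are a concentration ``x >= 0`` (nM), a half-max abundance
    ``K > 0`` (nM) and an integer cooperativity ``n >= 1``.  The result is a
    dimensionless fraction in [0, 1), strictly increasing in ``x``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("hill_activation requires x >= 0")
    if K <= 0:
        raise DomainError("hill_activation requires K > 0")
    if n < 1 or int(n) != n:
        raise DomainError("hill_activation requires integer n >= 1")
    xn = x**n
    out = xn / (xn + float(K) ** n)
    return out if out.ndim else float(out)


def hill_inhibition(x, K):
    """Saturating inhibition ``K / (x + K)``: a fraction in (0, 1], decreasing in x."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("hill_inhibition requires x >= 0")
    if K <= 0:
        raise DomainError("hill_inhibition requires K > 0")
    out = float(K) / (x + float(K))
    return out if out.ndim else float(out)


def _load_registry() -> dict:
    with resources.files("floranet.data").joinpath("parameters.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class ParameterSet:
    """The 35 kinetic constants of the full model plus delay and cooperativity.

    ``beta``, ``K`` and ``d`` are 1-indexed in the scientific notation
    (``beta1``..``beta12`` etc.); here they are stored as tuples and the
    named accessors accept the 1-based index: ``p.beta[0]`` is beta1.
    """

    beta: tuple[float, ...]
    K: tuple[float, ...]
    d: tuple[float, ...]
    delta_days: float = 0.5
    n: int = 3

    def __post_init__(self):
        if len(self.beta) != 12 or len(self.K) != 16 or len(self.d) != 6:
            raise ConfigurationError("need 12 beta, 16 K and 6 d values")
        if any(v <= 0 for v in (*self.beta, *self.K, *self.d)):
            raise ConfigurationError("all kinetic constants must be strictly positive")
        if self.delta_days < 0:
            raise ConfigurationError("delay must be non-negative")
        if self.n < 1 or int(self.n) != self.n:
            raise ConfigurationError("Hill cooperativity n must be an integer >= 1")

    # -- construction -----------------------------------------------------
    @classmethod
    def from_dict(cls, values: dict) -> "ParameterSet":
        beta = tuple(float(values[f"beta{i}"]) for i in range(1, 13))
        K = tuple(float(values[f"K{i}"]) for i in range(1, 17))
        d = tuple(float(values[f"d{i}"]) for i in range(1, 7))
        return cls(beta, K, d, float(values.get("delta", 0.5)), int(values.get("n", 3)))

    @classmethod
    def default(cls) -> "ParameterSet":
        """The literature parameter set shipped with the package."""
        return cls.from_dict(_load_registry()["values"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc.get("values", doc))

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        out = {f"beta{i + 1}": float(v) for i, v in enumerate(self.beta)}
        out.update({f"K{i + 1}": float(v) for i, v in enumerate(self.K)})
        out.update({f"d{i + 1}": float(v) for i, v in enumerate(self.d)})
        out["delta"] = float(self.delta_days)
        out["n"] = int(self.n)
        return out

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"values": self.to_dict()}, fh, sort_keys=False)

    # -- manipulation -----------------------------------------------------
    def with_values(self, **overrides) -> "ParameterSet":
        """Return a copy with named constants replaced (e.g. ``beta1=50``)."""
        values = self.to_dict()
        for key, val in overrides.items():
            if key not in values:
                raise ConfigurationError(f"unknown parameter {key!r}")
            values[key] = val
        return ParameterSet.from_dict(values)

    @property
    def delta_min(self) -> float:
        return self.delta_days * MINUTES_PER_DAY

    def validate_ranges(self) -> bool:
        """True iff every constant lies inside the admissible ranges."""
        lo_b, hi_b = PARAMETER_RANGES["beta"]
        lo_K, hi_K = PARAMETER_RANGES["K"]
        lo_d, hi_d = PARAMETER_RANGES["d"]
        lo_t, hi_t = PARAMETER_RANGES["delta"]
        return (
            all(lo_b <= v <= hi_b for v in self.beta)
            and all(lo_K <= v <= hi_K for v in self.K)
            and all(lo_d <= v <= hi_d for v in self.d)
            and lo_t <= self.delta_days <= hi_t
        )


class InputSignals:
    """The four external inputs x7..x10 (SVPm, FLCm, SVPl, FLCl) in nM.

    Each channel is either a non-negative constant or a piecewise-linear
    non-negative function of time (minutes), mirroring how the experimental
    expression series were linearly interpolated in the source study.
    """

    CHANNELS = ("x7", "x8", "x9", "x10")

    def __init__(self, channels: dict):
        self._channels = {}
        for name in self.CHANNELS:
            if name not in channels:
                raise ConfigurationError(f"missing input channel {name}")
            self._channels[name] = self._normalize(name, channels[name])

    @staticmethod
    def _normalize(name, spec):
        if np.isscalar(spec):
            val = float(spec)
            if val < 0:
                raise DomainError(f"input {name} must be non-negative")
            return val
        t, v = (np.asarray(a, dtype=float) for a in spec)
        if t.ndim != 1 or t.shape != v.shape or len(t) < 2:
            raise ConfigurationError(f"input {name}: need matching knot arrays")
        if np.any(np.diff(t) <= 0):
            raise ConfigurationError(f"input {name}: knot times must increase")
        if np.any(v < 0):
            raise DomainError(f"input {name} must be non-negative")
        return (t, v)

    @classmethod
    def constant(cls, x7: float, x8: float, x9: float, x10: float) -> "InputSignals":
        return cls(dict(zip(cls.CHANNELS, (x7, x8, x9, x10))))

    @classmethod
    def default(cls) -> "InputSignals":
        """Constant input levels reconstructed from the published equilibrium.

        The experimental SVP/FLC levels behind the published analysis are not
        redistributable; these synthetic constants are back-solved so that
        the model's unique positive equilibrium matches the published one
        (see ``data/inputs_synthetic.yaml``).
        """
        with resources.files("floranet.data").joinpath("inputs_synthetic.yaml").open() as fh:
            doc = yaml.safe_load(fh)
        return cls.constant(*(doc["values"][k] for k in cls.CHANNELS))

    @property
    def is_constant(self) -> bool:
        return all(np.isscalar(v) or isinstance(v, float) for v in self._channels.values())

    def constants(self) -> tuple[float, float, float, float]:
        """The four constant levels; raises ModeError for time-varying inputs."""
        if not self.is_constant:
            raise ModeError("inputs are time-varying; constant mode required")
        return tuple(self._channels[k] for k in self.CHANNELS)

    def __call__(self, t: float) -> np.ndarray:
        """Evaluate (x7, x8, x9, x10) at time t (minutes)."""
        out = np.empty(4)
        for i, name in enumerate(self.CHANNELS):
            ch = self._channels[name]
            if isinstance(ch, float):
                out[i] = ch
            else:
                knots_t, knots_v = ch
                out[i] = np.interp(t, knots_t, knots_v)
        return out

    def to_dict(self) -> dict:
        out = {}
        for name, ch in self._channels.items():
            out[name] = ch if isinstance(ch, float) else {
                "t_min": list(map(float, ch[0])),
                "value": list(map(float, ch[1])),
            }
        return out


@dataclass(frozen=True)
class DerivedConstants:
    """Constants of the reduced three-gene (AP1, LFY, SOC1) model.

    ``u`` is the constant FT level fixed by the leaf inputs; ``U1``/``U2``
    carry the FT and FT-FD action onto AP1 and SOC1; ``V1..V8`` and
    ``S1..S12`` are the lumped rates and saturation constants that appear
    after FD, AGL24 and FT are decoupled at their quasi-steady values.
    """

    u: float
    U1: float
    U2: float
    V: tuple[float, ...]
    S: tuple[float, ...]


def derive_constants(p: ParameterSet, inputs: InputSignals) -> DerivedConstants:
    """Compute the reduced-model constants from the registry and constant inputs."""
    x7, x8, x9, x10 = inputs.constants()
    k11 = hill_inhibition(x7, p.K[10])
    k12 = hill_inhibition(x8, p.K[11])
    u = p.beta[11] * hill_inhibition(x9, p.K[14]) * hill_inhibition(x10, p.K[15]) / p.d[5]
    b = p.beta
    K = p.K
    d = p.d
    V = (
        b[0],
        b[1] * b[9],
        b[3],
        b[4],
        b[5] * b[10],
        b[8] * b[9] * k11 * k12,
        b[6] * k11 * k12,
        b[7] * b[10] * k11 * k12,
    )
    S = (
        K[0],
        b[9] + d[3] * K[1],
        d[3] * K[1] * K[12],
        K[3],
        K[4],
        b[10] + d[4] * K[5],
        d[4] * K[5] * K[13],
        b[9] + d[3] * K[8],
        d[3] * K[8] * K[12],
        K[6],
        b[10] + d[4] * K[7],
        d[4] * K[7] * K[13],
    )
    U1 = b[2] * u / (u + K[2])
    U2 = u / (u + K[9])
    return DerivedConstants(u=u, U1=U1, U2=U2, V=V, S=S)


@dataclass(frozen=True)
class MotifParams:
    """Parameters of the two-gene AP1-LFY motif.

    ``F1`` and ``F2`` are the joint FT-FD / FT action constants on LFY and
    AP1 (inhibiting below 1, activating above 1).  The derived ``omega``
    coefficients define the steady-state polynomial
    ``(w1 + w2 F2) x2^n - w3 F1 F2 x2^(n-1) + w4 = 0``.
    """

    beta1: float
    beta4: float
    K1: float
    K4: float
    d1: float
    d2: float
    n: int = 3
    F1: float = 1.0
    F2: float = 1.0

    def __post_init__(self):
        if any(v <= 0 for v in (self.beta1, self.beta4, self.K1, self.K4,
                                self.d1, self.d2, self.F1, self.F2)):
            raise ConfigurationError("motif parameters must be strictly positive")

    @classmethod
    def from_parameters(cls, p: ParameterSet, F1: float = 1.0, F2: float = 1.0) -> "MotifParams":
        return cls(beta1=p.beta[0], beta4=p.beta[3], K1=p.K[0], K4=p.K[3],
                   d1=p.d[0], d2=p.d[1], n=p.n, F1=F1, F2=F2)

    def with_F(self, F1: float | None = None, F2: float | None = None) -> "MotifParams":
        return replace(self, F1=self.F1 if F1 is None else F1,
                       F2=self.F2 if F2 is None else F2)

    @property
    def omega1(self) -> float:
        return self.d1 * self.d2 * self.K4

    @property
    def omega2(self) -> float:
        return self.d2 * self.beta1

    @property
    def omega3(self) -> float:
        return self.beta1 * self.beta4

    @property
    def omega4(self) -> float:
        return self.d1 * self.d2 * self.K1**self.n * self.K4

    @property
    def x2_upper_bound(self) -> float:
        """Existence bound for positive equilibria: x2 < beta4*F1/d2."""
        return self.beta4 * self.F1 / self.d2
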