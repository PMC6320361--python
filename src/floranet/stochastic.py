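"""Stochastic AP1-LFY motifs: switching simulation and mean-square stability.

Two noise models perturb the deterministic motif.  Additive noise adds a
constant-amplitude white-noise term ``sigma_i dW_i`` to each rate, so even
sub-threshold initial states can be kicked across the flowering threshold
("stochastic switching").  Multiplicative noise scales with the distance
from a reference equilibrium, ``sigma_i (x_i - xbar_i) dW_i``, and admits a
quadratic Lyapunov certificate: the trivial state is locally asymptotically
stable in probability whenever ``sigma_i < sqrt(2 d_i)``, with the
Lyapunov weight ``theta`` required to exceed
``(beta4 F1 / K4)^2 / ((2 d1 - sigma1^2)(2 d2 - sigma2^2))``.

Sample paths use the Euler-Maruyama scheme with a fixed step.  Because
additive noise can push concentrations negative, states are clamped at
zero after every step (the Hill terms are meaningless below zero); clamp
activations are counted and reported.  Randomness is organised so runs are
reproducible across machines: one master seed, one spawned child stream
per trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bifurcation import classify_basin
from .errors import ConfigurationError, DivergenceError
from .kinetics import MINUTES_PER_DAY, MotifParams
from .models import Trajectory

NOISE_KINDS = ("additive", "multiplicative")


@dataclass
class SDEConfig:
    """Noise model, amplitudes, discretisation and ensemble bookkeeping.

    ``sigma1``/``sigma2`` are in nM/sqrt(min) for additive noise and
    1/sqrt(min) for multiplicative noise; ``reference`` is the equilibrium
    the multiplicative noise is centred on (defaults to the origin).
    """

    kind: str = "additive"
    sigma1: float = 0.05
    sigma2: float = 0.05
    reference: tuple[float, float] = (0.0, 0.0)
    dt: float = 0.5
    horizon_days: float = 50.0
    n_paths: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.kind not in NOISE_KINDS:
            raise ConfigurationError(f"noise kind must be one of {NOISE_KINDS}")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ConfigurationError("noise amplitudes must be non-negative")
        if self.dt <= 0 or self.horizon_days <= 0:
            raise ConfigurationError("dt and horizon must be positive")
        if self.n_paths < 1:
            raise ConfigurationError("ensemble size must be at least 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.horizon_days * MINUTES_PER_DAY / self.dt))

    @property
    def sigma(self) -> np.ndarray:
        return np.array([self.sigma1, self.sigma2])


@dataclass
class EnsembleSummary:
    """Endpoints, basin labels and switching statistics of an SDE ensemble."""

    endpoints: np.ndarray          # (n_paths, 2)
    labels: list[str]              # 'trivial' | 'flowering' | 'unresolved'
    switching_fraction: float      # share of paths reaching the flowering state
    snapshots: np.ndarray          # (n_frames, n_paths, 2) recorded states
    snapshot_times: np.ndarray     # minutes
    clamp_count: int
    config: SDEConfig

    def temporal_histogram(self, variable: int = 0, bins: int = 30) -> pd.DataFrame:
        """Long-format (time_bin, value_bin, count) histogram of one variable."""
        vals = self.snapshots[:, :, variable]
        edges = np.histogram_bin_edges(vals, bins=bins)
        rows = []
        for i, t in enumerate(self.snapshot_times):
            counts, _ = np.histogram(vals[i], bins=edges)
            for j, c in enumerate(counts):
                rows.append((t, 0.5 * (edges[j] + edges[j + 1]), int(c)))
        return pd.DataFrame(rows, columns=["time_min", "value_bin", "count"])


@dataclass
class LyapunovCheck:
    """Evaluation of the mean-square stability certificate at the origin."""

    sigma1: float
    sigma2: float
    bound1: float                      # sqrt(2 d1)
    bound2: float                      # sqrt(2 d2)
    condition: bool                    # both sigma_i strictly below their bound
    theta_lower: float | None          # infimum of admissible Lyapunov weights
    theta: float | None                # the weight actually chosen (2x infimum)
    eps_window: tuple[float, float] | None  # admissible Young's-inequality eps


def _drift(x, mp: MotifParams):
    """Vectorised motif drift for states of shape (..., 2)."""
    x1 = x[..., 0]
    x2 = x[..., 1]
    x2n = x2**mp.n
    out = np.empty_like(x)
    out[..., 0] = mp.beta1 * x2n / (x2n + mp.K1**mp.n) * mp.F2 - mp.d1 * x1
    out[..., 1] = mp.beta4 * x1 / (x1 + mp.K4) * mp.F1 - mp.d2 * x2
    return out


def _simulate(config: SDEConfig, initial, mp: MotifParams, record_every: int):
    """Shared Euler-Maruyama core, vectorised over paths."""
    n = config.n_paths
    dt = config.dt
    sqdt = math.sqrt(dt)
    sigma = config.sigma
    ref = np.asarray(config.reference, dtype=float)
    x = np.broadcast_to(np.asarray(initial, dtype=float), (n, 2)).copy()
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(n)]
    n_steps = config.n_steps
    frames = [x.copy()]
    frame_times = [0.0]
    clamp_count = 0
    chunk = 20000
    step = 0
    while step < n_steps:
        k = min(chunk, n_steps - step)
        # per-path noise streams, drawn chunkwise: (k, n, 2)
        noise = np.stack([g.standard_normal((k, 2)) for g in streams], axis=1)
        for i in range(k):
            drift = _drift(x, mp)
            if config.kind == "additive":
                diffusion = sigma * noise[i]
            else:
                diffusion = sigma * (x - ref) * noise[i]
            x = x + drift * dt + diffusion * sqdt
            neg = x < 0
            if neg.any():
                clamp_count += int(neg.sum())
                x[neg] = 0.0
            step += 1
            if step % record_every == 0 or step == n_steps:
                if not np.all(np.isfinite(x)):
                    raise DivergenceError(step * dt)
                frames.append(x.copy())
                frame_times.append(step * dt)
    return np.array(frames), np.array(frame_times), clamp_count


def euler_maruyama(config: SDEConfig, initial, mp: MotifParams) -> Trajectory:
    """One Euler-Maruyama sample path of the stochastic motif.

    With both amplitudes zero the path coincides exactly with the explicit
    Euler solution of the deterministic motif.
    """
    single = SDEConfig(**{**config.__dict__, "n_paths": 1})
    frames, times, clamp_count = _simulate(single, initial, mp, record_every=1)
    traj = Trajectory(times, frames[:, 0, :], ("AP1", "LFY"), model=f"sde-{config.kind}")
    traj.clamp_count = clamp_count
    return traj


def run_ensemble(config: SDEConfig, initial, mp: MotifParams,
                 record_every: int | None = None) -> EnsembleSummary:
    """Simulate an ensemble and classify each endpoint's basin.

    Endpoint basins are decided by deterministic continuation: each final
    state is handed to :func:`floranet.bifurcation.classify_basin`, so a
    path counts as switched only if the noise actually carried it into the
    flowering basin.
    """
    if record_every is None:
        record_every = max(1, config.n_steps // 400)
    frames, times, clamp_count = _simulate(config, initial, mp, record_every)
    endpoints = frames[-1]
    labels = [classify_basin(endpoint, mp) for endpoint in endpoints]
    switching = sum(1 for l in labels if l == "flowering") / len(labels)
    return EnsembleSummary(endpoints=endpoints, labels=labels,
                           switching_fraction=switching, snapshots=frames,
                           snapshot_times=times, clamp_count=clamp_count,
                           config=config)


def ms_stability_check(sigma1: float, sigma2: float, mp: MotifParams) -> LyapunovCheck:
    """Evaluate the Lyapunov mean-square stability certificate at the origin."""
    if sigma1 < 0 or sigma2 < 0:
        raise ConfigurationError("noise amplitudes must be non-negative")
    bound1 = math.sqrt(2 * mp.d1)
    bound2 = math.sqrt(2 * mp.d2)
    condition = sigma1 < bound1 and sigma2 < bound2
    if not condition:
        return LyapunovCheck(sigma1, sigma2, bound1, bound2, condition,
                             None, None, None)
    coupling = mp.beta4 * mp.F1 / mp.K4
    theta_lower = coupling**2 / ((2 * mp.d1 - sigma1**2) * (2 * mp.d2 - sigma2**2))
    theta = 2.0 * theta_lower
    eps_lo = coupling / (2 * mp.d2 - sigma2**2)
    eps_hi = theta * (2 * mp.d1 - sigma1**2) / coupling
    return LyapunovCheck(sigma1, sigma2, bound1, bound2, condition,
                         theta_lower, theta, (eps_lo, eps_hi))
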