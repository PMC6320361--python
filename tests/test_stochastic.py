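import numpy as np
import pytest

from floranet import (
    SDEConfig,
    euler_maruyama,
    integrate_motif,
    ms_stability_check,
    run_ensemble,
)
from floranet.errors import ConfigurationError
from floranet.models import motif_rhs
from floranet.stochastic import _drift


class TestEulerMaruyama:
    def test_zero_noise_equals_explicit_euler(self, motif_best):
        config = SDEConfig(kind="additive", sigma1=0.0, sigma2=0.0,
                           dt=0.5, horizon_days=1.0, n_paths=1, seed=9)
        traj = euler_maruyama(config, (0.2, 1.2), motif_best)
        x = np.array([[0.2, 1.2]])
        for _ in range(config.n_steps):
            x = x + _drift(x, motif_best) * config.dt
        assert np.array_equal(traj.endpoint, x[0])
        # and the drift is the deterministic motif vector field
        y = np.array([0.2, 1.2])
        for _ in range(config.n_steps):
            y = y + motif_rhs(0.0, y, motif_best) * config.dt
        np.testing.assert_allclose(traj.endpoint, y, rtol=1e-9, atol=1e-300)

    def test_fixed_seed_reproducible(self, motif_best):
        config = SDEConfig(sigma1=0.05, sigma2=0.05, horizon_days=0.5,
                           n_paths=1, seed=42)
        a = euler_maruyama(config, (0.2, 1.2), motif_best)
        b = euler_maruyama(config, (0.2, 1.2), motif_best)
        assert np.array_equal(a.y, b.y)

    def test_multiplicative_noise_vanishes_at_reference(self, motif_best):
        from floranet import stable_flowering_state
        ref = stable_flowering_state(motif_best)
        config = SDEConfig(kind="multiplicative", sigma1=0.3, sigma2=0.1,
                           reference=ref, horizon_days=0.5, n_paths=1, seed=1)
        noisy = euler_maruyama(config, ref, motif_best)
        quiet = euler_maruyama(
            SDEConfig(**{**config.__dict__, "sigma1": 0.0, "sigma2": 0.0}),
            ref, motif_best)
        np.testing.assert_allclose(noisy.y, quiet.y, rtol=1e-9, atol=1e-12)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SDEConfig(kind="pink")
        with pytest.raises(ConfigurationError):
            SDEConfig(sigma1=-0.1)
        with pytest.raises(ConfigurationError):
            SDEConfig(n_paths=0)


class TestEnsemble:
    def test_subthreshold_switching_with_5pct_noise(self, motif_best):
        """Additive noise lets sub-threshold starts reach the flowering
        state: both basins are populated across the ensemble."""
        config = SDEConfig(kind="additive", sigma1=0.05, sigma2=0.05,
                           n_paths=100, seed=0, horizon_days=50.0)
        summary = run_ensemble(config, (0.2, 1.2), motif_best, record_every=500)
        assert 0.0 < summary.switching_fraction < 1.0
        assert set(summary.labels) >= {"trivial", "flowering"}

    def test_zero_noise_subthreshold_never_switches(self, motif_best):
        config = SDEConfig(kind="additive", sigma1=0.0, sigma2=0.0,
                           n_paths=4, seed=0, horizon_days=5.0)
        summary = run_ensemble(config, (0.2, 1.2), motif_best)
        assert summary.switching_fraction == 0.0

    def test_switching_monotone_in_noise(self, motif_best):
        """More noise, more switching (within binomial error)."""
        fractions = []
        for sigma in (0.005, 0.02, 0.05):
            config = SDEConfig(kind="additive", sigma1=sigma, sigma2=sigma,
                               n_paths=100, seed=31, horizon_days=20.0)
            s = run_ensemble(config, (0.2, 1.2), motif_best, record_every=2000)
            fractions.append(s.switching_fraction)
        assert fractions[0] <= fractions[1] + 0.1
        assert fractions[1] <= fractions[2] + 0.1
        assert fractions[2] > fractions[0]

    def test_ensemble_mean_approaches_deterministic_as_noise_shrinks(self, motif_best):
        det = integrate_motif(motif_best, (5.0, 10.0), horizon_days=2.0,
                              step=0.5).endpoint
        errs = []
        for sigma in (0.25, 0.01):
            config = SDEConfig(kind="additive", sigma1=sigma, sigma2=sigma,
                               n_paths=200, seed=8, horizon_days=2.0)
            s = run_ensemble(config, (5.0, 10.0), motif_best, record_every=1000)
            errs.append(np.linalg.norm(s.endpoints.mean(axis=0) - det))
        assert errs[1] < errs[0]

    def test_histogram_counts_partition_ensemble(self, motif_best):
        config = SDEConfig(sigma1=0.05, sigma2=0.05, n_paths=20, seed=3,
                           horizon_days=1.0)
        s = run_ensemble(config, (0.2, 1.2), motif_best, record_every=100)
        hist = s.temporal_histogram(variable=1, bins=10)
        per_time = hist.groupby("time_min")["count"].sum()
        assert (per_time == config.n_paths).all()


class TestLyapunovCertificate:
    def test_noise_free_theta_bound(self, motif_best):
        chk = ms_stability_check(0.0, 0.0, motif_best)
        expected = (motif_best.beta4 * motif_best.F1 / motif_best.K4) ** 2 / (
            4 * motif_best.d1 * motif_best.d2)
        assert chk.condition
        assert chk.theta_lower == pytest.approx(expected, rel=1e-12)

    def test_bounds_from_degradation_rates(self, motif_best):
        chk = ms_stability_check(1.3, 0.18, motif_best)
        assert chk.bound1 == pytest.approx(np.sqrt(2 * 0.86), rel=1e-12)
        assert chk.bound2 == pytest.approx(np.sqrt(2 * 0.017), rel=1e-12)
        assert chk.condition
        assert chk.eps_window[0] < chk.eps_window[1]

    def test_violated_bound_yields_no_certificate(self, motif_best):
        chk = ms_stability_check(1.3, 0.2, motif_best)   # 0.2 > sqrt(0.034)
        assert not chk.condition
        assert chk.theta_lower is None and chk.eps_window is None

    def test_second_moment_decays_inside_certificate_region(self, motif_best):
        """Multiplicative noise at 80% of both bounds: the ensemble second
        moment about the origin decays; pushing the LFY amplitude 20% above
        its bound destroys the decay."""
        b1 = np.sqrt(2 * motif_best.d1)
        b2 = np.sqrt(2 * motif_best.d2)

        def moment_ratio(sigma2):
            config = SDEConfig(kind="multiplicative", sigma1=0.8 * b1,
                               sigma2=sigma2, reference=(0.0, 0.0),
                               n_paths=500, seed=7, horizon_days=0.0347)
            s = run_ensemble(config, (0.0, 0.01), motif_best, record_every=25)
            m0 = (s.snapshots[0] ** 2).sum(axis=1).mean()
            mT = (s.snapshots[-1] ** 2).sum(axis=1).mean()
            return mT / m0

        assert moment_ratio(0.8 * b2) < 1.0
        assert moment_ratio(1.2 * b2) > 1.0

    def test_switching_fraction_converges_under_step_halving(self, motif_best):
        fractions = []
        for dt in (0.5, 0.25):
            config = SDEConfig(kind="additive", sigma1=0.05, sigma2=0.05,
                               dt=dt, n_paths=100, seed=12, horizon_days=20.0)
            s = run_ensemble(config, (0.2, 1.2), motif_best, record_every=4000)
            fractions.append(s.switching_fraction)
        assert abs(fractions[0] - fractions[1]) <= 0.15
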