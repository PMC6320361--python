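import numpy as np
import pytest

from floranet import (
    derive_constants,
    full_rhs,
    integrate_dde,
    integrate_full,
    integrate_motif,
    integrate_reduced,
    motif_rhs,
    reduced_rhs,
)
from floranet.errors import DivergenceError, DomainError
from floranet.models import Trajectory

from .conftest import GERMINATION_STATE, PUBLISHED_STEADY_STATE


class TestFullRhs:
    def test_zero_at_published_steady_state(self, params, inputs):
        rates = full_rhs(0.0, PUBLISHED_STEADY_STATE,
                         PUBLISHED_STEADY_STATE[5], params, inputs)
        assert np.max(np.abs(rates) / np.abs(PUBLISHED_STEADY_STATE)) < 1e-5

    def test_pure_production_at_origin(self, params, inputs):
        rates = full_rhs(0.0, np.zeros(6), 0.0, params, inputs)
        # LFY, FD, AGL24 have purely activating production, zero at the
        # origin; AP1, SOC1, FT are driven by the constant FT/input terms.
        assert rates[5] > 0 and rates[0] >= 0
        assert np.all(rates >= 0)

    def test_decay_dominates_for_tiny_production(self, params, inputs):
        tiny = params.with_values(**{f"beta{i}": 1e-300 for i in range(1, 13)})
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 60.0])
        rates = full_rhs(0.0, x, x[5], tiny, inputs)
        assert np.allclose(rates, -np.array(tiny.d) * x, rtol=1e-10)

    def test_shape_error(self, params, inputs):
        with pytest.raises(DomainError):
            full_rhs(0.0, np.zeros(5), 0.0, params, inputs)


class TestReducedRhs:
    def test_only_constant_input_term_at_origin(self, params, inputs):
        c = derive_constants(params, inputs)
        rates = reduced_rhs(0.0, np.zeros(3), c, params)
        assert rates[0] == pytest.approx(c.U1)
        assert rates[1] == 0.0 and rates[2] == 0.0

    def test_reduced_ap1_tracks_full_model(self, params, inputs):
        """Decoupling FD/AGL24/FT preserves the AP1 sigmoid and endpoint."""
        c = derive_constants(params, inputs)
        full = integrate_full(params, inputs, GERMINATION_STATE,
                              horizon_days=40, step=2.0, delta_days=0.0)
        red = integrate_reduced(params, c, GERMINATION_STATE[:3],
                                horizon_days=40, step=2.0)
        assert red.endpoint[0] == pytest.approx(full.endpoint[0], rel=0.02)
        # the reduced model converges at least as fast (constant inputs sit
        # at their high steady levels)
        i_full = int(np.argmax(full.y[:, 0] >= 0.5 * full.endpoint[0]))
        i_red = int(np.argmax(red.y[:, 0] >= 0.5 * red.endpoint[0]))
        assert i_red <= i_full


class TestDDEIntegrator:
    def test_scalar_delay_problem_closed_form(self):
        """x' = -x(t - 1), constant history 1: x(t) = 1 - t on [0, 1]."""
        def rhs(t, x, xd, p, inputs):
            return np.array([-xd])

        traj = integrate_dde(rhs, np.array([1.0]), delta=1.0, horizon=1.0,
                             step=0.05, delayed_index=0)
        assert traj.y[-1, 0] == pytest.approx(0.0, abs=1e-12)
        mid = int(np.argmin(np.abs(traj.t - 0.5)))
        assert traj.y[mid, 0] == pytest.approx(0.5, abs=1e-12)

    def test_zero_delay_reduces_to_ode(self, params, inputs):
        a = integrate_full(params, inputs, GERMINATION_STATE, horizon_days=1.0,
                          step=1.0, delta_days=0.0)
        # reference: same RK4 on the delay-free vector field, finer step
        b = integrate_full(params, inputs, GERMINATION_STATE, horizon_days=1.0,
                          step=0.25, delta_days=0.0)
        assert np.allclose(a.endpoint, b.endpoint, rtol=1e-6)

    def test_nonnegativity_from_nonnegative_start(self, params, inputs):
        traj = integrate_full(params, inputs, GERMINATION_STATE,
                              horizon_days=5.0, step=1.0)
        assert np.all(traj.y >= 0)

    def test_step_halving_convergence(self, params, inputs):
        """Endpoint error shrinks at least linearly with the step.

        With the transport delay active the stored-channel interpolation
        limits the observed order to ~2; with zero delay the scheme is
        plain RK4 and the order is ~4.
        """
        ref = integrate_full(params, inputs, GERMINATION_STATE, horizon_days=1.0,
                             step=0.125, delta_days=0.5)
        errs = []
        for step in (2.0, 1.0, 0.5):
            traj = integrate_full(params, inputs, GERMINATION_STATE,
                                  horizon_days=1.0, step=step, delta_days=0.5)
            errs.append(np.max(np.abs(traj.endpoint - ref.endpoint)))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders > 1.0)

    def test_step_larger_than_delay_rejected(self, params, inputs):
        with pytest.raises(DomainError):
            integrate_full(params, inputs, GERMINATION_STATE, horizon_days=1.0,
                           step=15.0, delta_days=10.0 / 1440.0)

    def test_divergence_guard_names_time(self, params, inputs):
        # unphysically slow degradation + huge production forces a blow-up
        def explosive(t, x, xd, p, i):
            return x * 1.0  # exponential growth, rate 1/min

        with pytest.raises(DivergenceError) as err:
            integrate_dde(explosive, np.array([1.0] * 6), delta=0.0,
                          horizon=1e4, step=1.0)
        assert err.value.time_min > 0


class TestTrajectory:
    def test_frame_layout(self, motif_best):
        traj = integrate_motif(motif_best, (0.24, 5.0), horizon_days=0.1, step=1.0)
        frame = traj.to_frame()
        assert list(frame.columns) == ["time_min", "day", "AP1", "LFY"]
        assert len(frame) == len(traj.t)

    def test_grid_validation(self):
        with pytest.raises(DomainError):
            Trajectory(np.array([0.0, 0.0, 1.0]), np.zeros((3, 2)),
                       ("a", "b"), model="x")


def test_motif_rhs_matches_reduced_structure(motif_best):
    """At the motif level the AP1 equation keeps only the LFY Hill term."""
    rates = motif_rhs(0.0, np.array([0.0, 0.0]), motif_best)
    assert rates[0] == 0.0 and rates[1] == 0.0
    rates = motif_rhs(0.0, np.array([0.0, 1e9]), motif_best)
    assert rates[0] == pytest.approx(motif_best.beta1 * motif_best.F2, rel=1e-6)
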