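import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isosentinel.datatypes import ValidationError
from isosentinel.mcmc import McmcConfig
from isosentinel.synthetic import ScenarioSpec, simulate_turnover
from isosentinel.turnover import (derive_t0_t1, fit_turnover_model,
                                  q_fraction, turnover_mean)

FAST = McmcConfig(n_chains=3, n_iter=3000, n_burn=1000, seed=0)


class TestQFraction:
    def test_pre_lag_clamps_to_zero(self):
        t0, _ = derive_t0_t1(0.03, 0.047)
        assert q_fraction(0.03, 0.047, t0 - 1) == 0.0

    def test_plateau_clamps_to_one(self):
        _, t1 = derive_t0_t1(0.03, 0.047)
        assert q_fraction(0.03, 0.047, t1 + 1) == 1.0

    def test_shifted_arithmetic(self):
        assert q_fraction(0.0, 0.047, 24.0) == pytest.approx(0.47)

    def test_literal_convention(self):
        assert q_fraction(0.0, 0.02, 24.0, convention="literal") == pytest.approx(0.48)

    @settings(derandomize=True, max_examples=50)
    @given(a=st.floats(-0.5, 0.5), b=st.floats(0.001, 0.2),
           d1=st.floats(0, 60), d2=st.floats(0, 60))
    def test_non_decreasing_in_days(self, a, b, d1, d2):
        lo, hi = sorted([d1, d2])
        assert q_fraction(a, b, lo) <= q_fraction(a, b, hi) + 1e-12


class TestTurnoverMean:
    def test_piecewise_regions(self):
        assert turnover_mean(7, -60, -110, 0.03, 0.047) == -60
        assert turnover_mean(40, -60, -110, 0.03, 0.047) == -110

    def test_midpoint_mixing(self):
        # choose days so q = 0.5 exactly: a + b(d-14) = 0.5
        d = 14 + (0.5 - 0.03) / 0.047
        assert turnover_mean(d, -60, -110, 0.03, 0.047) == pytest.approx(-85.0)

    def test_continuity_at_joins_when_ramp_anchored(self):
        # a = 0 anchors q(14) = 0; b chosen so q(35) = 1
        b = 1.0 / 21
        eps = 1e-7
        left = turnover_mean(14 - eps, -60, -110, 0.0, b)
        right = turnover_mean(14 + eps, -60, -110, 0.0, b)
        assert left == pytest.approx(right, abs=1e-4)
        left = turnover_mean(35 - eps, -60, -110, 0.0, b)
        right = turnover_mean(35 + eps, -60, -110, 0.0, b)
        assert left == pytest.approx(right, abs=1e-4)

    @settings(derandomize=True, max_examples=50)
    @given(days=st.floats(0, 60), init=st.floats(-200, 0),
           final=st.floats(-200, 0), a=st.floats(0, 0.3),
           b=st.floats(0.001, 0.1))
    def test_mean_bounded_by_endpoints(self, days, init, final, a, b):
        mu = float(turnover_mean(days, init, final, a, b))
        lo, hi = sorted([init, final])
        assert lo - 1e-9 <= mu <= hi + 1e-9


class TestDeriveT0T1:
    def test_zero_intercept(self):
        t0, t1 = derive_t0_t1(0.0, 0.047)
        assert t0 == pytest.approx(14.0)
        assert t1 == pytest.approx(1 / 0.047 + 14)

    def test_unit_step_at_day_13(self):
        t0, _ = derive_t0_t1(0.047, 0.047)
        assert t0 == pytest.approx(13.0)

    def test_t0_below_t1_always(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.2, 100)
        b = rng.uniform(0.001, 0.2, 100)
        t0, t1 = derive_t0_t1(a, b)
        assert np.all(t0 < t1)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValidationError):
            derive_t0_t1(0.1, 0.0)


class TestFitTurnover:
    @pytest.fixture(scope="class")
    def posterior(self):
        obs, _ = simulate_turnover(ScenarioSpec(seed=11),
                                   np.random.default_rng(11))
        return fit_turnover_model(obs, FAST)

    def test_recovers_generating_parameters(self, posterior):
        spec = ScenarioSpec()
        lo, hi = np.percentile(posterior.b_draws, [2.5, 97.5])
        assert lo <= spec.b_true <= hi
        assert posterior.init_draws.mean() == pytest.approx(spec.init_true, abs=3)
        assert posterior.final_draws.mean() == pytest.approx(spec.final_true, abs=3)

    def test_b_positive_and_t0_below_t1_per_draw(self, posterior):
        assert np.all(posterior.b_draws > 0)
        assert np.all(posterior.t0_draws < posterior.t1_draws)

    def test_ci_is_percentile_of_transform_not_transform_of_means(self, posterior):
        """T0/T1 intervals come from per-draw transforms."""
        t0_direct, _ = derive_t0_t1(posterior.a_draws, posterior.b_draws)
        assert np.allclose(np.sort(t0_direct), np.sort(posterior.t0_draws))
        # the transform of the posterior means differs from the mean of
        # transforms whenever the posterior has spread
        t0_of_means, _ = derive_t0_t1(posterior.a_draws.mean(),
                                      posterior.b_draws.mean())
        assert abs(float(t0_of_means) - posterior.t0_draws.mean()) > 1e-6

    def test_zero_noise_concentrates_on_truth(self):
        spec = ScenarioSpec(sigma_exp=(0.1, 0.1, 0.1), seed=2)
        obs, _ = simulate_turnover(spec, np.random.default_rng(2))
        post = fit_turnover_model(obs, FAST)
        assert post.init_draws.mean() == pytest.approx(spec.init_true, abs=0.3)
        assert post.final_draws.mean() == pytest.approx(spec.final_true, abs=0.3)
        # posterior spread collapses with the noise
        assert post.init_draws.std() < 0.5
        assert post.final_draws.std() < 0.5

    def test_missing_group_warns_but_fits(self):
        spec = ScenarioSpec(seed=3)
        obs, _ = simulate_turnover(spec, np.random.default_rng(3))
        ramp_free = [o for o in obs if o.group != "ramp"]
        with pytest.warns(UserWarning, match="ramp"):
            post = fit_turnover_model(
                ramp_free, McmcConfig(n_chains=2, n_iter=600, n_burn=200, seed=1))
        assert np.isfinite(post.b_draws).all()

    def test_wing_elytra_excluded(self):
        from isosentinel.datatypes import TurnoverObservation
        obs, _ = simulate_turnover(ScenarioSpec(seed=4), np.random.default_rng(4))
        with_wings = obs + [
            TurnoverObservation(f"W{i}", 35.0, -70.0, tissue="wings")
            for i in range(5)
        ]
        cfg = McmcConfig(n_chains=2, n_iter=600, n_burn=200, seed=2)
        a = fit_turnover_model(obs, cfg)
        b = fit_turnover_model(with_wings, cfg)
        assert np.array_equal(a.b_draws, b.b_draws)
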