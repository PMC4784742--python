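import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from isosentinel.datatypes import TrafficRecord, ValidationError
from isosentinel.mixing import (MixingHyperparams, SourcePrior,
                                beetle_loglik_marginal, build_source_prior,
                                mixture_mean, mixture_variance, p_from_time,
                                time_prior_logpdf, truncated_lognormal_mean,
                                weighted_end_member, window_weights)


class TestWindowWeights:
    def test_mid_june_enumeration(self):
        w, months = window_weights(dt.date(2013, 6, 15))
        assert np.allclose(w * 90, [15, 31, 30, 14])
        assert list(months) == [6, 5, 4, 3]

    def test_thirty_day_month_chain(self):
        # 30 Jun backwards: Jun 30 + May 31 + Apr 29 days fill the window
        w, months = window_weights(dt.date(2013, 6, 30))
        assert w.sum() == pytest.approx(1.0)
        assert np.allclose(w * 90, [30, 31, 29, 0])

    @settings(derandomize=True, max_examples=100)
    @given(ordinal=st.integers(dt.date(2000, 1, 1).toordinal(),
                               dt.date(2020, 12, 31).toordinal()))
    def test_partition_of_window(self, ordinal):
        w, months = window_weights(dt.date.fromordinal(ordinal))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w >= 0)
        assert len(set(months)) == 4

    def test_year_boundary(self):
        w, months = window_weights(dt.date(2013, 1, 15))
        assert list(months) == [1, 12, 11, 10]
        assert w.sum() == pytest.approx(1.0)


class TestEndMemberMixing:
    def test_constant_values_convexity(self):
        w, _ = window_weights(dt.date(2013, 6, 15))
        assert weighted_end_member([-80.0] * 4, w) == pytest.approx(-80.0)

    def test_degenerate_window(self):
        assert weighted_end_member([-100, -110, -120, -130],
                                   [1, 0, 0, 0]) == -100

    def test_weighted_average_arithmetic(self):
        assert weighted_end_member([-100, -110, -120, -130],
                                   [0.2, 0.3, 0.3, 0.2]) == pytest.approx(-115.0)

    def test_mixture_mean_limits(self):
        assert mixture_mean(1.0, -120.0, -60.0) == -120.0
        assert mixture_mean(0.0, -120.0, -60.0) == -60.0
        assert mixture_mean(0.5, -120.0, -60.0) == -90.0

    def test_mixture_mean_rejects_bad_p(self):
        with pytest.raises(ValidationError):
            mixture_mean(1.2, -120.0, -60.0)


class TestMixtureVariance:
    @pytest.fixture()
    def hyper(self):
        return MixingHyperparams(sigma_pdx=2.0, sigma_source=3.0,
                                 sigma_composite=5.0)

    def test_fully_equilibrated_ignores_source(self, hyper):
        assert mixture_variance(1.0, 3, hyper) == pytest.approx(4.0)
        assert mixture_variance(1.0, 58, hyper) == pytest.approx(4.0)

    def test_new_arrival_from_composite(self, hyper):
        assert mixture_variance(0.0, 58, hyper) == pytest.approx(25.0)

    def test_blend_arithmetic(self, hyper):
        assert mixture_variance(0.5, 3, hyper) == pytest.approx(6.5)


class TestTimePrior:
    def test_integrates_to_one(self):
        mu, sig = math.log(20), 0.8
        val, _ = quad(lambda t: math.exp(time_prior_logpdf(t, mu, sig)),
                      0.5, 60, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_outside_truncation_is_minus_inf(self):
        assert time_prior_logpdf(0.4, 0.0, 1.0) == -np.inf
        assert time_prior_logpdf(60.5, 0.0, 1.0) == -np.inf

    def test_small_sigma_concentrates_at_exp_mu(self):
        mu = math.log(10)
        dense = time_prior_logpdf(10.0, mu, 0.01)
        off = time_prior_logpdf(12.0, mu, 0.01)
        assert dense - off > 100

    def test_truncated_mean_inside_bounds(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(0, 20, 200)
        sig = rng.uniform(0.05, 50, 200)
        m = truncated_lognormal_mean(mu, sig)
        assert np.all((m > 0.5) & (m < 60.0))

    def test_truncated_mean_matches_quadrature(self):
        mu, sig = math.log(15), 0.6
        num, _ = quad(lambda t: t * math.exp(time_prior_logpdf(t, mu, sig)),
                      0.5, 60, limit=200)
        assert truncated_lognormal_mean(mu, sig) == pytest.approx(num, rel=1e-6)


class TestSourcePrior:
    def test_traffic_weighting_arithmetic(self):
        traffic = [TrafficRecord("A", 90.0, 35.0), TrafficRecord("B", 10.0, 40.0)]
        prior = build_source_prior(traffic, "traffic")
        assert np.allclose(prior.probs, [0.72, 0.08, 0.20])

    def test_flat_mode(self):
        traffic = [TrafficRecord(f"R{i}", float(i), 35.0) for i in range(57)]
        prior = build_source_prior(traffic, "flat")
        assert np.allclose(prior.probs[:-1], 0.8 / 57)
        assert prior.probs[-1] == pytest.approx(0.20)

    def test_composite_mass_both_modes(self):
        traffic = [TrafficRecord("A", 5.0, 35.0), TrafficRecord("B", 2.0, 40.0)]
        for mode in ("traffic", "flat"):
            assert build_source_prior(traffic, mode).probs[-1] == pytest.approx(0.20)

    def test_zero_flights_rejected_in_traffic_mode(self):
        traffic = [TrafficRecord("A", 0.0, 35.0)]
        with pytest.raises(ValidationError):
            build_source_prior(traffic, "traffic")


class TestMarginalLikelihood:
    def _setup(self, seed=0, n_regions=58):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(n_regions - 1)) * 0.8
        prior = SourcePrior(np.append(probs, 0.2), "traffic",
                            [f"R{i}" for i in range(n_regions - 1)])
        hyper = MixingHyperparams(sigma_pdx=3.0, sigma_source=4.0,
                                  sigma_composite=8.0)
        em_src = rng.normal(-90, 15, n_regions)
        return prior, hyper, em_src

    def test_equals_explicit_enumeration(self):
        """Marginal likelihood must equal the explicit 58-term sum."""
        prior, hyper, em_src = self._setup()
        d2h, time, a, b = -95.0, 20.0, 0.03, 0.047
        em_pdx = -125.0
        ll, weights = beetle_loglik_marginal(d2h, time, hyper, prior,
                                             em_pdx, em_src, a, b)
        p = float(p_from_time(a, b, time))
        total = 0.0
        for j in range(58):
            mu = p * em_pdx + (1 - p) * em_src[j]
            var = mixture_variance(p, j + 1, hyper)
            total += prior.probs[j] * math.exp(
                -0.5 * (d2h - mu) ** 2 / var) / math.sqrt(2 * math.pi * var)
        assert ll == pytest.approx(math.log(total), rel=1e-12)
        assert weights.sum() == pytest.approx(1.0, rel=1e-12)

    def test_degenerate_prior_reduces_to_single_normal(self):
        prior = SourcePrior(np.array([0.8, 0.0, 0.2]), "traffic", ["A", "B"])
        hyper = MixingHyperparams(sigma_pdx=3.0, sigma_source=4.0,
                                  sigma_composite=400.0)
        em_src = np.array([-90.0, -50.0, -1000.0])
        ll, weights = beetle_loglik_marginal(-92.0, 2.0, hyper, prior,
                                             -125.0, em_src, 0.0, 0.047)
        # p = 0 at 2 days: single-source normal at the 'A' end-member
        expected = (-0.5 * ((-92.0 + 90.0) / 4.0) ** 2
                    - math.log(4.0 * math.sqrt(2 * math.pi)) + math.log(0.8))
        assert ll == pytest.approx(np.logaddexp(
            expected, math.log(0.2) - 0.5 * ((-92.0 + 1000.0) / 400.0) ** 2
            - math.log(400.0 * math.sqrt(2 * math.pi))), rel=1e-9)
        assert weights[0] > 0.999

    def test_longer_time_pulls_mean_toward_local(self):
        """Increasing latent time weakly increases p, shifting the most
        likely source interpretation toward the local end-member."""
        prior, hyper, em_src = self._setup(seed=1)
        em_pdx = -150.0
        p_vals = [float(p_from_time(0.03, 0.047, t)) for t in (5, 20, 30, 50)]
        assert all(x <= y for x, y in zip(p_vals, p_vals[1:]))
        mus = [mixture_mean(p, em_pdx, em_src.mean()) for p in p_vals]
        assert all(x >= y for x, y in zip(mus, mus[1:]))

    def test_exchangeable_under_relabeling(self):
        prior, hyper, em_src = self._setup(seed=2)
        ll1, w1 = beetle_loglik_marginal(-95.0, 20.0, hyper, prior, -125.0,
                                         em_src, 0.03, 0.047)
        # swap two non-composite regions (probs and end-members together)
        perm = np.arange(58)
        perm[[3, 11]] = perm[[11, 3]]
        prior2 = SourcePrior(prior.probs[perm], "traffic",
                             [prior.region_ids[i] for i in perm[:-1]])
        ll2, w2 = beetle_loglik_marginal(-95.0, 20.0, hyper, prior2, -125.0,
                                         em_src[perm], 0.03, 0.047)
        assert ll1 == pytest.approx(ll2, rel=1e-12)
        assert np.allclose(w1[perm], w2)
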