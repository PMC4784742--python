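import numpy as np
import pytest

from isosentinel.datatypes import SurveillanceRecord, ValidationError
from isosentinel.reporting import (exp_decline_fit, d2h_year_trend,
                                   latitude_source_regression,
                                   posterior_minus_prior_regression,
                                   prior_robustness,
                                   voucher_annual_regression)


def _normal_equations(x, y, w=None):
    """Independent weighted least-squares oracle."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    w = np.ones_like(x) if w is None else np.asarray(w, float)
    X = np.column_stack([np.ones_like(x), x])
    A = X.T @ (w[:, None] * X)
    beta = np.linalg.solve(A, X.T @ (w * y))
    resid = y - X @ beta
    ybar = (w * y).sum() / w.sum()
    ss_res = (w * resid ** 2).sum()
    ss_tot = (w * (y - ybar) ** 2).sum()
    return beta[1], beta[0], 1 - ss_res / ss_tot


class TestAgainstNormalEquations:
    def test_unweighted_matches_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(30, 48, 40)
        y = -0.002 * x + 0.05 + rng.normal(0, 0.005, 40)
        res = latitude_source_regression(y, x, weighted=False)
        slope, intercept, r2 = _normal_equations(x, y)
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-10)
        assert res.r_squared == pytest.approx(r2, rel=1e-10)

    def test_weighted_matches_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(30, 48, 40)
        y = -0.001 * x + 0.06 + rng.normal(0, 0.01, 40)
        ci_w = rng.uniform(0.01, 0.2, 40)
        res = latitude_source_regression(y, x, ci_widths=ci_w, weighted=True)
        slope, _, _ = _normal_equations(x, y, w=1.0 / ci_w)
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.weights_used

    def test_equal_weights_equals_unweighted(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, 25)
        y = 2 * x + rng.normal(0, 0.1, 25)
        a = latitude_source_regression(y, x, ci_widths=np.full(25, 0.3),
                                       weighted=True)
        b = latitude_source_regression(y, x, weighted=False)
        assert a.slope == pytest.approx(b.slope, rel=1e-10)
        assert a.r_squared == pytest.approx(b.r_squared, rel=1e-10)


class TestVoucherRegression:
    def test_collinear_data_r2_one(self, default_dataset):
        locs = default_dataset.inputs.locations
        import datetime as dt
        from isosentinel.datatypes import SpecimenRecord
        sites = [l for l in locs if l.role == "voucher_site"][:5]
        vouchers = [
            SpecimenRecord(f"V{i}", -48.0 + float(np.mean(s.precip_monthly_pred)),
                           s.location_id, dt.date(2012, 7, 1), "voucher")
            for i, s in enumerate(sites)
        ]
        res = voucher_annual_regression(vouchers, locs)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.slope == pytest.approx(1.0, abs=1e-9)

    def test_synthetic_surface_strong(self, default_dataset):
        res = voucher_annual_regression(default_dataset.inputs.vouchers,
                                        default_dataset.inputs.locations)
        assert res.r_squared > 0.6
        assert 0.5 < res.slope < 1.5

    def test_shuffled_responses_slope_near_zero(self, default_dataset):
        """Permutation destroys the isoscape signal."""
        rng = np.random.default_rng(3)
        vouchers = list(default_dataset.inputs.vouchers)
        d2h = np.array([v.d2h for v in vouchers])
        slopes = []
        from dataclasses import replace
        for _ in range(20):
            shuffled = [replace(v, d2h=val)
                        for v, val in zip(vouchers, rng.permutation(d2h))]
            slopes.append(voucher_annual_regression(
                shuffled, default_dataset.inputs.locations).slope)
        assert abs(np.mean(slopes)) < 0.1

    def test_too_few_sites_rejected(self, default_dataset):
        vouchers = [v for v in default_dataset.inputs.vouchers
                    if v.location_id == "V01"]
        with pytest.raises(ValidationError, match="3 distinct"):
            voucher_annual_regression(vouchers,
                                      default_dataset.inputs.locations)


class TestYearTrend:
    def test_flat_series_zero_slope(self):
        import datetime as dt
        from isosentinel.datatypes import SpecimenRecord
        pdx = [SpecimenRecord(f"P{i}", -100.0, "PDX",
                              dt.date(2007 + i % 8, 7, 1), "pdx")
               for i in range(24)]
        res = d2h_year_trend(pdx)
        assert res.slope == pytest.approx(0.0, abs=1e-9)

    def test_injected_trend_recovered(self):
        import datetime as dt
        from isosentinel.datatypes import SpecimenRecord
        rng = np.random.default_rng(4)
        pdx = []
        for i in range(120):
            year = 2007 + i % 8
            pdx.append(SpecimenRecord(
                f"P{i}", -120.0 + 9.2 * (year - 2007) + rng.normal(0, 5),
                "PDX", dt.date(year, 7, 1), "pdx"))
        res = d2h_year_trend(pdx)
        assert res.slope == pytest.approx(9.2, abs=1.0)
        assert res.r_squared > 0.5


class TestLatitudeRegressions:
    def test_uniform_probabilities_zero_slope(self):
        lats = np.linspace(30, 48, 57)
        res = latitude_source_regression(np.full(57, 1 / 57.0), lats,
                                         weighted=False)
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_southern_mass_gives_negative_slope(self):
        lats = np.linspace(30, 48, 57)
        probs = np.exp(-(lats - 30) / 4)
        probs /= probs.sum()
        res = latitude_source_regression(probs, lats, weighted=False)
        assert res.slope < 0
        assert res.p_value < 0.001

    def test_posterior_equals_prior_zero_slope(self):
        lats = np.linspace(30, 48, 57)
        probs = np.random.default_rng(5).dirichlet(np.ones(57))
        res = posterior_minus_prior_regression(probs, probs, lats)
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_southern_enrichment_negative_slope(self):
        lats = np.linspace(30, 48, 57)
        prior = np.full(57, 1 / 57.0)
        post = prior + 0.01 * (44 - lats) / 57
        post /= post.sum()
        res = posterior_minus_prior_regression(post, prior, lats)
        assert res.slope < 0


class TestExpDecline:
    @staticmethod
    def _series(rate, y0=2.0, years=range(1991, 2015)):
        return [SurveillanceRecord(year=y,
                                   beetles_per_aircraft=y0 * (1 - rate) ** (y - 1991))
                for y in years]

    def test_exact_fifteen_percent(self):
        fit = exp_decline_fit(self._series(0.15))
        assert fit.rate_percent == pytest.approx(15.0, abs=1e-9)

    def test_constant_series_zero(self):
        fit = exp_decline_fit(self._series(0.0))
        assert fit.rate_percent == pytest.approx(0.0, abs=1e-9)

    def test_missing_years_skipped(self):
        recs = self._series(0.15)
        recs[5] = SurveillanceRecord(year=recs[5].year,
                                     beetles_per_aircraft=None)
        fit = exp_decline_fit(recs)
        assert fit.n_used == 23
        assert fit.rate_percent == pytest.approx(15.0, abs=1e-9)

    def test_zero_years_dropped_with_sensitivity_variant(self):
        recs = self._series(0.15)
        recs[3] = SurveillanceRecord(year=recs[3].year,
                                     beetles_per_aircraft=0.0)
        fit = exp_decline_fit(recs)
        assert fit.n_dropped_zero == 1
        assert fit.rate_percent == pytest.approx(15.0, abs=0.2)
        assert fit.rate_percent_pseudocount is not None


class TestPriorRobustness:
    def test_identical_runs_slope_and_r2_one(self):
        t = np.random.default_rng(6).uniform(1, 50, 101)
        res = prior_robustness(t, t)
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_independent_times_r2_near_zero(self):
        rng = np.random.default_rng(7)
        res = prior_robustness(rng.uniform(1, 50, 500), rng.uniform(1, 50, 500))
        assert res.r_squared < 0.05
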