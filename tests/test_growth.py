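import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetalconn.growth import (
    SigmoidGrowthModel,
    bootstrap_compare,
    expansion_interval,
    fit_linear,
    fit_sigmoid,
    inflection,
    stage_assign,
    summary_ttest,
)


def _logistic(x, a, b, c, d):
    return d + c / (1 + np.exp(-(x - a) / b))


class TestLinearFit:
    def test_exact_line(self):
        x = np.linspace(21, 37, 10)
        fit = fit_linear(x, 2 * x + 1)
        assert fit.slope_ == pytest.approx(2.0)
        assert fit.intercept_ == pytest.approx(1.0)
        assert fit.sse_ == pytest.approx(0.0, abs=1e-18)
        assert fit.r2_ == pytest.approx(1.0)

    def test_null_limit(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(21, 37, 500)
        fit = fit_linear(x, rng.standard_normal(500))
        assert abs(fit.r2_) < 0.02

    def test_five_point_normal_equations_oracle(self):
        x = np.array([21.0, 25.0, 29.0, 33.0, 37.0])
        y = np.array([0.1, -0.2, 0.4, 0.35, 0.6])
        design = np.column_stack([x, np.ones(5)])
        slope, intercept = np.linalg.solve(design.T @ design, design.T @ y)
        fit = fit_linear(x, y)
        assert fit.slope_ == pytest.approx(slope, rel=1e-12)
        assert fit.intercept_ == pytest.approx(intercept, rel=1e-12)
        resid = y - fit.predict(x)
        assert fit.sse_ == pytest.approx((resid**2).sum())
        # adjusted R2 definition with p = 2
        assert fit.adj_r2_ == pytest.approx(1 - (1 - fit.r2_) * 4 / 2)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            fit_linear(np.full(6, 25.0), np.arange(6.0))


class TestSigmoidFit:
    def test_noiseless_recovery_of_printed_scale_parameters(self):
        x = np.arange(21.0, 38.0)
        y = _logistic(x, 26.59, 1.0, 0.5, -0.05)
        fit = fit_sigmoid(x, y, robust=False)
        assert fit.a_ == pytest.approx(26.59, abs=1e-4)
        assert fit.b_ == pytest.approx(1.0, abs=1e-4)
        assert fit.c_ == pytest.approx(0.5, abs=1e-4)
        assert fit.d_ == pytest.approx(-0.05, abs=1e-4)

    def test_robust_fit_resists_gross_outlier(self):
        x = np.arange(21.0, 38.0)
        y0 = _logistic(x, 26.59, 1.0, 0.5, -0.05)
        robust_wins = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            y = y0 + rng.normal(0, 0.02, x.size)
            y[rng.integers(x.size)] += 1.5
            err_r = abs(fit_sigmoid(x, y, robust=True).a_ - 26.59)
            err_p = abs(fit_sigmoid(x, y, robust=False).a_ - 26.59)
            robust_wins += int(err_r <= err_p)
        assert robust_wins >= 24  # paired comparison favours the robust fit

    def test_flat_data_flagged_degenerate(self):
        x = np.linspace(21, 37, 12)
        fit = fit_sigmoid(x, np.full(12, 0.2), robust=False)
        assert fit.degenerate_

    def test_sklearn_param_round_trip(self):
        model = SigmoidGrowthModel(robust=True)
        params = model.get_params()
        assert params["robust"] is True
        clone = SigmoidGrowthModel(**params)
        assert clone.get_params() == params


class TestInflection:
    def test_identity_with_parameter(self):
        x = np.arange(21.0, 38.0)
        fit = fit_sigmoid(x, _logistic(x, 26.589, 1.2, 0.5, -0.05), robust=False)
        assert inflection(fit) == pytest.approx(26.589, abs=1e-3)

    def test_numerical_argmax_of_derivative(self):
        x = np.arange(21.0, 38.0)
        fit = fit_sigmoid(x, _logistic(x, 27.2, 1.5, 0.4, 0.0), robust=False)
        grid = np.linspace(21, 37, 4001)
        deriv = np.gradient(fit.predict(grid), grid)
        assert grid[np.argmax(deriv)] == pytest.approx(inflection(fit), abs=grid[1] - grid[0])

    def test_shift_equivariance(self):
        x = np.arange(21.0, 38.0)
        y = _logistic(x, 26.0, 1.0, 0.5, 0.0)
        a0 = inflection(fit_sigmoid(x, y, robust=False))
        a1 = inflection(fit_sigmoid(x + 1.0, y, robust=False))
        assert a1 - a0 == pytest.approx(1.0, abs=1e-6)

    def test_linear_fit_not_applicable(self):
        fit = fit_linear(np.arange(21.0, 30.0), np.arange(9.0))
        with pytest.raises(ValueError):
            inflection(fit)


class TestExpansionInterval:
    def _fit(self, a=26.59, b=1.0):
        x = np.arange(21.0, 38.0)
        return fit_sigmoid(x, _logistic(x, a, b, 0.5, -0.05), robust=False)

    def test_closed_form_at_ninety_percent(self):
        lo, hi = expansion_interval(self._fit(), 0.9)
        half = 2 * np.arccosh(0.9**-0.5)
        assert half == pytest.approx(0.655, abs=1e-3)
        assert lo == pytest.approx(26.59 - half, abs=1e-3)
        assert hi == pytest.approx(26.59 + half, abs=1e-3)

    def test_fraction_half_closed_form(self):
        lo, hi = expansion_interval(self._fit(b=2.0), 0.5)
        assert (hi - lo) / 2 == pytest.approx(2 * 2.0 * np.arccosh(np.sqrt(2)), rel=1e-6)
        assert (hi - lo) / 2 == pytest.approx(1.7627 * 2.0, abs=2e-4)

    def test_interval_collapses_as_fraction_approaches_one(self):
        fit = self._fit()
        lo, hi = expansion_interval(fit, 0.999999)
        assert hi - lo < 0.01

    @settings(max_examples=40, deadline=None)
    @given(
        a=st.floats(24.0, 30.0),
        b=st.floats(0.5, 3.0),
        fraction=st.floats(0.5, 0.98),
    )
    def test_closed_form_matches_grid_search(self, a, b, fraction):
        fit = SigmoidGrowthModel(robust=False)
        x = np.linspace(21, 37, 30)
        fit.fit(x, _logistic(x, a, b, 0.5, 0.0))
        lo, hi = expansion_interval(fit, fraction)
        grid = np.arange(a - 12 * b, a + 12 * b, 1e-3)
        s = 1 / (1 + np.exp(-(grid - fit.a_) / fit.b_))
        deriv = fit.c_ / fit.b_ * s * (1 - s)
        above = grid[deriv >= fraction * fit.c_ / (4 * fit.b_)]
        assert above[0] == pytest.approx(lo, abs=2e-3)
        assert above[-1] == pytest.approx(hi, abs=2e-3)

    def test_zero_amplitude_rejected(self):
        x = np.linspace(21, 37, 12)
        fit = fit_sigmoid(x, np.full(12, 0.1), robust=False)
        with pytest.raises(ValueError):
            expansion_interval(fit, 0.9)


class TestBootstrapCompare:
    def test_seeded_draws_reproducible(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(21, 37, 24)
        y = _logistic(x, 26.5, 1.0, 0.5, 0.0) + rng.normal(0, 0.05, 24)
        a = bootstrap_compare(x, y, n_iter=120, seed=5, robust=False)
        b = bootstrap_compare(x, y, n_iter=120, seed=5, robust=False)
        assert np.array_equal(a.sigmoid_sse, b.sigmoid_sse)
        assert a.preferred_model == b.preferred_model

    def test_clear_sigmoid_truth_preferred(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(21, 37, 32)
        y = _logistic(x, 26.5, 1.0, 0.5, 0.0) + rng.normal(0, 0.05, 32)
        res = bootstrap_compare(x, y, n_iter=200, seed=2, robust=False)
        assert res.preferred_model == "sigmoid"
        assert res.p_value < 0.05

    def test_subsample_too_small_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_compare(np.linspace(21, 37, 8), np.zeros(8), n_iter=100, frac=0.5)

    def test_record_lengths_match_iterations(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(21, 37, 20)
        y = _logistic(x, 26.0, 1.0, 0.4, 0.0) + rng.normal(0, 0.08, 20)
        res = bootstrap_compare(x, y, n_iter=110, seed=1, robust=False)
        assert res.linear_sse.size + res.n_skipped == 110
        assert res.sigmoid_oos_sse.size == res.linear_oos_sse.size


class TestStageAssign:
    @pytest.mark.parametrize(
        "ga,stage",
        [(24.0, "pre"), (25.99, "pre"), (26.0, "expansion"), (28.99, "expansion"), (29.0, "post"), (33.5, "post")],
    )
    def test_boundaries(self, ga, stage):
        assert stage_assign(ga) == stage

    @pytest.mark.parametrize("ga", [20.9, 38.5])
    def test_out_of_range(self, ga):
        with pytest.raises(ValueError):
            stage_assign(ga)


class TestSummaryTtest:
    def test_matches_raw_data_ttest(self):
        # simulation oracle: summaries computed from raw samples reproduce
        # the two-sample pooled test on the raw data
        import scipy.stats

        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 40), rng.normal(0.4, 1.2, 55)
        res = summary_ttest(a.mean(), a.std(ddof=1), 40, b.mean(), b.std(ddof=1), 55)
        t, p = scipy.stats.ttest_ind(a, b, equal_var=True)
        assert res.t == pytest.approx(t, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-10)
        assert res.difference == pytest.approx(b.mean() - a.mean())

    def test_equal_groups_give_unit_p(self):
        res = summary_ttest(1.0, 0.5, 10, 1.0, 0.5, 10)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_zero_variance_identical_means_convention(self):
        res = summary_ttest(2.0, 0.0, 5, 2.0, 0.0, 5)
        assert res.p == 1.0

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            summary_ttest(0, 1, 1, 0, 1, 5)
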