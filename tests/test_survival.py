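"""Quasi-binomial logit-polynomial fitting against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

import lumispan as ls
from lumispan.survival import SaturatedModelError, SeparationError


def neg_log_likelihood(beta, t, n, y):
    eta = np.polynomial.polynomial.polyval(t, beta)
    p = expit(eta)
    return -np.sum(y * np.log(p) + (n - y) * np.log1p(-p))


def grid_refine_mle(t, n, y, b0_range, b1_range, n_grid=80):
    """Independent maximizer: coarse grid over (b0, b1), Nelder-Mead refine."""
    best, best_val = None, np.inf
    for b0 in np.linspace(*b0_range, n_grid):
        for b1 in np.linspace(*b1_range, n_grid):
            val = neg_log_likelihood((b0, b1), t, n, y)
            if val < best_val:
                best, best_val = (b0, b1), val
    res = minimize(
        neg_log_likelihood,
        best,
        args=(t, n, y),
        method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000},
    )
    return res.x


class TestFitLogisticSurvival:
    def test_flat_half_survival_gives_zero_coefficients(self):
        series = ls.SurvivalSeries([1, 2, 3], [100] * 3, [50] * 3)
        model = ls.fit_logistic_survival(series, ls.ModelConfig(degree=1))
        assert np.all(np.abs(model.coefficients) < 1e-8)

    def test_two_point_saturated_closed_form(self):
        # logit(0.8) = ln 4 at day 10, logit(0.2) = -ln 4 at day 20
        series = ls.SurvivalSeries([10, 20], [10, 10], [8, 2])
        model = ls.fit_logistic_survival(series, ls.ModelConfig(degree=1))
        assert model.coefficients[0] == pytest.approx(4.1589, abs=1e-4)
        assert model.coefficients[1] == pytest.approx(-0.27726, abs=1e-4)
        # saturated: the curve passes through every observed logit
        assert model.fitted_proportions == pytest.approx([0.8, 0.2], abs=1e-6)

    def test_matches_brute_force_likelihood_oracle(self, four_point_series):
        model = ls.fit_logistic_survival(
            four_point_series, ls.ModelConfig(degree=1)
        )
        oracle = grid_refine_mle(
            four_point_series.timepoints,
            four_point_series.n_scored,
            four_point_series.n_alive,
            b0_range=(0.0, 10.0),
            b1_range=(-1.0, 0.0),
        )
        assert model.coefficients == pytest.approx(oracle, abs=1e-3)

    def test_matches_statsmodels_glm(self, simulated_series):
        sm = pytest.importorskip("statsmodels.api")
        model = ls.fit_logistic_survival(
            simulated_series, ls.ModelConfig(degree=3)
        )
        t = simulated_series.timepoints
        X = np.vander((t - t.mean()) / t.std(), 4, increasing=True)
        endog = np.column_stack(
            [
                simulated_series.n_alive,
                simulated_series.n_scored - simulated_series.n_alive,
            ]
        )
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
        from lumispan.survival import _raw_scale_transform

        raw = _raw_scale_transform(3, t.mean(), t.std()) @ res.params
        assert model.coefficients == pytest.approx(raw, rel=1e-6, abs=1e-10)
        assert model.pearson_chi2 == pytest.approx(res.pearson_chi2, rel=1e-8)

    def test_saturated_consistency_cubic(self):
        # 4 interior proportions, 4 parameters: exact interpolation
        series = ls.SurvivalSeries(
            [5, 10, 15, 20], [50] * 4, [45, 35, 20, 5]
        )
        model = ls.fit_logistic_survival(series, ls.ModelConfig(degree=3))
        assert model.fitted_proportions == pytest.approx(
            series.proportions, abs=1e-8
        )

    def test_degree_other_than_1_or_3_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            ls.ModelConfig(degree=2)

    def test_all_alive_rejected(self):
        series = ls.SurvivalSeries([1, 2, 3], [10] * 3, [10] * 3)
        with pytest.raises(ValueError, match="all"):
            ls.fit_logistic_survival(series, ls.ModelConfig(degree=1))

    def test_separation_raises(self):
        # a perfect step at huge counts has unbounded likelihood
        series = ls.SurvivalSeries(
            [1, 2, 3, 4], [1000] * 4, [1000, 1000, 0, 0]
        )
        with pytest.raises(SeparationError):
            ls.fit_logistic_survival(series, ls.ModelConfig(degree=1))

    def test_fitted_proportions_interior_and_eta_finite(self, simulated_series):
        model = ls.fit_logistic_survival(
            simulated_series, ls.ModelConfig(degree=3)
        )
        assert model.converged
        p = model.fitted_proportions
        assert np.all((p > 0) & (p < 1))
        assert np.all(np.isfinite(model.linear_predictor(simulated_series.timepoints)))

    def test_parameter_recovery_within_wald_errors(self, cubic_curve):
        # large-sample fits recover the generating coefficients within
        # 3 Wald standard errors in at least 95% of seeds
        truth = np.zeros(4)
        truth[: len(cubic_curve.coefficients)] = cubic_curve.coefficients
        design_t = tuple(np.linspace(2, 30, 15))
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            design = ls.LifespanDesign(
                timepoints=design_t, n_per_timepoint=1000, seed=30_000 + s
            )
            series = ls.simulate_lifespan_series(cubic_curve, design)
            model = ls.fit_logistic_survival(series, ls.ModelConfig(degree=3))
            se = model.standard_errors()
            hits += bool(np.all(np.abs(model.coefficients - truth) <= 3 * se))
        assert hits / n_rep >= 0.95


class TestPredictSurvival:
    def test_half_at_zero_linear_predictor(self):
        series = ls.SurvivalSeries([10, 20], [10, 10], [8, 2])
        model = ls.fit_logistic_survival(series, ls.ModelConfig(degree=1))
        t_half = -model.coefficients[0] / model.coefficients[1]
        assert ls.predict_survival(model, t_half) == pytest.approx(0.5)

    def test_known_values(self):
        series = ls.SurvivalSeries([10, 20], [10, 10], [8, 2])
        model = ls.fit_logistic_survival(series, ls.ModelConfig(degree=1))
        assert ls.predict_survival(model, 10.0) == pytest.approx(0.8, abs=1e-4)

    def test_extrapolated_tail(self, linear_curve):
        series = ls.simulate_lifespan_series(
            linear_curve, ls.LifespanDesign(seed=8)
        )
        model = ls.fit_logistic_survival(series, ls.ModelConfig(degree=1))
        # inverse-logit(-5) for the generating curve at day 40
        assert expit(linear_curve.linear_predictor(40.0)) == pytest.approx(
            0.00669, abs=1e-5
        )
        assert 0 < ls.predict_survival(model, 40.0) < 1


class TestPearsonDispersion:
    def test_perfect_fit_floors_at_one(self):
        # interior proportions lying exactly on a logistic line
        t = np.array([5.0, 10.0, 15.0, 20.0])
        p = expit(5.0 - 0.25 * t)
        n = 400
        series = ls.SurvivalSeries(t, [n] * 4, np.round(n * p).astype(int))
        model = ls.fit_logistic_survival(series, ls.ModelConfig(degree=1))
        phi = ls.pearson_dispersion(model, series)
        assert phi == 1.0  # raw value ~0 is floored

    def test_hand_computed_statistic(self, four_point_series):
        model = ls.fit_logistic_survival(
            four_point_series, ls.ModelConfig(degree=1)
        )
        n = four_point_series.n_scored
        y = four_point_series.n_alive
        p = model.fitted_proportions
        by_hand = np.sum((y - n * p) ** 2 / (n * p * (1 - p))) / 2
        phi = ls.pearson_dispersion(
            model, four_point_series, dispersion_floor=0.0
        )
        assert phi == pytest.approx(by_hand, abs=1e-6)

    def test_covariance_scales_linearly_with_dispersion(self, four_point_series):
        # the worked series underdisperses, so the floor sets phi directly
        low = ls.fit_logistic_survival(
            four_point_series, ls.ModelConfig(degree=1, dispersion_floor=1.0)
        )
        high = ls.fit_logistic_survival(
            four_point_series, ls.ModelConfig(degree=1, dispersion_floor=2.0)
        )
        assert low.dispersion == 1.0 and high.dispersion == 2.0
        assert high.covariance == pytest.approx(2.0 * low.covariance)

    def test_saturated_fit_rejected(self):
        series = ls.SurvivalSeries([10, 20], [10, 10], [8, 2])
        model = ls.fit_logistic_survival(series, ls.ModelConfig(degree=1))
        with pytest.raises(SaturatedModelError, match="saturated"):
            ls.pearson_dispersion(model, series)
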