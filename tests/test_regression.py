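import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from fibergxe import (
    ConvergenceError,
    DomainError,
    SeparationError,
    ValidationError,
    fit_conditional_logistic,
    fit_logistic,
    likelihood_ratio_test,
    trend_test,
    wald_or_ci,
)


def paired_binary_design(n10, n01, n_concordant=5):
    """1:1 pairs discordant on one binary exposure, plus concordant filler."""
    rows, y, sets = [], [], []
    k = 0
    for count, case_exposed in ((n10, 1.0), (n01, 0.0)):
        for _ in range(count):
            rows += [[case_exposed], [1.0 - case_exposed]]
            y += [True, False]
            sets += [f"p{k}"] * 2
            k += 1
    for _ in range(n_concordant):
        rows += [[1.0], [1.0]]
        y += [True, False]
        sets += [f"p{k}"] * 2
        k += 1
    return pd.DataFrame(rows, columns=["exposed"]), np.array(y), np.array(sets)


def random_matched_data(rng, n_pairs=40, p=2):
    X = pd.DataFrame(rng.normal(size=(2 * n_pairs, p)), columns=[f"x{j}" for j in range(p)])
    sets = np.repeat([f"p{i}" for i in range(n_pairs)], 2)
    y = np.tile([True, False], n_pairs)
    return X, y, sets


class TestConditionalLogistic:
    def test_paired_binary_closed_form(self):
        """For pairs discordant on a binary covariate the MLE is log(n10/n01)."""
        X, y, sets = paired_binary_design(10, 5)
        fit = fit_conditional_logistic(X, y, sets)
        assert fit.converged
        assert fit.params["exposed"] == pytest.approx(np.log(2.0), abs=1e-8)

    def test_balanced_discordance_gives_zero(self):
        X, y, sets = paired_binary_design(7, 7)
        fit = fit_conditional_logistic(X, y, sets)
        assert fit.params["exposed"] == pytest.approx(0.0, abs=1e-8)

    def test_all_concordant_not_identified(self):
        X, y, sets = paired_binary_design(0, 0, n_concordant=10)
        with pytest.raises(ValidationError, match="constant within"):
            fit_conditional_logistic(X, y, sets)

    def test_set_without_case_rejected(self):
        X = pd.DataFrame({"x": [1.0, 0.0]})
        with pytest.raises(ValidationError, match="exactly 1 case"):
            fit_conditional_logistic(X, [False, False], ["p0", "p0"])

    def test_matches_pair_difference_likelihood(self):
        """1:1 conditional fit equals the intercept-free logistic on differences."""
        rng = np.random.default_rng(5)
        X, y, sets = random_matched_data(rng, n_pairs=60)
        fit = fit_conditional_logistic(X, y, sets)
        diffs = X.to_numpy()[::2] - X.to_numpy()[1::2]  # case minus control

        def negll(beta):
            return np.sum(np.logaddexp(0.0, -diffs @ beta))

        res = optimize.minimize(negll, np.zeros(X.shape[1]), method="BFGS", tol=1e-12)
        np.testing.assert_allclose(fit.params.to_numpy(), res.x, atol=1e-6)
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-8)

    def test_oracle_agreement_statsmodels(self):
        """Coefficients and SEs match statsmodels ConditionalLogit."""
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(11)
        for _ in range(10):
            X, y, sets = random_matched_data(rng, n_pairs=30)
            fit = fit_conditional_logistic(X, y, sets)
            oracle = ConditionalLogit(y.astype(float), X, groups=sets).fit(
                method="newton", disp=False
            )
            np.testing.assert_allclose(fit.params.to_numpy(), oracle.params, rtol=1e-6)
            np.testing.assert_allclose(fit.bse.to_numpy(), oracle.bse, rtol=1e-6)

    def test_loglik_trace_monotone(self):
        rng = np.random.default_rng(3)
        X, y, sets = random_matched_data(rng, n_pairs=50, p=3)
        fit = fit_conditional_logistic(X, y, sets)
        assert np.all(np.diff(fit.ll_trace) >= -1e-10)
        assert fit.loglik <= 0.0


class TestLogistic:
    def test_two_by_two_closed_form(self):
        """The saturated 2x2 fit reproduces the empirical odds ratio 4.0."""
        exposed = np.r_[np.ones(30), np.zeros(30)]
        y = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)].astype(bool)
        fit = fit_logistic(pd.DataFrame({"exposed": exposed}), y)
        assert np.exp(fit.params["exposed"]) == pytest.approx(4.0, rel=1e-6)

    def test_null_covariate_coefficient_near_zero(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"x": np.r_[np.ones(50), -np.ones(50)]})
        y = np.tile([True, False], 50)
        fit = fit_logistic(X, y)
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0]}), [True, True])

    def test_separation_reported_with_covariate(self):
        x = np.r_[np.linspace(1, 2, 20), np.linspace(-2, -1, 20)]
        y = x > 0
        with pytest.raises(SeparationError) as err:
            fit_logistic(pd.DataFrame({"sep_var": x}), y)
        assert err.value.covariate in ("sep_var", "const")

    def test_oracle_agreement_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(13)
        for _ in range(10):
            X = pd.DataFrame(rng.normal(size=(120, 3)), columns=list("abc"))
            eta = 0.3 * X["a"] - 0.5 * X["b"]
            y = rng.random(120) < 1 / (1 + np.exp(-eta))
            fit = fit_logistic(X, y)
            oracle = sm.Logit(y.astype(float), sm.add_constant(X)).fit(disp=False)
            np.testing.assert_allclose(fit.params.to_numpy(), oracle.params, rtol=1e-6)
            np.testing.assert_allclose(fit.bse.to_numpy(), oracle.bse, rtol=1e-6)


class TestWaldAndLrt:
    def test_wald_interval_values(self):
        fit = _dummy_fit({"x": 0.0}, {"x": 0.1})
        or_, lo, hi = wald_or_ci(fit, "x")
        assert or_ == pytest.approx(1.0)
        assert lo == pytest.approx(np.exp(-1.96 * 0.1), abs=1e-3)
        assert hi == pytest.approx(np.exp(1.96 * 0.1), abs=1e-3)

    def test_wald_point_estimate(self):
        fit = _dummy_fit({"x": np.log(2.0)}, {"x": 0.7})
        assert wald_or_ci(fit, "x")[0] == pytest.approx(2.0)

    def test_wider_at_higher_level(self):
        fit = _dummy_fit({"x": 0.5}, {"x": 0.2})
        _, lo95, hi95 = wald_or_ci(fit, "x", 0.95)
        _, lo99, hi99 = wald_or_ci(fit, "x", 0.99)
        assert lo99 < lo95 and hi99 > hi95

    def test_identical_models_vacuous(self):
        fit = _dummy_fit({"x": 0.5}, {"x": 0.2}, loglik=-10.0)
        stat, df, p = likelihood_ratio_test(fit, fit)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_chi_square_tail_value(self):
        full = _dummy_fit({"x": 0.5, "z": 0.1}, {"x": 0.2, "z": 0.2}, loglik=-10.0)
        reduced = _dummy_fit({"x": 0.5}, {"x": 0.2}, loglik=-10.0 - 3.84 / 2)
        stat, df, p = likelihood_ratio_test(full, reduced)
        assert (stat, df) == (pytest.approx(3.84), 1)
        assert p == pytest.approx(0.050, abs=0.001)

    def test_non_nested_rejected(self):
        a = _dummy_fit({"x": 0.5}, {"x": 0.2})
        b = _dummy_fit({"z": 0.5}, {"z": 0.2})
        with pytest.raises(ValidationError):
            likelihood_ratio_test(a, b)

    def test_lr_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(21)
        X = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
        y = rng.random(200) < 1 / (1 + np.exp(-(0.5 * X["a"])))
        full = fit_logistic(X, y)
        reduced = fit_logistic(X[["b"]], y)
        stat1, _, _ = likelihood_ratio_test(full, reduced)
        X2 = X.copy()
        X2["a"] = 100.0 * X2["a"] - 7.0
        X2["b"] = 0.01 * X2["b"] + 3.0
        stat2, _, _ = likelihood_ratio_test(fit_logistic(X2, y), fit_logistic(X2[["b"]], y))
        assert stat2 == pytest.approx(stat1, rel=1e-6)


class TestTrendTest:
    def test_monotone_dose_response_detected(self):
        rng = np.random.default_rng(8)
        n = 1200
        quartile = rng.integers(1, 5, size=n)
        medians = {1: 5.0, 2: 8.0, 3: 10.0, 4: 13.0}
        score = np.array([medians[q] for q in quartile])
        y = rng.random(n) < 1 / (1 + np.exp(-(-1.5 + 0.3 * (score - 9))))
        adjust = pd.DataFrame(index=range(n))
        p = trend_test(adjust, y, quartile, medians)
        assert p < 0.01

    def test_null_trend_not_significant(self):
        rng = np.random.default_rng(10)
        n = 1200
        quartile = rng.integers(1, 5, size=n)
        medians = {1: 5.0, 2: 8.0, 3: 10.0, 4: 13.0}
        y = rng.random(n) < 0.3
        p = trend_test(pd.DataFrame(index=range(n)), y, quartile, medians)
        assert p > 0.05

    def test_identical_medians_rejected(self):
        with pytest.raises(DomainError):
            trend_test(
                pd.DataFrame(index=range(4)),
                [True, False, True, False],
                [1, 2, 3, 4],
                {1: 9.0, 2: 9.0, 3: 9.0, 4: 9.0},
            )

    def test_lr_variant_agrees_in_order_of_magnitude(self):
        rng = np.random.default_rng(10)
        n = 800
        quartile = rng.integers(1, 5, size=n)
        medians = {1: 5.0, 2: 8.0, 3: 10.0, 4: 13.0}
        score = np.array([medians[q] for q in quartile])
        y = rng.random(n) < 1 / (1 + np.exp(-(0.15 * (score - 9))))
        adjust = pd.DataFrame(index=range(n))
        p_wald = trend_test(adjust, y, quartile, medians, statistic="wald")
        p_lr = trend_test(adjust, y, quartile, medians, statistic="lr")
        assert np.log10(p_wald) == pytest.approx(np.log10(p_lr), abs=0.5)


def _dummy_fit(params, ses, loglik=-1.0):
    from fibergxe.regression import FitResult

    names = list(params)
    cov = pd.DataFrame(np.diag([ses[c] ** 2 for c in names]), index=names, columns=names)
    return FitResult(
        params=pd.Series(params),
        cov=cov,
        loglik=loglik,
        converged=True,
        n_iter=1,
        n_obs=100,
        model="logit",
        ll_trace=np.array([loglik]),
    )
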