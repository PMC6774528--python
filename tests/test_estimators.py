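"""Maximum-likelihood estimators: probit, truncated normal, Tobit, double hurdle."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr, ndtri

from btcoi.estimators import (
    CraggDoubleHurdle,
    PerfectSeparationError,
    ProbitModel,
    RankDeficientError,
    TobitRegression,
    TruncatedNormalRegression,
    probit_negll,
    probit_score,
    tobit_negll,
    tobit_score,
    truncated_negll,
    truncated_score,
)
from conftest import simple_hurdle_data


# ---------------------------------------------------------------------------
# analytic scores vs numerical differentiation of the objectives
# ---------------------------------------------------------------------------

def _num_grad(f, x, h=1e-6):
    g = np.empty_like(x)
    for j in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        g[j] = (f(xp) - f(xm)) / (2 * h)
    return g


@pytest.mark.parametrize("which", ["probit", "truncated", "tobit"])
def test_analytic_score_matches_numerical_gradient(which):
    rng = np.random.default_rng(3)
    n = 150
    X = np.column_stack([np.ones(n), rng.standard_normal(n),
                         rng.binomial(1, 0.4, n)])
    if which == "probit":
        y = rng.binomial(1, 0.6, n).astype(float)
        for _ in range(5):
            theta = rng.normal(scale=0.7, size=3)
            np.testing.assert_allclose(
                probit_score(theta, X, y),
                _num_grad(lambda t: probit_negll(t, X, y), theta),
                rtol=1e-5, atol=1e-5)
    elif which == "truncated":
        q = np.abs(rng.normal(3.0, 1.0, n)) + 0.1
        for _ in range(5):
            theta = np.append(rng.normal(scale=0.5, size=3) + [3, 0, 0], 0.3)
            np.testing.assert_allclose(
                truncated_score(theta, X, q),
                _num_grad(lambda t: truncated_negll(t, X, q), theta),
                rtol=1e-5, atol=1e-5)
    else:
        y = np.maximum(rng.normal(0.5, 1.5, n), 0.0)
        for _ in range(5):
            theta = np.append(rng.normal(scale=0.5, size=3), 0.2)
            np.testing.assert_allclose(
                tobit_score(theta, X, y),
                _num_grad(lambda t: tobit_negll(t, X, y), theta),
                rtol=1e-5, atol=1e-5)


# ---------------------------------------------------------------------------
# probit
# ---------------------------------------------------------------------------

class TestProbit:
    @pytest.mark.parametrize("p", [0.5, 0.3, 0.8])
    def test_intercept_only_recovers_quantile(self, p):
        # with an intercept-only design the MLE is gamma0 = Phi^-1(mean)
        n = 1000
        y = np.zeros(n)
        y[: int(p * n)] = 1.0
        m = ProbitModel(fit_intercept=False).fit(np.ones((n, 1)), y)
        assert m.params_[0] == pytest.approx(ndtri(y.mean()), abs=1e-7)

    def test_intercept_only_beats_grid(self):
        """1-D brute-force oracle: no grid point improves on the MLE."""
        rng = np.random.default_rng(0)
        y = rng.binomial(1, 0.37, 400).astype(float)
        X = np.ones((400, 1))
        m = ProbitModel(fit_intercept=False).fit(X, y)
        ll_hat = m.llf_
        for g0 in np.linspace(-2, 2, 161):
            assert -probit_negll(np.array([g0]), X, y) <= ll_hat + 1e-10

    def test_parameter_recovery(self):
        rng = np.random.default_rng(5)
        n = 5000
        X = np.column_stack([rng.standard_normal(n), rng.binomial(1, 0.5, n)])
        g = np.array([0.3, -0.8, 0.5])
        y = (g[0] + X @ g[1:] + rng.standard_normal(n) > 0).astype(float)
        m = ProbitModel().fit(X, y)
        np.testing.assert_array_less(np.abs(m.params_ - g), 3 * m.se_)

    def test_matches_reference_implementation(self):
        sm = pytest.importorskip("statsmodels.api")
        for seed in (0, 1):
            rng = np.random.default_rng(seed)
            n = 400
            X = np.column_stack([rng.standard_normal(n),
                                 rng.binomial(1, 0.5, n)])
            y = (0.2 - 0.7 * X[:, 0] + 0.4 * X[:, 1]
                 + rng.standard_normal(n) > 0).astype(float)
            m = ProbitModel().fit(X, y)
            ref = sm.Probit(y, sm.add_constant(X)).fit(
                disp=0, method="newton", tol=1e-12)
            np.testing.assert_allclose(m.params_, ref.params, atol=1e-6)

    def test_single_class_outcome_refused(self):
        with pytest.raises(PerfectSeparationError):
            ProbitModel().fit(np.random.default_rng(0).normal(size=(50, 2)),
                              np.ones(50))

    def test_perfect_separation_detected(self):
        x = np.linspace(-2, 2, 100)[:, None]
        y = (x.ravel() > 0).astype(float)
        with pytest.raises(PerfectSeparationError):
            ProbitModel().fit(x, y)

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"a": rng.standard_normal(100)})
        X["b"] = 2.0 * X["a"]
        y = rng.binomial(1, 0.5, 100).astype(float)
        with pytest.raises(RankDeficientError, match="[ab]"):
            ProbitModel().fit(X, y)


# ---------------------------------------------------------------------------
# truncated normal regression
# ---------------------------------------------------------------------------

class TestTruncatedNormal:
    def test_negligible_truncation_limit_matches_ols(self):
        # data far from zero with small noise: truncation irrelevant
        rng = np.random.default_rng(2)
        n = 2000
        x = rng.standard_normal(n)
        q = 50.0 + 3.0 * x + 0.5 * rng.standard_normal(n)
        m = TruncatedNormalRegression().fit(x[:, None], q)
        ols = np.polyfit(x, q, 1)
        assert m.intercept_ == pytest.approx(ols[1], abs=1e-3)
        assert m.coef_[0] == pytest.approx(ols[0], abs=1e-3)
        assert m.sigma_ == pytest.approx(0.5, rel=0.05)

    def test_intercept_only_beats_grid(self):
        """2-D grid oracle around the MLE of (beta0, sigma)."""
        rng = np.random.default_rng(3)
        lat = rng.normal(1.0, 2.0, 500)
        q = lat[lat > 0]
        Z = np.ones((q.size, 1))
        m = TruncatedNormalRegression(fit_intercept=False).fit(Z, q)
        for b0 in np.linspace(m.params_[0] - 1.5, m.params_[0] + 1.5, 21):
            for s in np.linspace(max(m.sigma_ - 1, 0.2), m.sigma_ + 1, 21):
                ll = -truncated_negll(np.array([b0, np.log(s)]), Z, q)
                assert ll <= m.llf_ + 1e-9

    def test_parameter_recovery_with_heavy_truncation(self):
        rng = np.random.default_rng(4)
        n = 20000
        x = rng.standard_normal(n)
        lat = 0.5 + 1.0 * x + 2.0 * rng.standard_normal(n)
        keep = lat > 0  # ~55% truncated away at x=0
        m = TruncatedNormalRegression().fit(x[keep][:, None], lat[keep])
        se = m.se_
        est = np.append(m.params_, m.sigma_)
        for e, t, s in zip(est, [0.5, 1.0, 2.0], [se[0], se[1], m.sigma_ * se[2]]):
            assert abs(e - t) < 3 * s

    def test_non_positive_outcome_refused(self):
        with pytest.raises(ValueError, match="positive"):
            TruncatedNormalRegression().fit(np.ones((10, 1)),
                                            np.array([1.0] * 9 + [0.0]))


# ---------------------------------------------------------------------------
# Tobit
# ---------------------------------------------------------------------------

class TestTobit:
    def test_without_censoring_equals_normal_mle(self):
        rng = np.random.default_rng(6)
        n = 1500
        x = rng.standard_normal(n)
        y = 20.0 + 2.0 * x + 1.5 * rng.standard_normal(n)  # never near 0
        assert (y > 0).all()
        m = TobitRegression().fit(x[:, None], y)
        ols = np.polyfit(x, y, 1)
        assert m.intercept_ == pytest.approx(ols[1], abs=1e-6)
        assert m.coef_[0] == pytest.approx(ols[0], abs=1e-6)
        resid = y - (m.intercept_ + m.coef_[0] * x)
        assert m.sigma_ == pytest.approx(np.sqrt(np.mean(resid**2)), rel=1e-6)

    def test_parameter_recovery_under_tobit_dgp(self):
        rng = np.random.default_rng(7)
        n = 4000
        X = np.column_stack([rng.standard_normal(n), rng.binomial(1, 0.5, n)])
        b = np.array([0.4, 1.0, -0.8])
        y = np.maximum(b[0] + X @ b[1:] + 1.2 * rng.standard_normal(n), 0.0)
        m = TobitRegression().fit(X, y)
        np.testing.assert_array_less(np.abs(m.params_ - b), 3 * m.se_[:-1])

    def test_all_zero_outcome_refused(self):
        with pytest.raises(ValueError, match="identically zero"):
            TobitRegression().fit(np.ones((10, 1)), np.zeros(10))

    def test_nested_in_double_hurdle(self):
        """On any dataset ll_tobit <= ll of the double hurdle."""
        for seed in (0, 1, 2):
            X, qh, *_ = simple_hurdle_data(seed, n=500)
            dh_fit = CraggDoubleHurdle().fit(X, qh)
            tob = TobitRegression().fit(X, qh)
            assert tob.llf_ <= dh_fit.ll_ + 1e-8


# ---------------------------------------------------------------------------
# double hurdle
# ---------------------------------------------------------------------------

class TestCraggDoubleHurdle:
    def test_loglik_is_sum_of_components(self):
        X, qh, *_ = simple_hurdle_data(10)
        f = CraggDoubleHurdle().fit(X, qh)
        assert f.ll_ == pytest.approx(f.ll_probit_ + f.ll_truncated_, abs=1e-10)
        assert f.n_positive_ <= f.n_obs_
        assert f.sigma_ > 0

    def test_joint_maximization_agrees_with_two_stage(self):
        X, qh, *_ = simple_hurdle_data(11)
        two = CraggDoubleHurdle().fit(X, qh)
        joint = CraggDoubleHurdle(method="joint").fit(X, qh)
        assert joint.ll_ == pytest.approx(two.ll_, abs=1e-6)
        np.testing.assert_allclose(joint.gamma_, two.gamma_, atol=1e-5)
        np.testing.assert_allclose(joint.beta_, two.beta_, atol=1e-4)

    def test_inconsistent_indicator_rejected(self):
        X, qh, *_ = simple_hurdle_data(12)
        dh_bad = (qh > 0).astype(float)
        dh_bad[0] = 1.0 - dh_bad[0]
        with pytest.raises(ValueError, match="inconsistent"):
            CraggDoubleHurdle().fit(X, qh, dh=dh_bad)

    def test_all_positive_outcome_refuses_first_hurdle(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((200, 2))
        qh = np.abs(rng.normal(10, 1, 200)) + 1
        with pytest.raises(PerfectSeparationError):
            CraggDoubleHurdle().fit(X, qh)

    def test_scale_invariance_of_hurdle2_covariate(self):
        """Rescaling a covariate by c divides its beta by c, ll unchanged."""
        X, qh, *_ = simple_hurdle_data(14)
        f1 = CraggDoubleHurdle().fit(X, qh)
        X2 = X.copy()
        X2["x1"] = X2["x1"] * 10.0
        f2 = CraggDoubleHurdle().fit(X2, qh)
        assert f2.ll_ == pytest.approx(f1.ll_, abs=1e-6)
        j = 1 + list(X.columns).index("x1")
        assert f2.beta_[j] == pytest.approx(f1.beta_[j] / 10.0, rel=1e-5)
        assert f2.gamma_[j] == pytest.approx(f1.gamma_[j] / 10.0, rel=1e-5)

    def test_parameter_recovery(self):
        X, qh, g, b, sigma = simple_hurdle_data(15, n=5000)
        f = CraggDoubleHurdle().fit(X, qh)
        np.testing.assert_allclose(f.gamma_, g, atol=0.12)
        np.testing.assert_allclose(f.beta_, b, atol=0.15)
        assert f.sigma_ == pytest.approx(sigma, rel=0.06)

    def test_predictions_compose(self):
        X, qh, *_ = simple_hurdle_data(16)
        f = CraggDoubleHurdle().fit(X, qh)
        np.testing.assert_allclose(
            f.predict(X),
            f.predict_treatment_proba(X) * f.predict_conditional_cost(X))
        p = f.predict_treatment_proba(X)
        assert ((p >= 0) & (p <= 1)).all()
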