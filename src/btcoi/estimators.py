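"""Maximum-likelihood estimators for zero-inflated cost outcomes.

scikit-learn style estimators:

* :class:`ProbitModel` — binary probit (hurdle 1: does the farmer incur any
  treatment cost?).
* :class:`TruncatedNormalRegression` — zero-truncated normal regression
  (hurdle 2: the positive cost level).
* :class:`TobitRegression` — type-I Tobit, left-censored at zero (the
  restricted alternative in the specification test).
* :class:`CraggDoubleHurdle` — the two combined. With independent hurdle
  errors the joint likelihood separates, so the MLE is the probit fit on all
  observations plus the truncated fit on the positive subsample, and the
  model log-likelihood is the sum of the two components. A direct joint
  maximization over (gamma, beta, log sigma) is available via
  ``method="joint"`` and agrees with the two-stage route to optimizer
  tolerance.

All three likelihoods use analytic gradients; covariance matrices come from
the inverse observed information (finite-difference Hessian of the analytic
score). Optimization is BFGS from a couple of data-driven starts followed by
safeguarded Newton polishing down to a gradient-norm tolerance.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import qr as _qr
from scipy.optimize import minimize
from scipy.special import log_ndtr, ndtr
from sklearn.base import BaseEstimator

from ._stats import inverse_mills, norm_logpdf, numerical_hessian

__all__ = [
    "ProbitModel",
    "TruncatedNormalRegression",
    "TobitRegression",
    "CraggDoubleHurdle",
    "PerfectSeparationError",
    "RankDeficientError",
]


class PerfectSeparationError(RuntimeError):
    """Raised when the probit outcome is perfectly predicted."""


class RankDeficientError(ValueError):
    """Raised when a design matrix is not of full column rank."""


# ---------------------------------------------------------------------------
# shared machinery
# ---------------------------------------------------------------------------

def _as_design(X, fit_intercept, feature_names=None):
    """Return (design with optional intercept column first, names)."""
    if hasattr(X, "columns"):
        feature_names = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    if fit_intercept:
        X = np.column_stack([np.ones(X.shape[0]), X])
        names = ["const"] + list(feature_names)
    else:
        names = list(feature_names)
    return X, names


def _check_rank(X, names):
    r, p = np.linalg.matrix_rank(X), X.shape[1]
    if r < p:
        # QR with pivoting: columns associated with ~zero R diagonal
        _, R, piv = _qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in piv[diag < tol]] or [names[j] for j in piv[r:]]
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {r} < {p}); "
            f"offending column(s): {bad}"
        )


def _column_scales(D):
    """Per-column scale factors for optimizer conditioning (1 for constant
    columns, i.e. the intercept)."""
    s = D.std(axis=0)
    s[s <= 0] = 1.0
    return s


def _maximize(negll, grad, starts, gtol=1e-8, max_newton=60):
    """Minimize ``negll`` with BFGS from several starts, then Newton-polish
    (finite-difference Hessian of the analytic gradient). Convergence is a
    gradient norm below ``gtol`` relative to the objective scale (callers
    pass standardized designs, so the criterion is meaningful).
    Returns (x, fun, n_iter, converged)."""
    best = None
    for x0 in starts:
        res = minimize(negll, np.asarray(x0, dtype=float), jac=grad,
                       method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
        if best is None or res.fun < best.fun:
            best = res
    x, n_iter = best.x.copy(), int(best.nit)

    def tol_at(fx):
        return gtol * max(1.0, abs(fx))

    for _ in range(max_newton):
        g = np.asarray(grad(x))
        if np.linalg.norm(g, ord=np.inf) < tol_at(negll(x)):
            break
        H = numerical_hessian(grad, x)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = g
        # backtracking: accept a step that lowers the objective, or one that
        # leaves it within floating-point noise while shrinking the gradient
        # (near the optimum the objective resolution limits what a correct
        # Newton step can show)
        f0, t = negll(x), 1.0
        g_norm = np.linalg.norm(g, ord=np.inf)
        f_noise = 1e-12 * max(1.0, abs(f0))
        improved = False
        for _ in range(40):
            xn = x - t * step
            fn = negll(xn)
            if np.isfinite(fn) and (
                fn < f0
                or (fn <= f0 + f_noise
                    and np.linalg.norm(np.asarray(grad(xn)), ord=np.inf)
                    < 0.5 * g_norm)
            ):
                improved = True
                break
            t *= 0.5
        if not improved:
            break  # at the floating-point optimum
        x = xn
        n_iter += 1
    fx = float(negll(x))
    converged = (np.linalg.norm(np.asarray(grad(x)), ord=np.inf)
                 < max(tol_at(fx), 1e-6))
    return x, fx, n_iter, bool(converged)


def _vcov_from_grad(grad, x):
    """Inverse observed information; NaN matrix if not invertible."""
    H = numerical_hessian(grad, x)  # Hessian of the *negative* ll
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full((x.size, x.size), np.nan)


# ---------------------------------------------------------------------------
# probit
# ---------------------------------------------------------------------------

def probit_negll(params, X, y):
    t = X @ params
    return -float(y @ log_ndtr(t) + (1.0 - y) @ log_ndtr(-t))


def probit_score(params, X, y):
    """Gradient of the *negative* log-likelihood."""
    t = X @ params
    g = y * inverse_mills(t) - (1.0 - y) * inverse_mills(-t)
    return -(X.T @ g)


class ProbitModel(BaseEstimator):
    """Binary probit regression by maximum likelihood.

    Parameters
    ----------
    fit_intercept : bool, default True
        Prepend a constant column to the design.
    gtol : float, default 1e-8
        Gradient-norm convergence tolerance.

    Attributes
    ----------
    params_ : ndarray, full coefficient vector (intercept first if fitted).
    coef_, intercept_ : sklearn-style split of ``params_``.
    llf_ : float, maximized log-likelihood.
    vcov_ : ndarray, inverse observed information.
    se_ : ndarray, standard errors.
    feature_names_ : list of str, names aligned with ``params_``.
    """

    def __init__(self, fit_intercept=True, gtol=1e-8):
        self.fit_intercept = fit_intercept
        self.gtol = gtol

    def fit(self, X, y):
        X, names = _as_design(X, self.fit_intercept)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("probit outcome must be binary 0/1")
        if y.min() == y.max():
            raise PerfectSeparationError(
                "outcome takes a single value; the first hurdle is degenerate"
            )
        _check_rank(X, names)

        # optimize on a column-standardized design for conditioning
        scales = _column_scales(X)
        Xs = X / scales
        # starts: zeros and the classic OLS-on-(2y-1) inspired initial
        ols = np.linalg.lstsq(Xs, 2.5 * (2.0 * y - 1.0), rcond=None)[0]
        xs, negll_val, n_iter, converged = _maximize(
            lambda b: probit_negll(b, Xs, y),
            lambda b: probit_score(b, Xs, y),
            [np.zeros(X.shape[1]), ols],
            gtol=self.gtol,
        )
        x = xs / scales
        p = ndtr(X @ x)
        correct = np.where(y == 1.0, p, 1.0 - p)
        if correct.min() > 1.0 - 1e-10:
            raise PerfectSeparationError(
                "perfect separation detected: all outcomes predicted with "
                "probability 1"
            )
        self.params_ = x
        self.feature_names_ = names
        self.llf_ = -negll_val
        self.vcov_ = _vcov_from_grad(lambda b: probit_score(b, X, y), x)
        self.se_ = np.sqrt(np.diag(self.vcov_))
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_obs_ = int(y.size)
        if self.fit_intercept:
            self.intercept_, self.coef_ = x[0], x[1:]
        else:
            self.intercept_, self.coef_ = 0.0, x
        return self

    def decision_function(self, X):
        X, _ = _as_design(X, self.fit_intercept)
        return X @ self.params_

    def predict_proba(self, X):
        p1 = ndtr(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


# ---------------------------------------------------------------------------
# zero-truncated normal regression
# ---------------------------------------------------------------------------

def truncated_negll(params, Z, q):
    b, s = params[:-1], np.exp(params[-1])
    e = (q - Z @ b) / s
    a = (Z @ b) / s
    ll = norm_logpdf(e) - np.log(s) - log_ndtr(a)
    return -float(ll.sum())


def truncated_score(params, Z, q):
    b, s = params[:-1], np.exp(params[-1])
    e = (q - Z @ b) / s
    a = (Z @ b) / s
    lam = inverse_mills(a)
    gb = (Z.T @ (e - lam)) / s
    gs = float(np.sum(e * e - 1.0 + a * lam))  # wrt log sigma
    return -np.concatenate([gb, [gs]])


class TruncatedNormalRegression(BaseEstimator):
    """Regression for strictly positive outcomes under zero truncation.

    The outcome is N(z'beta, sigma^2) conditioned on being positive;
    the conditional mean is z'beta + sigma * lambda(z'beta / sigma) with
    lambda the inverse Mills ratio. Internally parameterized in log sigma.

    Attributes: ``coef_``, ``intercept_``, ``params_`` (beta), ``sigma_``,
    ``llf_``, ``vcov_`` (beta and log sigma), ``se_``, ``converged_``.
    """

    def __init__(self, fit_intercept=True, gtol=1e-8):
        self.fit_intercept = fit_intercept
        self.gtol = gtol

    def fit(self, Z, q):
        Z, names = _as_design(Z, self.fit_intercept)
        q = np.asarray(q, dtype=float).ravel()
        if q.shape[0] != Z.shape[0]:
            raise ValueError("Z and q have incompatible shapes")
        if np.any(q <= 0):
            raise ValueError(
                "truncated regression requires strictly positive outcomes; "
                f"{int(np.sum(q <= 0))} non-positive value(s) found"
            )
        _check_rank(Z, names)

        # standardize columns and the outcome for optimizer conditioning
        scales = _column_scales(Z)
        ysd = q.std() if q.std() > 0 else 1.0
        Zs, qs = Z / scales, q / ysd
        ols = np.linalg.lstsq(Zs, qs, rcond=None)[0]
        resid = qs - Zs @ ols
        s0 = max(resid.std(), 1e-3)
        start = np.concatenate([ols, [np.log(s0)]])
        xs, negll_val, n_iter, converged = _maximize(
            lambda t: truncated_negll(t, Zs, qs),
            lambda t: truncated_score(t, Zs, qs),
            [start],
            gtol=self.gtol,
        )
        x = np.concatenate([xs[:-1] * ysd / scales, [xs[-1] + np.log(ysd)]])
        self.params_ = x[:-1]
        self.sigma_ = float(np.exp(x[-1]))
        self.feature_names_ = names
        # density of the scaled outcome: ll(q) = ll(q/ysd) - n log(ysd)
        self.llf_ = -negll_val - q.size * np.log(ysd)
        self.vcov_ = _vcov_from_grad(lambda t: truncated_score(t, Z, q), x)
        self.se_ = np.sqrt(np.diag(self.vcov_))
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_obs_ = int(q.size)
        if self.fit_intercept:
            self.intercept_, self.coef_ = x[0], x[1:-1]
        else:
            self.intercept_, self.coef_ = 0.0, x[:-1]
        if not converged:
            import warnings

            warnings.warn(
                "truncated regression did not reach gradient tolerance; "
                "parameters returned as-is",
                RuntimeWarning,
            )
        return self

    def predict(self, Z):
        """Conditional mean given positivity: z'b + sigma lambda(z'b/sigma)."""
        Z, _ = _as_design(Z, self.fit_intercept)
        xb = Z @ self.params_
        return xb + self.sigma_ * inverse_mills(xb / self.sigma_)


# ---------------------------------------------------------------------------
# Tobit (type I, left-censored at zero)
# ---------------------------------------------------------------------------

def tobit_negll(params, Z, y):
    b, s = params[:-1], np.exp(params[-1])
    xb = Z @ b
    a = xb / s
    pos = y > 0
    ll = np.where(pos, norm_logpdf((y - xb) / s) - np.log(s), log_ndtr(-a))
    return -float(ll.sum())


def tobit_score(params, Z, y):
    b, s = params[:-1], np.exp(params[-1])
    xb = Z @ b
    a = xb / s
    pos = y > 0
    e = np.where(pos, (y - xb) / s, 0.0)
    lam0 = inverse_mills(-a)
    gi = np.where(pos, e, -lam0) / s
    gb = Z.T @ gi
    gs = float(np.sum(np.where(pos, e * e - 1.0, a * lam0)))  # wrt log sigma
    return -np.concatenate([gb, [gs]])


class TobitRegression(BaseEstimator):
    """Type-I Tobit: one coefficient vector drives both the probability of a
    positive outcome and its level (the double-hurdle restriction
    gamma = beta / sigma). Left-censoring point fixed at zero.

    Attributes mirror :class:`TruncatedNormalRegression`.
    """

    def __init__(self, fit_intercept=True, gtol=1e-8):
        self.fit_intercept = fit_intercept
        self.gtol = gtol

    def fit(self, Z, y):
        Z, names = _as_design(Z, self.fit_intercept)
        y = np.asarray(y, dtype=float).ravel()
        if y.shape[0] != Z.shape[0]:
            raise ValueError("Z and y have incompatible shapes")
        if np.any(y < 0):
            raise ValueError("Tobit outcome must be non-negative")
        if np.all(y == 0):
            raise ValueError("Tobit outcome is identically zero; nothing to fit")
        _check_rank(Z, names)

        scales = _column_scales(Z)
        ysd = y.std() if y.std() > 0 else 1.0
        Zs, ys = Z / scales, y / ysd
        ols = np.linalg.lstsq(Zs, ys, rcond=None)[0]
        s0 = max((ys - Zs @ ols).std(), 1e-3)
        start = np.concatenate([ols, [np.log(s0)]])
        xs, negll_val, n_iter, converged = _maximize(
            lambda t: tobit_negll(t, Zs, ys),
            lambda t: tobit_score(t, Zs, ys),
            [start],
            gtol=self.gtol,
        )
        x = np.concatenate([xs[:-1] * ysd / scales, [xs[-1] + np.log(ysd)]])
        self.params_ = x[:-1]
        self.sigma_ = float(np.exp(x[-1]))
        self.feature_names_ = names
        # only uncensored observations carry a density term in y
        self.llf_ = -negll_val - np.count_nonzero(y) * np.log(ysd)
        self.vcov_ = _vcov_from_grad(lambda t: tobit_score(t, Z, y), x)
        self.se_ = np.sqrt(np.diag(self.vcov_))
        self.n_iter_ = n_iter
        self.converged_ = converged
        self.n_obs_ = int(y.size)
        self.n_censored_ = int(np.sum(y == 0))
        if self.fit_intercept:
            self.intercept_, self.coef_ = x[0], x[1:-1]
        else:
            self.intercept_, self.coef_ = 0.0, x[:-1]
        return self

    def predict(self, Z):
        """Unconditional mean E[y] = Phi(a) (xb + sigma lambda(a)), a = xb/sigma."""
        Z, _ = _as_design(Z, self.fit_intercept)
        xb = Z @ self.params_
        a = xb / self.sigma_
        return ndtr(a) * (xb + self.sigma_ * inverse_mills(a))


# ---------------------------------------------------------------------------
# Cragg double hurdle
# ---------------------------------------------------------------------------

class CraggDoubleHurdle(BaseEstimator):
    """Cragg double-hurdle model for a zero-inflated cost outcome.

    Hurdle 1: P(cost incurred | x) = Phi(x'gamma) (probit, fitted on all
    observations). Hurdle 2: positive costs follow a zero-truncated
    N(z'beta, sigma^2) (fitted on the positive subsample). With independent
    hurdle errors the joint log-likelihood is the sum of the two component
    log-likelihoods, which is exactly the bookkeeping used in the
    specification test against the nested Tobit.

    Parameters
    ----------
    hurdle1, hurdle2 : sequence of column names/indices or None
        Columns of ``X`` entering each hurdle (None = all columns). Both
        designs always include an intercept.
    method : {"two-stage", "joint"}
        Two-stage exploits separability; "joint" maximizes the combined
        likelihood over the full parameter vector in one optimizer run
        (used as an internal cross-check; identical answer).

    Attributes
    ----------
    gamma_, beta_ : ndarray — hurdle-1 / hurdle-2 coefficients (intercept first).
    sigma_ : float — hurdle-2 error SD.
    ll_probit_, ll_truncated_, ll_ : component and total log-likelihoods.
    vcov_gamma_, vcov_h2_ : covariance blocks (h2 includes log sigma last).
    n_obs_, n_positive_, converged_, n_iter_ : fit metadata.
    """

    def __init__(self, hurdle1=None, hurdle2=None, method="two-stage", gtol=1e-8):
        self.hurdle1 = hurdle1
        self.hurdle2 = hurdle2
        self.method = method
        self.gtol = gtol

    def _split(self, X):
        if hasattr(X, "columns"):
            X1 = X if self.hurdle1 is None else X[list(self.hurdle1)]
            X2 = X if self.hurdle2 is None else X[list(self.hurdle2)]
        else:
            X = np.asarray(X, dtype=float)
            X1 = X if self.hurdle1 is None else X[:, list(self.hurdle1)]
            X2 = X if self.hurdle2 is None else X[:, list(self.hurdle2)]
        return X1, X2

    def fit(self, X, y, dh=None):
        y = np.asarray(y, dtype=float).ravel()
        if np.any(y < 0):
            raise ValueError("cost outcome must be non-negative")
        if dh is not None:
            dh = np.asarray(dh, dtype=float).ravel()
            bad = np.flatnonzero(dh.astype(bool) != (y > 0))
            if bad.size:
                raise ValueError(
                    "treatment indicator inconsistent with cost positivity "
                    f"at row(s) {bad[:10].tolist()}"
                )
        dh = (y > 0).astype(float)
        X1, X2 = self._split(X)

        if self.method not in ("two-stage", "joint"):
            raise ValueError(f"unknown method {self.method!r}")

        probit = ProbitModel(gtol=self.gtol).fit(X1, dh)
        pos = y > 0
        X2pos = X2[pos] if not hasattr(X2, "loc") else X2.loc[pos]
        trunc = TruncatedNormalRegression(gtol=self.gtol).fit(X2pos, y[pos])

        if self.method == "joint":
            D1, _ = _as_design(X1, True)
            D2, _ = _as_design(X2, True)
            D2p = D2[pos]
            qpos = y[pos]
            k1 = D1.shape[1]
            s1 = _column_scales(D1)
            s2 = _column_scales(D2p)
            ysd = qpos.std() if qpos.std() > 0 else 1.0
            D1s, D2s, qs = D1 / s1, D2p / s2, qpos / ysd

            def negll(theta):
                return probit_negll(theta[:k1], D1s, dh) + truncated_negll(
                    theta[k1:], D2s, qs
                )

            def grad(theta):
                return np.concatenate(
                    [probit_score(theta[:k1], D1s, dh),
                     truncated_score(theta[k1:], D2s, qs)]
                )

            ols = np.linalg.lstsq(D2s, qs, rcond=None)[0]
            s0 = max((qs - D2s @ ols).std(), 1e-3)
            start = np.concatenate([np.zeros(k1), ols, [np.log(s0)]])
            x, negf, n_iter, converged = _maximize(negll, grad, [start],
                                                   gtol=self.gtol)
            gamma = x[:k1] / s1
            beta = x[k1:-1] * ysd / s2
            logsig = x[-1] + np.log(ysd)
            self.gamma_ = gamma
            self.beta_ = beta
            self.sigma_ = float(np.exp(logsig))
            self.ll_probit_ = -probit_negll(gamma, D1, dh)
            self.ll_truncated_ = -truncated_negll(
                np.concatenate([beta, [logsig]]), D2p, qpos)
            self.ll_ = -negf - qpos.size * np.log(ysd)
            self.n_iter_ = n_iter
            self.converged_ = converged
            self.vcov_gamma_ = probit.vcov_
            self.vcov_h2_ = trunc.vcov_
        else:
            self.gamma_ = probit.params_
            self.beta_ = trunc.params_
            self.sigma_ = trunc.sigma_
            self.ll_probit_ = probit.llf_
            self.ll_truncated_ = trunc.llf_
            self.ll_ = probit.llf_ + trunc.llf_
            self.n_iter_ = probit.n_iter_ + trunc.n_iter_
            self.converged_ = probit.converged_ and trunc.converged_
            self.vcov_gamma_ = probit.vcov_
            self.vcov_h2_ = trunc.vcov_

        self.probit_ = probit
        self.truncated_ = trunc
        self.h1_feature_names_ = probit.feature_names_
        self.h2_feature_names_ = trunc.feature_names_
        self.n_obs_ = int(y.size)
        self.n_positive_ = int(pos.sum())
        return self

    # -- model-implied quantities ------------------------------------------
    def _designs(self, X):
        X1, X2 = self._split(X)
        D1, _ = _as_design(X1, True)
        D2, _ = _as_design(X2, True)
        return D1, D2

    def predict_treatment_proba(self, X):
        D1, _ = self._designs(X)
        return ndtr(D1 @ self.gamma_)

    def predict_conditional_cost(self, X):
        """E[Q | Q > 0, z] = z'beta + sigma lambda(z'beta / sigma)."""
        _, D2 = self._designs(X)
        xb = D2 @ self.beta_
        return xb + self.sigma_ * inverse_mills(xb / self.sigma_)

    def predict(self, X):
        """Unconditional expected cost E[Q | x, z] =
        Phi(x'gamma) [z'beta + sigma lambda(z'beta / sigma)]."""
        return self.predict_treatment_proba(X) * self.predict_conditional_cost(X)
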