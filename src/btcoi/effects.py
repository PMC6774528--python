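"""Average marginal effects for the double-hurdle model.

Conditional effects (CAME) are reported per hurdle:

* hurdle 1 — effect on the treatment probability Phi(x'gamma);
* hurdle 2 — effect on the conditional cost E[Q | Q>0, z] =
  z'beta + sigma lambda(z'beta / sigma).

Unconditional effects (UAME) combine both hurdles through
E[Q | x, z] = Phi(x'gamma) (z'beta + sigma lambda(z'beta / sigma)).

All effects are sample averages of per-observation effects (not effects at
the mean): analytic derivatives for continuous covariates, discrete 0 -> 1
differences for dummies. Standard errors come from a nonparametric bootstrap
that resamples farmers with replacement and re-estimates both hurdles in
every replicate.
"""

from __future__ import annotations

import warnings
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from ._stats import inverse_mills, norm_logpdf
from .hurdle import DesignSpec, DoubleHurdleFit, fit_double_hurdle

__all__ = [
    "came",
    "uame",
    "unconditional_expected_cost",
    "bootstrap_se",
    "marginal_effects_table",
]


def _norm_pdf(t):
    return np.exp(norm_logpdf(t))


def _is_dummy(values: np.ndarray) -> bool:
    return np.all(np.isin(values, (0.0, 1.0)))


def _designs(fit: DoubleHurdleFit, df: pd.DataFrame):
    X1, X2, _, _, prepared = fit.design.build(df)
    return X1, X2, prepared


def _h1_matrix(X1: pd.DataFrame) -> np.ndarray:
    return np.column_stack([np.ones(len(X1)), X1.to_numpy(dtype=float)])


def _conditional_mean(X2v: np.ndarray, beta: np.ndarray, sigma: float):
    xb = np.column_stack([np.ones(len(X2v)), X2v]) @ beta
    return xb + sigma * inverse_mills(xb / sigma)


def _phi_gamma(X1v: np.ndarray, gamma: np.ndarray):
    return ndtr(np.column_stack([np.ones(len(X1v)), X1v]) @ gamma)


def came(fit: DoubleHurdleFit, df: pd.DataFrame, covariate: str):
    """Conditional average marginal effects of one covariate.

    Returns ``(h1_effect, h2_effect)``; an entry is None where the covariate
    does not enter that hurdle (the base category of a dummy set or a
    hurdle-1-only regressor). Raises if the covariate enters neither design.
    """
    X1, X2, _ = _designs(fit, df)
    in1, in2 = covariate in X1.columns, covariate in X2.columns
    if not (in1 or in2):
        raise KeyError(f"covariate {covariate!r} absent from both hurdles")
    gamma = fit.gamma.to_numpy()
    beta = fit.beta.to_numpy()
    sigma = fit.sigma

    h1 = h2 = None
    if in1:
        v = X1[covariate].to_numpy(dtype=float)
        if _is_dummy(v):
            p1 = _phi_gamma(X1.assign(**{covariate: 1.0}).to_numpy(dtype=float), gamma)
            p0 = _phi_gamma(X1.assign(**{covariate: 0.0}).to_numpy(dtype=float), gamma)
            h1 = float(np.mean(p1 - p0))
        else:
            idx = np.column_stack([np.ones(len(X1)), X1.to_numpy(dtype=float)]) @ gamma
            g_k = gamma[1 + list(X1.columns).index(covariate)]
            h1 = float(g_k * np.mean(_norm_pdf(idx)))
    if in2:
        v = X2[covariate].to_numpy(dtype=float)
        if _is_dummy(v):
            m1 = _conditional_mean(X2.assign(**{covariate: 1.0}).to_numpy(dtype=float),
                                   beta, sigma)
            m0 = _conditional_mean(X2.assign(**{covariate: 0.0}).to_numpy(dtype=float),
                                   beta, sigma)
            h2 = float(np.mean(m1 - m0))
        else:
            xb = np.column_stack([np.ones(len(X2)), X2.to_numpy(dtype=float)]) @ beta
            a = xb / sigma
            lam = inverse_mills(a)
            b_k = beta[1 + list(X2.columns).index(covariate)]
            # d/dz_k [xb + sigma lam(a)] = b_k (1 + lam'(a)) = b_k (1 - lam (a + lam))
            h2 = float(b_k * np.mean(1.0 - lam * (a + lam)))
    return h1, h2


def uame(fit: DoubleHurdleFit, df: pd.DataFrame, covariate: str) -> float:
    """Unconditional average marginal effect on E[Q | x, z] (Rs)."""
    X1, X2, _ = _designs(fit, df)
    in1, in2 = covariate in X1.columns, covariate in X2.columns
    if not (in1 or in2):
        raise KeyError(f"covariate {covariate!r} absent from both hurdles")
    gamma = fit.gamma.to_numpy()
    beta = fit.beta.to_numpy()
    sigma = fit.sigma
    X1v = X1.to_numpy(dtype=float)
    X2v = X2.to_numpy(dtype=float)

    values = (X1[covariate] if in1 else X2[covariate]).to_numpy(dtype=float)
    if _is_dummy(values):
        def at(val):
            A1 = X1.assign(**{covariate: val}).to_numpy(dtype=float) if in1 else X1v
            A2 = X2.assign(**{covariate: val}).to_numpy(dtype=float) if in2 else X2v
            return _phi_gamma(A1, gamma) * _conditional_mean(A2, beta, sigma)
        return float(np.mean(at(1.0) - at(0.0)))

    idx1 = np.column_stack([np.ones(len(X1)), X1v]) @ gamma
    xb = np.column_stack([np.ones(len(X2)), X2v]) @ beta
    a = xb / sigma
    lam = inverse_mills(a)
    cond = xb + sigma * lam
    g_k = gamma[1 + list(X1.columns).index(covariate)] if in1 else 0.0
    b_k = beta[1 + list(X2.columns).index(covariate)] if in2 else 0.0
    deriv = (g_k * _norm_pdf(idx1) * cond
             + ndtr(idx1) * b_k * (1.0 - lam * (a + lam)))
    return float(np.mean(deriv))


def unconditional_expected_cost(fit: DoubleHurdleFit, df: pd.DataFrame) -> float:
    """Sample mean of the model-implied unconditional cost of illness (Rs)."""
    X1, X2, _ = _designs(fit, df)
    p = _phi_gamma(X1.to_numpy(dtype=float), fit.gamma.to_numpy())
    m = _conditional_mean(X2.to_numpy(dtype=float), fit.beta.to_numpy(), fit.sigma)
    return float(np.mean(p * m))


def bootstrap_se(statistic: Callable[[pd.DataFrame], Dict[str, float]],
                 df: pd.DataFrame, reps: int, seed: int,
                 max_failure_share: float = 0.10) -> pd.DataFrame:
    """Nonparametric bootstrap SEs for any per-dataset statistic.

    Farmers are resampled with replacement; ``statistic`` is re-evaluated on
    each replicate (for model-based statistics this means full re-estimation
    of both hurdles). Replicates that raise are dropped and counted; a
    warning is emitted if more than ``max_failure_share`` fail. Deterministic
    given ``seed``.

    Returns a frame indexed by statistic name with columns ``se``,
    ``n_effective`` and ``n_failed``.
    """
    if reps < 2:
        raise ValueError("bootstrap requires reps >= 2")
    rng = np.random.default_rng(seed)
    n = len(df)
    draws: List[Dict[str, float]] = []
    n_failed = 0
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        try:
            draws.append(statistic(df.iloc[idx].reset_index(drop=True)))
        except Exception:
            n_failed += 1
    if not draws:
        raise RuntimeError("every bootstrap replicate failed")
    if n_failed > max_failure_share * reps:
        warnings.warn(
            f"bootstrap: {n_failed}/{reps} replicates failed to estimate",
            RuntimeWarning)
    frame = pd.DataFrame(draws)
    out = pd.DataFrame({
        "se": frame.std(ddof=1),
        "n_effective": frame.notna().sum(),
    })
    out["n_failed"] = n_failed
    return out


def marginal_effects_table(df: pd.DataFrame, design: DesignSpec,
                           covariates: Optional[Sequence[str]] = None,
                           bootstrap_reps: int = 500, seed: int = 0,
                           fit: Optional[DoubleHurdleFit] = None
                           ) -> pd.DataFrame:
    """CAME/UAME per covariate with bootstrap SEs, plus the unconditional
    expected cost baseline (stored in ``attrs``).

    ``bootstrap_reps=0`` skips the bootstrap (point estimates only).
    """
    if fit is None:
        fit = fit_double_hurdle(df, design)
    if covariates is None:
        covariates = [c for c in dict.fromkeys(design.hurdle1_covariates
                                               + design.hurdle2_covariates)]

    def point(d: pd.DataFrame, f: Optional[DoubleHurdleFit] = None
              ) -> Dict[str, float]:
        f = f or fit_double_hurdle(d, design)
        vals: Dict[str, float] = {}
        for c in covariates:
            h1, h2 = came(f, d, c)
            if h1 is not None:
                vals[f"came_h1:{c}"] = h1
            if h2 is not None:
                vals[f"came_h2:{c}"] = h2
            vals[f"uame:{c}"] = uame(f, d, c)
        vals["unconditional_expected_cost"] = unconditional_expected_cost(f, d)
        return vals

    est = point(df, fit)
    if bootstrap_reps:
        ses = bootstrap_se(point, df, reps=bootstrap_reps, seed=seed)["se"]
    else:
        ses = pd.Series(np.nan, index=list(est))

    rows = []
    for c in covariates:
        rows.append({
            "covariate": c,
            "came_h1": est.get(f"came_h1:{c}", np.nan),
            "came_h1_se": ses.get(f"came_h1:{c}", np.nan),
            "came_h2": est.get(f"came_h2:{c}", np.nan),
            "came_h2_se": ses.get(f"came_h2:{c}", np.nan),
            "uame": est[f"uame:{c}"],
            "uame_se": ses.get(f"uame:{c}", np.nan),
        })
    table = pd.DataFrame(rows).set_index("covariate")
    table.attrs["unconditional_expected_cost"] = est["unconditional_expected_cost"]
    table.attrs["unconditional_expected_cost_se"] = float(
        ses.get("unconditional_expected_cost", np.nan))
    table.attrs["model"] = design.name or design.bt_mode
    table.attrs["n_obs"] = fit.n_obs
    table.attrs["bootstrap_reps"] = bootstrap_reps
    table.attrs["seed"] = seed
    return table
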