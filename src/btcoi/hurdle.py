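"""Model specification and fitting for the double-hurdle analysis.

:class:`DesignSpec` turns a survey table into the two hurdle design
matrices under one of three definitions of Bt adoption:

* ``self_reported`` — a single dummy from the farmer's stated belief
  (don't-know / no-response pooled with non-adopters);
* ``lab_dummies``   — weak-Bt and true-Bt dummies from the lab
  classification, non-Bt as base category;
* ``expression_level`` — the continuous ELISA expression level, with the
  sample restricted to true-Bt adopters.

Off-farm employment enters hurdle 1 only (whether treatment is sought), not
hurdle 2 (how much it costs). The likelihood-ratio test compares the
double-hurdle fit (probit + truncated components) against the nested Tobit;
its degrees of freedom default to the number of hurdle-1 slope coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .adoption import classify_survey
from .datagen import EXPRESSION_THRESHOLD
from .estimators import (
    CraggDoubleHurdle,
    ProbitModel,
    TobitRegression,
    TruncatedNormalRegression,
)

__all__ = [
    "DesignSpec",
    "model_design",
    "DoubleHurdleFit",
    "TobitFit",
    "fit_probit",
    "fit_truncated_normal",
    "fit_double_hurdle",
    "fit_tobit",
    "lr_statistic",
    "lr_test",
    "inverse_mills",
]

# re-export: the inverse Mills ratio is part of this module's public surface
from ._stats import inverse_mills  # noqa: E402

_BASE_CONTROLS = ["cotton_area", "self_spray", "protective_gear",
                  "sc_habits", "age", "education", "punjab"]


@dataclass
class DesignSpec:
    """Covariate lists and adoption definition for one model."""

    bt_mode: str = "lab_dummies"
    hurdle1_covariates: List[str] = field(default_factory=list)
    hurdle2_covariates: List[str] = field(default_factory=list)
    threshold: float = EXPRESSION_THRESHOLD
    #: optional extra row filter applied before the bt_mode filter
    sample_filter: Optional[Callable[[pd.DataFrame], pd.Series]] = None
    name: str = ""

    def __post_init__(self):
        if self.bt_mode not in ("self_reported", "lab_dummies",
                                "expression_level"):
            raise ValueError(f"unknown bt_mode {self.bt_mode!r}")
        bt_cols = {
            "self_reported": ["bt_self"],
            "lab_dummies": ["weak_bt", "true_bt"],
            "expression_level": ["bt_expression"],
        }[self.bt_mode]
        if not self.hurdle1_covariates:
            self.hurdle1_covariates = bt_cols + _BASE_CONTROLS + ["off_farm"]
        if not self.hurdle2_covariates:
            self.hurdle2_covariates = bt_cols + _BASE_CONTROLS

    def prepare(self, df: pd.DataFrame) -> pd.DataFrame:
        """Derive adoption columns and apply the sample restriction."""
        d = df.copy()
        if "punjab" not in d.columns:
            d["punjab"] = (d["province"].str.lower() == "punjab").astype(float)
        lab = classify_survey(d, threshold=self.threshold)
        d["lab_category"] = lab
        d["weak_bt"] = (lab == "weak_bt").astype(float)
        d["true_bt"] = (lab == "true_bt").astype(float)
        d["bt_self"] = (d["belief"] == "bt").astype(float)
        if self.sample_filter is not None:
            d = d[self.sample_filter(d)]
        if self.bt_mode == "expression_level":
            d = d[d["lab_category"] == "true_bt"]
        return d

    def build(self, df: pd.DataFrame
              ) -> Tuple[pd.DataFrame, pd.DataFrame, np.ndarray, np.ndarray,
                         pd.DataFrame]:
        """Return (X1, X2, qh, dh, prepared-frame); intercepts are added by
        the estimators."""
        d = self.prepare(df)
        missing = [c for c in set(self.hurdle1_covariates
                                  + self.hurdle2_covariates)
                   if c not in d.columns]
        if missing:
            raise KeyError(f"design covariates missing from data: {sorted(missing)}")
        qh = d["qh"].to_numpy(dtype=float)
        dh = d["dh"].to_numpy(dtype=float)
        bad = np.flatnonzero(dh.astype(bool) != (qh > 0))
        if bad.size:
            ids = d.iloc[bad[:10]].get("farmer_id", pd.Series(bad[:10])).tolist()
            raise ValueError(
                f"dh inconsistent with qh positivity for record(s): {ids}")
        X1 = d[self.hurdle1_covariates].astype(float)
        X2 = d[self.hurdle2_covariates].astype(float)
        return X1, X2, qh, dh, d


def model_design(model: str) -> DesignSpec:
    """Preset designs: "I" self-reported dummy, "II" lab dummies,
    "III" expression level on the true-Bt subsample."""
    key = model.strip().upper()
    modes = {"I": "self_reported", "II": "lab_dummies",
             "III": "expression_level"}
    if key not in modes:
        raise ValueError(f"unknown model {model!r}; expected I, II or III")
    return DesignSpec(bt_mode=modes[key], name=f"Model {key}")


# ---------------------------------------------------------------------------
# fit wrappers and result containers
# ---------------------------------------------------------------------------

@dataclass
class DoubleHurdleFit:
    design: DesignSpec
    gamma: pd.Series
    beta: pd.Series
    sigma: float
    ll_probit: float
    ll_truncated: float
    ll_total: float
    se_gamma: pd.Series
    se_beta: pd.Series
    se_sigma: float
    n_obs: int
    n_positive: int
    converged: bool
    n_iter: int
    estimator: CraggDoubleHurdle

    def to_dict(self) -> dict:
        return {
            "model": self.design.name or self.design.bt_mode,
            "bt_mode": self.design.bt_mode,
            "gamma": self.gamma.to_dict(),
            "beta": self.beta.to_dict(),
            "sigma": self.sigma,
            "se_gamma": self.se_gamma.to_dict(),
            "se_beta": self.se_beta.to_dict(),
            "se_sigma": self.se_sigma,
            "ll_probit": self.ll_probit,
            "ll_truncated": self.ll_truncated,
            "ll_total": self.ll_total,
            "n_obs": self.n_obs,
            "n_positive": self.n_positive,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


@dataclass
class TobitFit:
    design: DesignSpec
    beta: pd.Series
    sigma: float
    ll_tobit: float
    se_beta: pd.Series
    n_obs: int
    n_censored: int
    converged: bool
    estimator: TobitRegression


def fit_probit(dh, X) -> ProbitModel:
    """Probit for the first hurdle; thin wrapper over :class:`ProbitModel`."""
    return ProbitModel().fit(X, dh)


def fit_truncated_normal(qh, Z) -> TruncatedNormalRegression:
    """Zero-truncated regression for the positive-cost subsample."""
    return TruncatedNormalRegression().fit(Z, qh)


def fit_double_hurdle(df: pd.DataFrame, design: DesignSpec,
                      method: str = "two-stage") -> DoubleHurdleFit:
    """Fit the double-hurdle model on a survey table carrying qh/dh."""
    X1, X2, qh, dh, _ = design.build(df)
    est = CraggDoubleHurdle(hurdle1=list(X1.columns), hurdle2=list(X2.columns),
                            method=method)
    # combined frame with both covariate sets
    both = pd.concat([X1, X2.loc[:, [c for c in X2.columns
                                     if c not in X1.columns]]], axis=1)
    est.fit(both, qh, dh=dh)
    h1n, h2n = est.h1_feature_names_, est.h2_feature_names_
    se_g = np.sqrt(np.diag(est.vcov_gamma_))
    se_h2 = np.sqrt(np.diag(est.vcov_h2_))
    # delta method: vcov is in log sigma, SE(sigma) = sigma * SE(log sigma)
    return DoubleHurdleFit(
        design=design,
        gamma=pd.Series(est.gamma_, index=h1n),
        beta=pd.Series(est.beta_, index=h2n),
        sigma=est.sigma_,
        ll_probit=est.ll_probit_,
        ll_truncated=est.ll_truncated_,
        ll_total=est.ll_,
        se_gamma=pd.Series(se_g, index=h1n),
        se_beta=pd.Series(se_h2[:-1], index=h2n),
        se_sigma=float(est.sigma_ * se_h2[-1]),
        n_obs=est.n_obs_,
        n_positive=est.n_positive_,
        converged=est.converged_,
        n_iter=est.n_iter_,
        estimator=est,
    )


def fit_tobit(df: pd.DataFrame, design: DesignSpec) -> TobitFit:
    """Type-I Tobit on the censored cost outcome with the hurdle-2 design."""
    _, X2, qh, _, _ = design.build(df)
    est = TobitRegression().fit(X2, qh)
    return TobitFit(
        design=design,
        beta=pd.Series(est.params_, index=est.feature_names_),
        sigma=est.sigma_,
        ll_tobit=est.llf_,
        se_beta=pd.Series(est.se_[:-1], index=est.feature_names_),
        n_obs=est.n_obs_,
        n_censored=est.n_censored_,
        converged=est.converged_,
        estimator=est,
    )


def lr_statistic(ll_probit: float, ll_truncated: float, ll_tobit: float,
                 df: int) -> Tuple[float, int, float]:
    """LR bookkeeping from component log-likelihoods:
    chi2 = 2 [(ll_probit + ll_truncated) - ll_tobit]."""
    stat = 2.0 * ((ll_probit + ll_truncated) - ll_tobit)
    if stat < -1e-6:
        raise ValueError(
            f"negative LR statistic ({stat:.6g}): the double-hurdle optimum "
            "lies below the nested Tobit — optimization failed")
    stat = max(stat, 0.0)
    return stat, int(df), float(chi2.sf(stat, df))


def lr_test(dh_fit: DoubleHurdleFit, tobit_fit: TobitFit,
            df: Optional[int] = None) -> Tuple[float, int, float]:
    """Specification test of the Tobit restriction against the double hurdle.

    ``df`` defaults to the number of hurdle-1 slope coefficients (the
    convention of the published table); pass the full restriction count
    explicitly where the two designs share every column.
    """
    if list(dh_fit.beta.index) != list(tobit_fit.beta.index):
        raise ValueError("double-hurdle and Tobit fits use different "
                         "hurdle-2 designs")
    if dh_fit.n_obs != tobit_fit.n_obs:
        raise ValueError("fits were computed on different samples")
    if df is None:
        df = len(dh_fit.gamma) - 1  # slopes, excluding the intercept
    return lr_statistic(dh_fit.ll_probit, dh_fit.ll_truncated,
                        tobit_fit.ll_tobit, df)
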