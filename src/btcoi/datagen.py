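"""Synthetic farm-survey generator.

Emulates the statistical structure of a household survey of cotton growers
in Punjab and Sindh: household/farm covariates, a lab-verified Bt adoption
status (strip tests on plant tissue at 70 days after sowing plus an ELISA
expression level in ug/g), an error-prone self-reported adoption belief, and
a zero-inflated seasonal cost-of-illness outcome generated by the two-stage
latent model

    dh* = gamma'x + mu,   mu ~ N(0, 1),      dh = 1{dh* > 0}
    Qh  | dh = 1  ~  N(beta'z, sigma^2) truncated to (0, inf),
    Qh  = 0 otherwise.

The truncation implements the corner-solution rule (a positive cost requires
both hurdles to be crossed); with independent errors this is exactly the
data-generating process whose likelihood separates into a probit plus a
zero-truncated regression, i.e. the model the estimation stage fits.

Default parameter values are calibrated to the study's descriptive tables
(covariate means/SDs, per-category expression moments, per-province
misclassification structure, hurdle coefficients of the lab-dummy model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr

from ._stats import (
    sample_truncated_lognormal,
    sample_truncated_normal,
    solve_truncated_lognormal,
    truncnorm_loc_for_mean,
)

__all__ = [
    "CovariateSpec",
    "MisclassRates",
    "DGPConfig",
    "default_config",
    "flip_rates_from_belief_errors",
    "apply_misclassification",
    "simulate_health_outcome",
    "generate_survey",
]

CATEGORIES = ("non_bt", "weak_bt", "true_bt")
BELIEFS = ("bt", "non_bt", "dont_know", "no_response")

#: ELISA expression threshold (ug/g) separating weak from true Bt adoption.
EXPRESSION_THRESHOLD = 1.90


@dataclass
class CovariateSpec:
    """Distribution of one covariate.

    kind: "truncnorm" (params: mean, sd, lower[, upper -> one-sided only
    lower is supported]), "bernoulli" (params: p), "categorical"
    (params: values, probs), "constant" (params: value).
    """

    kind: str
    params: dict

    def sample(self, rng, size):
        if self.kind == "truncnorm":
            # "mean" is the post-truncation target mean; the location
            # parameter is solved so the truncated distribution hits it
            lower = self.params.get("lower", -np.inf)
            loc = truncnorm_loc_for_mean(self.params["mean"],
                                         self.params["sd"], lower)
            return sample_truncated_normal(
                rng, loc, self.params["sd"], lower=lower, size=size,
            )
        if self.kind == "bernoulli":
            return rng.binomial(1, self.params["p"], size=size).astype(float)
        if self.kind == "categorical":
            return rng.choice(
                np.asarray(self.params["values"], dtype=float),
                p=self.params["probs"], size=size,
            )
        if self.kind == "constant":
            return np.full(size, float(self.params["value"]))
        raise ValueError(f"unknown covariate kind {self.kind!r}")


@dataclass
class MisclassRates:
    """Reporting-error mechanism for the adoption belief.

    type1_rate: P(report Bt | lab-negative field, farmer answers) — the
    source of type I errors (believing in Bt that is not there).
    type2_rate: P(report non-Bt | lab-positive field, farmer answers) — the
    source of type II errors.
    dontknow_rate / no_response_rate: assigned independently of the lab
    result before the flip logic.

    Note the published error rates condition the other way around (on the
    *belief*); :func:`flip_rates_from_belief_errors` converts those to this
    mechanism-level parameterization.
    """

    type1_rate: float
    type2_rate: float
    dontknow_rate: float = 0.0
    no_response_rate: float = 0.0

    def validate(self):
        for name in ("type1_rate", "type2_rate", "dontknow_rate", "no_response_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"misclass.{name}={v} outside [0, 1]")
        if self.dontknow_rate + self.no_response_rate > 1.0 + 1e-12:
            raise ValueError(
                "misclass rates inconsistent: dontknow_rate + no_response_rate > 1"
            )


def flip_rates_from_belief_errors(type1, type2, lab_positive_share):
    """Invert belief-conditional error rates into lab-conditional flip rates.

    Given the published-style rates t1 = P(lab-negative | belief Bt) and
    t2 = P(lab-positive | belief non-Bt) and the population lab-positive
    share pi, solve (among farmers who state a belief)

        t1 = (1-pi) a / [(1-pi) a + pi (1-b)]
        t2 = pi b / [(1-pi)(1-a) + pi b]

    for a = P(report Bt | lab-negative) and b = P(report non-Bt |
    lab-positive). The "don't know" share drops out because it is assigned
    independently of the lab result.
    """
    pi = float(lab_positive_share)
    if not 0.0 < pi < 1.0:
        raise ValueError("lab_positive_share must be strictly inside (0, 1)")
    if not (0.0 <= type1 < 1.0 and 0.0 <= type2 < 1.0):
        raise ValueError("belief-conditional error rates must lie in [0, 1)")
    # (1-pi) a (1-t1) = t1 pi (1-b)  and  pi b (1-t2) = t2 (1-pi)(1-a)
    c1 = type1 * pi / ((1.0 - pi) * (1.0 - type1))      # a = c1 (1-b)
    c2 = type2 * (1.0 - pi) / (pi * (1.0 - type2))      # b = c2 (1-a)
    a = c1 * (1.0 - c2) / (1.0 - c1 * c2)
    b = c2 * (1.0 - a)
    if not (0.0 <= a <= 1.0 and 0.0 <= b <= 1.0):
        raise ValueError(
            "belief-conditional rates are infeasible at this lab-positive share"
        )
    return float(a), float(b)


def _default_covariates() -> Dict[str, CovariateSpec]:
    # Calibrated to the pooled descriptive statistics of the study sample.
    return {
        "age": CovariateSpec("truncnorm", {"mean": 46.4, "sd": 11.7, "lower": 18.0}),
        "education": CovariateSpec("truncnorm", {"mean": 4.7, "sd": 4.4, "lower": 0.0}),
        "household_size": CovariateSpec(
            "truncnorm", {"mean": 8.9, "sd": 4.5, "lower": 1.0}),
        "off_farm": CovariateSpec("bernoulli", {"p": 0.20}),
        "farm_size": CovariateSpec("truncnorm", {"mean": 8.4, "sd": 16.4, "lower": 0.5}),
        "cotton_area": CovariateSpec(
            "truncnorm", {"mean": 5.5, "sd": 12.2, "lower": 0.25}),
        "self_spray": CovariateSpec("bernoulli", {"p": 0.60}),
        "protective_gear": CovariateSpec(
            "categorical",
            {"values": [0, 1, 2, 3, 4], "probs": [0.35, 0.12, 0.13, 0.12, 0.28]}),
        "sc_habits": CovariateSpec("bernoulli", {"p": 0.41}),
    }


@dataclass
class DGPConfig:
    """Full configuration of the synthetic-survey data-generating process."""

    n_farmers: int = 564
    province_share_punjab: float = 435.0 / 564.0
    #: true adoption category probabilities per province (non, weak, true)
    category_probs: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: {
            "punjab": (0.1839, 0.6435, 0.1726),
            "sindh": (0.2481, 0.5925, 0.1594),
        })
    covariate_params: Dict[str, CovariateSpec] = field(
        default_factory=_default_covariates)
    #: hurdle-1 coefficients on the latent probit scale ("const" required);
    #: keys resolve against covariates plus derived columns
    #: weak_bt/true_bt/punjab/bt_expression.
    gamma_true: Dict[str, float] = field(default_factory=lambda: {
        "const": 0.82, "weak_bt": -0.32, "true_bt": -0.68, "cotton_area": 0.0,
        "self_spray": 1.29, "protective_gear": 0.03, "off_farm": 0.07,
        "sc_habits": -0.01, "age": -0.01, "education": -0.08, "punjab": 0.26,
    })
    #: hurdle-2 coefficients in Rs (off-farm employment enters hurdle 1 only)
    beta_true: Dict[str, float] = field(default_factory=lambda: {
        "const": 741.38, "weak_bt": -36.46, "true_bt": -95.06,
        "cotton_area": 0.76, "self_spray": -47.54, "protective_gear": -40.46,
        "sc_habits": -21.46, "age": -3.72, "education": -25.50, "punjab": 130.49,
    })
    sigma_true: float = 147.42
    misclass: Dict[str, MisclassRates] = field(default_factory=lambda: {
        # mechanism-level flip rates derived from the published per-province
        # belief-conditional error rates via flip_rates_from_belief_errors
        # (punjab: t1=61/353, t2=17/30, pi=355/435; sindh: t1=1/50,
        # t2=14/28, pi=97/129)
        "punjab": MisclassRates(0.89964, 0.02958, dontknow_rate=51.0 / 435.0,
                                no_response_rate=1.0 / 435.0),
        "sindh": MisclassRates(0.04232, 0.31593, dontknow_rate=51.0 / 129.0),
    })
    #: target (mean, sd) of the ELISA expression level per category; weak and
    #: true are truncated at the 1.90 ug/g threshold and re-calibrated so the
    #: truncated moments hit these targets
    expression_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "non_bt": (0.37, 0.47), "weak_bt": (0.90, 0.47), "true_bt": (3.09, 1.31),
        })
    #: per-category pesticide use, kg/acre (mean, sd), truncated at 0
    pesticide_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "non_bt": (2.73, 1.84), "weak_bt": (2.29, 2.12), "true_bt": (1.98, 2.05),
        })
    #: number of lab-tested tissue samples per province
    n_strips: Dict[str, int] = field(
        default_factory=lambda: {"punjab": 2, "sindh": 5})
    strip_sensitivity: float = 0.9
    #: daily farm wage, Rs (mean, sd, floor)
    wage_params: Tuple[float, float, float] = (300.0, 60.0, 150.0)
    #: Beta(a, b) share of the cost of illness attributed to lost work days
    indirect_share_beta: Tuple[float, float] = (2.0, 3.0)
    seed: int = 0

    def validate(self):
        if int(self.n_farmers) <= 0:
            raise ValueError(f"n_farmers={self.n_farmers} must be positive")
        if not 0.0 <= self.province_share_punjab <= 1.0:
            raise ValueError("province_share_punjab outside [0, 1]")
        if self.sigma_true <= 0:
            raise ValueError(f"sigma_true={self.sigma_true} must be positive")
        for prov, probs in self.category_probs.items():
            p = np.asarray(probs, dtype=float)
            if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"category_probs[{prov!r}] is not a distribution")
        for prov, rates in self.misclass.items():
            rates.validate()
        for name in self.gamma_true:
            if name not in self._resolvable():
                raise ValueError(f"gamma_true names unknown covariate {name!r}")
        for name in self.beta_true:
            if name not in self._resolvable():
                raise ValueError(f"beta_true names unknown covariate {name!r}")
        if "const" not in self.gamma_true or "const" not in self.beta_true:
            raise ValueError("gamma_true and beta_true must include 'const'")
        if not 0.0 < self.strip_sensitivity <= 1.0:
            raise ValueError("strip_sensitivity outside (0, 1]")
        return self

    def _resolvable(self):
        return set(self.covariate_params) | {
            "const", "weak_bt", "true_bt", "punjab", "bt_expression"}


def default_config(**overrides) -> DGPConfig:
    """The study-calibrated default configuration, with keyword overrides."""
    return DGPConfig(**overrides).validate()


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def apply_misclassification(true_labels, rates: MisclassRates, rng,
                            lab_positive=None):
    """Produce self-reported beliefs from lab-based adoption labels.

    With probability ``dontknow_rate`` (resp. ``no_response_rate``) a farmer
    answers "don't know" (resp. gives no answer), independently of the lab
    result. Otherwise, lab-negative farmers report Bt with probability
    ``type1_rate`` and lab-positive farmers report non-Bt with probability
    ``type2_rate``.
    """
    rates.validate()
    labels = np.asarray(true_labels, dtype=object)
    if lab_positive is None:
        lab_positive = labels != "non_bt"
    lab_positive = np.asarray(lab_positive, dtype=bool)
    n = labels.size
    u = rng.uniform(size=n)
    v = rng.uniform(size=n)
    belief = np.where(lab_positive,
                      np.where(v < rates.type2_rate, "non_bt", "bt"),
                      np.where(v < rates.type1_rate, "bt", "non_bt"))
    belief = np.where(u < rates.dontknow_rate, "dont_know", belief)
    belief = np.where(
        (u >= rates.dontknow_rate)
        & (u < rates.dontknow_rate + rates.no_response_rate),
        "no_response", belief)
    return belief.astype(object)


def simulate_health_outcome(x_index, z_index, sigma, rng):
    """Draw (dh, Qh) from the two-stage latent model.

    Parameters are the already-formed linear indices gamma'x and beta'z.
    Hurdle 1: dh = 1{gamma'x + mu > 0}, mu ~ N(0,1). Hurdle 2, conditional
    on dh = 1: Qh from N(beta'z, sigma^2) truncated to (0, inf) — the
    corner-solution rule that a recorded cost is positive.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x_index = np.asarray(x_index, dtype=float)
    z_index = np.asarray(z_index, dtype=float)
    mu = rng.standard_normal(x_index.shape)
    dh = (x_index + mu > 0).astype(int)
    qh = np.zeros_like(z_index)
    pos = dh == 1
    if pos.any():
        qh[pos] = sample_truncated_normal(rng, z_index[pos], sigma, lower=0.0)
    return dh, qh


def _resolve_index(coeffs: Dict[str, float], table: pd.DataFrame) -> np.ndarray:
    idx = np.full(len(table), coeffs.get("const", 0.0), dtype=float)
    for name, c in coeffs.items():
        if name == "const" or c == 0.0:
            continue
        idx += c * table[name].to_numpy(dtype=float)
    return idx


def generate_survey(config: DGPConfig, seed: Optional[int] = None) -> pd.DataFrame:
    """Generate one synthetic survey; deterministic given (config, seed).

    Returns one row per farmer. Cost components decompose the simulated
    seasonal cost of illness so the accounting stage can rebuild it exactly:
    ``qh = self_treatment + consultation + medication + travel +
    days_lost * wage``.
    """
    config.validate()
    n = int(config.n_farmers)
    root_seed = config.seed if seed is None else seed
    # independent deterministic sub-streams per generation stage
    ss = np.random.SeedSequence(root_seed).spawn(5)
    rng_cov, rng_adopt, rng_belief, rng_health, rng_cost = (
        np.random.default_rng(s) for s in ss)

    punjab = (rng_cov.uniform(size=n) < config.province_share_punjab)
    table = pd.DataFrame({
        "farmer_id": [f"F{i:05d}" for i in range(n)],
        "province": np.where(punjab, "punjab", "sindh"),
        "punjab": punjab.astype(float),
    })
    for name, spec in config.covariate_params.items():
        table[name] = spec.sample(rng_cov, n)
    table["protective_gear"] = table.get(
        "protective_gear", pd.Series(np.zeros(n))).round().clip(0, 4)

    # --- true adoption category, expression, strips --------------------
    cat = np.empty(n, dtype=object)
    for prov in ("punjab", "sindh"):
        m = table["province"].to_numpy() == prov
        if m.any():
            cat[m] = rng_adopt.choice(
                np.asarray(CATEGORIES, dtype=object),
                p=config.category_probs[prov], size=int(m.sum()))
    table["true_category"] = cat
    table["weak_bt"] = (cat == "weak_bt").astype(float)
    table["true_bt"] = (cat == "true_bt").astype(float)

    # ELISA expression: truncated lognormal per category, calibrated so the
    # truncated moments equal the configured targets
    expr = np.zeros(n)
    bounds = {"non_bt": (0.0, np.inf),
              "weak_bt": (0.0, EXPRESSION_THRESHOLD),
              "true_bt": (EXPRESSION_THRESHOLD, np.inf)}
    for c in CATEGORIES:
        m = cat == c
        if not m.any():
            continue
        mean, sd = config.expression_params[c]
        lo, hi = bounds[c]
        mu_ln, s_ln = solve_truncated_lognormal(mean, sd, lo, hi)
        expr[m] = sample_truncated_lognormal(rng_adopt, mu_ln, s_ln, lo, hi,
                                             size=int(m.sum()))
    table["bt_expression"] = expr

    # strip tests: lab-negative fields are all-negative by definition;
    # lab-positive fields have >=1 positive among the tested samples
    strips = []
    sens = config.strip_sensitivity
    for i in range(n):
        k = config.n_strips[table.at[i, "province"]]
        if cat[i] == "non_bt":
            s = np.zeros(k, dtype=int)
        else:
            s = (rng_adopt.uniform(size=k) < sens).astype(int)
            if s.sum() == 0:
                s[rng_adopt.integers(k)] = 1
        strips.append("".join(map(str, s)))
    table["strip_results"] = strips

    # pesticide use by true category
    pest = np.zeros(n)
    for c in CATEGORIES:
        m = cat == c
        if m.any():
            mean, sd = config.pesticide_params[c]
            pest[m] = sample_truncated_normal(rng_adopt, mean, sd, lower=0.0,
                                              size=int(m.sum()))
    table["pesticide_qty"] = pest

    # --- belief via misclassification ----------------------------------
    belief = np.empty(n, dtype=object)
    for prov in ("punjab", "sindh"):
        m = table["province"].to_numpy() == prov
        if m.any():
            belief[m] = apply_misclassification(
                cat[m], config.misclass[prov], rng_belief)
    table["belief"] = belief

    # --- health outcome --------------------------------------------------
    x_index = _resolve_index(config.gamma_true, table)
    z_index = _resolve_index(config.beta_true, table)
    dh, qh = simulate_health_outcome(x_index, z_index, config.sigma_true,
                                     rng_health)
    table["dh"] = dh
    table["qh"] = qh

    # --- decompose qh into reported cost components --------------------
    w_mean, w_sd, w_floor = config.wage_params
    wage = sample_truncated_normal(rng_cost, w_mean, w_sd, lower=w_floor, size=n)
    a, b = config.indirect_share_beta
    ind_share = rng_cost.beta(a, b, size=n)
    indirect = qh * ind_share
    days_lost = np.where(qh > 0, indirect / wage, 0.0)
    direct = qh - indirect
    # Dirichlet split of the direct outlay across the four components
    shares = rng_cost.dirichlet(np.ones(4), size=n)
    comp = direct[:, None] * shares
    table["wage"] = wage
    table["days_lost"] = days_lost
    table["self_treatment"] = comp[:, 0]
    table["consultation"] = comp[:, 1]
    table["medication"] = comp[:, 2]
    table["travel"] = comp[:, 3]
    return table


def config_to_dict(config: DGPConfig) -> dict:
    """JSON/YAML-serializable form of a config."""
    return asdict(config)


def config_from_dict(d: dict) -> DGPConfig:
    d = dict(d)
    if "covariate_params" in d:
        d["covariate_params"] = {
            k: v if isinstance(v, CovariateSpec) else CovariateSpec(**v)
            for k, v in d["covariate_params"].items()}
    if "misclass" in d:
        d["misclass"] = {
            k: v if isinstance(v, MisclassRates) else MisclassRates(**v)
            for k, v in d["misclass"].items()}
    for key in ("category_probs", "expression_params", "pesticide_params"):
        if key in d:
            d[key] = {k: tuple(v) for k, v in d[key].items()}
    for key in ("wage_params", "indirect_share_beta"):
        if key in d:
            d[key] = tuple(d[key])
    return DGPConfig(**d).validate()
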