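"""Lab-based Bt adoption classification and belief-vs-lab misclassification.

A farmer's field is classified from tissue-sample evidence collected 70 days
after sowing:

* ``non_bt``   — every strip test negative;
* ``weak_bt``  — at least one positive strip, ELISA expression below the
  effectiveness threshold (default 1.90 ug/g);
* ``true_bt``  — at least one positive strip, expression at or above the
  threshold.

The cross-tabulation of self-reported beliefs against strip outcomes
quantifies how often beliefs are wrong in a poorly regulated seed market:
the type I error rate is the share of self-declared Bt users whose strips
were all negative; the type II error rate is the share of self-declared
non-Bt users with at least one positive strip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .datagen import BELIEFS, EXPRESSION_THRESHOLD

__all__ = [
    "classify_lab_adoption",
    "classify_survey",
    "BeliefLabCrossTab",
    "cross_tabulate",
    "misclassification_rates",
]

logger = logging.getLogger(__name__)

_BASES = {
    "non_bt": "strip_all_negative",
    "weak_bt": "strip_positive_low_expression",
    "true_bt": "strip_positive_high_expression",
}


def classify_lab_adoption(strip_results: Sequence[int], expression: float,
                          threshold: float = EXPRESSION_THRESHOLD) -> str:
    """Classify one farmer from strip tests and the ELISA expression level.

    ``strip_results`` may be a sequence of 0/1 or a string like ``"10"``.
    A positive strip combined with expression below the threshold is
    accepted as ``weak_bt`` (strip tests can detect low expression levels
    that the threshold rules out; no consistency repair is attempted).
    """
    if isinstance(strip_results, (int, np.integer)):
        strip_results = str(strip_results)  # CSV round-trips "10" as 10
    if isinstance(strip_results, str):
        strip_results = [int(c) for c in strip_results]
    strips = list(strip_results)
    if len(strips) == 0:
        raise ValueError("cannot classify adoption: no strip-test results")
    if any(s not in (0, 1) for s in strips):
        raise ValueError("strip results must be binary")
    if expression < 0:
        raise ValueError(f"expression level must be non-negative, got {expression}")
    if not any(strips):
        return "non_bt"
    return "true_bt" if expression >= threshold else "weak_bt"


def classify_survey(df: pd.DataFrame, threshold: float = EXPRESSION_THRESHOLD,
                    expression_agg: str = "max") -> pd.Series:
    """Vectorized classification of a survey table.

    Expects ``strip_results`` (string of 0/1 per tested sample) and
    ``bt_expression`` columns. When a record carries multiple expression
    readings (list-valued), they are aggregated per ``expression_agg``
    ("max", matching the at-least-one-positive logic, or "mean").
    """
    if expression_agg not in ("max", "mean"):
        raise ValueError("expression_agg must be 'max' or 'mean'")

    def _agg(v):
        if np.isscalar(v) or isinstance(v, (int, float)):
            return float(v)
        arr = np.asarray(v, dtype=float)
        return float(arr.max() if expression_agg == "max" else arr.mean())

    expr = df["bt_expression"].map(_agg)
    return pd.Series(
        [classify_lab_adoption(s, e, threshold)
         for s, e in zip(df["strip_results"], expr)],
        index=df.index, name="lab_category",
    )


@dataclass
class BeliefLabCrossTab:
    """Belief x strip-outcome cross-tabulation, per province and pooled.

    ``table`` is tidy: one row per (province, belief, strip_outcome) with
    the count and cell means of expression (ug/g) and pesticide use
    (kg/acre). ``n_excluded`` counts records dropped for an unknown belief
    code.
    """

    table: pd.DataFrame
    n_excluded: int = 0

    def counts(self, province: Optional[str] = None) -> pd.DataFrame:
        """Counts pivoted to belief rows x strip-outcome columns."""
        t = self.table if province is None else self.table[
            self.table["province"] == province]
        out = (t.groupby(["belief", "strip_outcome"], observed=True)["n"]
               .sum().unstack(fill_value=0))
        for col in ("all_negative", "at_least_one_positive"):
            if col not in out.columns:
                out[col] = 0
        out = out[["all_negative", "at_least_one_positive"]]
        out["total"] = out.sum(axis=1)
        return out

    @property
    def provinces(self):
        return sorted(self.table["province"].unique())

    @classmethod
    def from_counts(cls, counts: Dict[str, Dict[str, Iterable[int]]]
                    ) -> "BeliefLabCrossTab":
        """Build a cross-tab from printed counts.

        ``counts[province][belief] = (n_all_negative, n_at_least_one_positive)``.
        """
        rows = []
        for prov, by_belief in counts.items():
            for belief, (neg, pos) in by_belief.items():
                if belief not in BELIEFS:
                    raise ValueError(f"unknown belief code {belief!r}")
                rows.append((prov, belief, "all_negative", int(neg), np.nan, np.nan))
                rows.append((prov, belief, "at_least_one_positive", int(pos),
                             np.nan, np.nan))
        return cls(pd.DataFrame(
            rows, columns=["province", "belief", "strip_outcome", "n",
                           "mean_expression", "mean_pesticide"]))


def cross_tabulate(df: pd.DataFrame) -> BeliefLabCrossTab:
    """Cross-tabulate self-reported belief against the strip-test outcome.

    Records with an unrecognized belief code are excluded with a logged
    count. Cell summaries report mean expression and mean pesticide use.
    """
    known = df["belief"].isin(BELIEFS)
    n_excluded = int((~known).sum())
    if n_excluded:
        logger.warning("cross_tabulate: excluded %d record(s) with unknown "
                       "belief codes %s", n_excluded,
                       sorted(df.loc[~known, "belief"].unique()))
    d = df[known].copy()
    strip_pos = d["strip_results"].map(
        lambda s: any(int(c) for c in s) if isinstance(s, str) else any(s))
    d["strip_outcome"] = np.where(strip_pos, "at_least_one_positive",
                                  "all_negative")
    g = (d.groupby(["province", "belief", "strip_outcome"], observed=True)
         .agg(n=("belief", "size"),
              mean_expression=("bt_expression", "mean"),
              mean_pesticide=("pesticide_qty", "mean"))
         .reset_index())
    return BeliefLabCrossTab(g, n_excluded=n_excluded)


def misclassification_rates(xtab: BeliefLabCrossTab,
                            include_no_response: bool = False) -> pd.DataFrame:
    """Belief-conditional error rates per province (and pooled).

    type1 = P(all strips negative | belief Bt); type2 = P(>=1 strip positive
    | belief non-Bt); ``self_reported_adoption`` = share declaring Bt;
    ``lab_adoption`` = share with >=1 positive strip;
    ``incorrect_or_uncertain`` = (type I count + type II count + don't-know
    count) / province total — the no-response row is excluded by default.
    Empty denominators yield NaN (undefined), never zero.
    """
    rows = {}
    for prov in list(xtab.provinces) + ["pooled"]:
        c = xtab.counts(None if prov == "pooled" else prov)
        tot = float(c["total"].sum())
        if tot == 0:
            continue

        def cell(belief, col):
            return float(c.at[belief, col]) if belief in c.index else 0.0

        n_bt = cell("bt", "total")
        n_non = cell("non_bt", "total")
        t1_count = cell("bt", "all_negative")
        t2_count = cell("non_bt", "at_least_one_positive")
        uncertain = cell("dont_know", "total")
        if include_no_response:
            uncertain += cell("no_response", "total")
        rows[prov] = {
            "type1": t1_count / n_bt if n_bt else np.nan,
            "type2": t2_count / n_non if n_non else np.nan,
            "self_reported_adoption": n_bt / tot,
            "lab_adoption": float(c["at_least_one_positive"].sum()) / tot,
            "incorrect_or_uncertain": (t1_count + t2_count + uncertain) / tot,
            "n": tot,
        }
    return pd.DataFrame(rows).T
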