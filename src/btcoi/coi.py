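"""Cost-of-illness accounting.

Builds the outcome pair (dh, Qh) from self-reported treatment expenses for
acute pesticide-related symptoms over one cotton season:

* direct cost  = self-treatment + physician consultation + medication +
  travel to/from health facilities (Rs);
* indirect cost = work days lost x local daily wage (Rs);
* Qh = direct + indirect; dh = 1 iff Qh > 0.

A farmer who lost work days but spent no cash still counts as treated
(dh = 1): recovery time is treatment. The total is a lower-bound estimate of
the true cost of ill health — nursing time, lost leisure, intangible costs
(pain, discomfort) and chronic effects are not monetized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CostComponents", "CostOfIllness", "direct_cost", "indirect_cost",
           "build_outcome", "add_cost_columns"]

DIRECT_FIELDS = ("self_treatment", "consultation", "medication", "travel")


@dataclass
class CostComponents:
    self_treatment: float = 0.0
    consultation: float = 0.0
    medication: float = 0.0
    travel: float = 0.0
    days_lost: float = 0.0
    wage: float = 0.0

    def validate(self):
        for name in DIRECT_FIELDS + ("days_lost", "wage"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"cost component {name!r} must be a "
                                 f"non-negative number, got {v}")
        if self.days_lost > 0 and self.wage <= 0:
            raise ValueError(
                "days_lost > 0 requires a positive wage to value lost time")
        return self


@dataclass
class CostOfIllness:
    dh: int
    direct: float
    indirect: float
    total: float


def direct_cost(c: CostComponents) -> float:
    """Sum of the four out-of-pocket treatment components (Rs)."""
    c.validate()
    return float(sum(getattr(c, f) for f in DIRECT_FIELDS))


def indirect_cost(c: CostComponents) -> float:
    """Opportunity cost of work days lost, valued at the daily wage (Rs)."""
    c.validate()
    return float(c.days_lost * c.wage)


def build_outcome(c: CostComponents) -> CostOfIllness:
    """Assemble (dh, Qh) for one farmer-season."""
    d = direct_cost(c)
    ind = indirect_cost(c)
    total = d + ind
    return CostOfIllness(dh=int(total > 0), direct=d, indirect=ind, total=total)


def add_cost_columns(df: pd.DataFrame, wage_fallback: float | None = None
                     ) -> pd.DataFrame:
    """Vectorized accounting over a survey table.

    Adds ``direct``, ``indirect``, ``qh`` and ``dh`` columns. ``wage_fallback``
    (e.g. a village-median wage) fills missing wages; records with days lost
    but no usable wage raise, naming the offending rows.
    """
    out = df.copy()
    for f in DIRECT_FIELDS + ("days_lost",):
        vals = out[f].to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            bad = out.index[~np.isfinite(vals) | (vals < 0)][:10].tolist()
            raise ValueError(f"column {f!r} has negative or non-finite values "
                             f"at rows {bad}")
    wage = out["wage"].to_numpy(dtype=float)
    if wage_fallback is not None:
        wage = np.where(np.isfinite(wage) & (wage > 0), wage, wage_fallback)
    days = out["days_lost"].to_numpy(dtype=float)
    needs_wage = (days > 0) & ~(np.isfinite(wage) & (wage > 0))
    if needs_wage.any():
        bad = out.index[needs_wage][:10].tolist()
        raise ValueError(
            f"days_lost > 0 with missing/non-positive wage at rows {bad}; "
            "provide wage_fallback to impute")
    out["direct"] = sum(out[f].to_numpy(dtype=float) for f in DIRECT_FIELDS)
    out["indirect"] = np.where(days > 0, days * wage, 0.0)
    out["qh"] = out["direct"] + out["indirect"]
    out["dh"] = (out["qh"] > 0).astype(int)
    return out
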