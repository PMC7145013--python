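"""Publication-style descriptive summaries.

Categorical variables are reported as absolute number and proportion (%,
2 decimals, count over the arm denominator); costs as mean with standard
deviation (1 decimal in display output, full precision in the machine-readable
summary).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import COST_COLUMNS, total_90day_cost
from .params import CHRONIC_FLAGS

__all__ = ["rate_pct", "descriptive_table", "cost_outcome_table"]

_CATEGORICALS = ("age_group", "sex", "region", "surgery_type")


def rate_pct(count: float, denom: float) -> float:
    """count / denominator x 100, reported to 2 decimals."""
    if denom <= 0:
        return 0.0
    return round(100.0 * count / denom, 2)


def _arm_label(df: pd.DataFrame) -> pd.Series:
    if "is_case" in df.columns:
        return df["is_case"].map({1: "vte", 0: "control"})
    if "vte" in df.columns:
        return df["vte"].map({1: "vte", 0: "no_vte"})
    return pd.Series(["all"] * len(df), index=df.index)


def descriptive_table(df: pd.DataFrame) -> pd.DataFrame:
    """Characteristics table: n (%) per covariate level, per arm."""
    if len(df) == 0:
        raise ValueError("empty cohort")
    arms = _arm_label(df)
    rows = []
    for arm in arms.unique():
        sub = df.loc[arms == arm]
        n = len(sub)
        for var in _CATEGORICALS:
            for level in sorted(sub[var].astype(str).unique()):
                c = int((sub[var].astype(str) == level).sum())
                rows.append((arm, f"{var}[{level}]", c, rate_pct(c, n)))
        for var in ("emergency", *CHRONIC_FLAGS):
            if var in sub.columns:
                c = int(sub[var].sum())
                rows.append((arm, var, c, rate_pct(c, n)))
    return pd.DataFrame(rows, columns=["arm", "variable", "n", "pct"])


def cost_outcome_table(df: pd.DataFrame) -> pd.DataFrame:
    """90-day outcomes and expenditures per arm: event rates as n (%), cost
    components and total as mean +/- SD."""
    if len(df) == 0:
        raise ValueError("empty cohort")
    arms = _arm_label(df)
    rows = []
    for arm in arms.unique():
        sub = df.loc[arms == arm]
        n = len(sub)
        for outcome in ("rmpo", "ovp"):
            c = int(sub[outcome].sum())
            rows.append((arm, f"{outcome}_rate", float(c), rate_pct(c, n)))
        for col in COST_COLUMNS:
            x = sub[col].to_numpy(float)
            rows.append((arm, f"{col}_mean", float(np.mean(x)), float(np.std(x, ddof=1))))
        tot = total_90day_cost(sub).to_numpy(float)
        rows.append((arm, "total_cost_mean", float(np.mean(tot)), float(np.std(tot, ddof=1))))
        rows.append((arm, "n", float(n), float("nan")))
    return pd.DataFrame(rows, columns=["arm", "measure", "value", "pct_or_sd"])
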