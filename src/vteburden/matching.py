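"""Probit propensity scores and 1:1 nearest-neighbor matching.

Cases are paired to the control with the closest propensity score, greedily,
without replacement by default (each control used at most once), processing
cases in descending score order so the hardest-to-match cases pick first.
Ties in distance go to the lowest control id.  Balance is summarised per
covariate as case %, control % and the standardized mean difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .glm import DesignSpec, ModelFit, build_design, fit_probit
from .params import CHRONIC_FLAGS

__all__ = [
    "PropensityFit",
    "MatchedCohort",
    "default_propensity_spec",
    "estimate_propensity",
    "match_nearest_neighbor",
    "build_matched_frame",
    "balance_table",
]


@dataclass
class PropensityFit:
    model: ModelFit
    #: probit scores Phi(x beta), indexed by episode_id
    scores: pd.Series


@dataclass
class MatchedCohort:
    #: columns: case_id, control_id, distance (|score difference|)
    pairs: pd.DataFrame
    unmatched_cases: list
    balance: pd.DataFrame | None = None


def default_propensity_spec(include_emergency: bool = False) -> DesignSpec:
    """Exposure model covariates: sex, age group, surgery type, provider region
    and the 30 chronic-condition flags (emergency admission optional)."""
    terms = ["sex", "age_group", "surgery_type", "region"]
    if include_emergency:
        terms.append("emergency")
    terms += list(CHRONIC_FLAGS)
    return DesignSpec(response="vte", terms=terms)


def estimate_propensity(cohort: pd.DataFrame, spec: DesignSpec | None = None) -> PropensityFit:
    if spec is None:
        spec = default_propensity_spec()
    X, y = build_design(cohort, spec)
    # unobserved levels / empty flags carry no information; drop them so the
    # design stays full rank
    X = X[[c for c in X.columns if c == "intercept" or X[c].nunique() > 1]]
    fit = fit_probit(X, y)
    eta = X.to_numpy(float) @ fit.params.to_numpy()
    scores = pd.Series(special.ndtr(eta), index=cohort["episode_id"].to_numpy())
    return PropensityFit(model=fit, scores=scores)


def match_nearest_neighbor(
    scores: pd.Series,
    case_ids,
    control_ids,
    replacement: bool = False,
    caliper: float | None = None,
    order: str = "descending",
    seed: int | None = None,
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor matching on the propensity score.

    ``scores`` is indexed by episode id and must cover all case and control
    ids (disjoint sets).  ``order`` controls case processing: "descending"
    (default) / "ascending" by case score, or "random" (requires ``seed``).
    Deterministic given options and seed.
    """
    case_ids = np.asarray(list(case_ids))
    control_ids = np.asarray(list(control_ids))
    if len(np.intersect1d(case_ids, control_ids)):
        raise ValueError("case and control id sets must be disjoint")
    if len(control_ids) == 0:
        warnings.warn("no controls available; all cases unmatched", stacklevel=2)
        return MatchedCohort(
            pairs=pd.DataFrame(columns=["case_id", "control_id", "distance"]),
            unmatched_cases=list(case_ids),
        )
    cs = scores.loc[case_ids].to_numpy(float)
    # controls sorted by (score, id) so equal-score runs are id-ordered
    ctab = pd.DataFrame({"id": control_ids, "score": scores.loc[control_ids].to_numpy(float)})
    ctab = ctab.sort_values(["score", "id"], kind="mergesort").reset_index(drop=True)
    c_score = ctab["score"].to_numpy()
    c_id = ctab["id"].to_numpy()
    avail = np.ones(len(ctab), bool)

    if order == "descending":
        case_order = np.lexsort((case_ids, -cs))
    elif order == "ascending":
        case_order = np.lexsort((case_ids, cs))
    elif order == "random":
        case_order = np.random.default_rng(seed).permutation(len(case_ids))
    else:
        raise ValueError(f"unknown order {order!r}")

    def _scan(start, step):
        j = start
        while 0 <= j < len(avail):
            if avail[j]:
                return j
            j += step
        return -1

    def _tie_candidates(j, s, dstar):
        """available controls at exactly |score - s| == dstar around slot j"""
        out = [j]
        for step in (-1, 1):
            k = j + step
            while 0 <= k < len(avail) and c_score[k] == c_score[j]:
                if avail[k]:
                    out.append(k)
                k += step
        return out

    pairs = []
    unmatched = []
    for ci in case_order:
        s = cs[ci]
        pos = np.searchsorted(c_score, s)
        left = _scan(pos - 1, -1)
        right = _scan(pos, +1)
        cand = []
        if left >= 0:
            cand.append((abs(s - c_score[left]), left))
        if right >= 0:
            cand.append((abs(s - c_score[right]), right))
        if not cand:
            unmatched.append(case_ids[ci])
            continue
        dstar = min(d for d, _ in cand)
        if caliper is not None and dstar > caliper:
            unmatched.append(case_ids[ci])
            continue
        slots = []
        for d, j in cand:
            if d == dstar:
                slots.extend(_tie_candidates(j, s, dstar))
        best = min(slots, key=lambda j: c_id[j])
        pairs.append((case_ids[ci], c_id[best], dstar))
        if not replacement:
            avail[best] = False

    pairs_df = pd.DataFrame(pairs, columns=["case_id", "control_id", "distance"])
    if unmatched:
        warnings.warn(f"{len(unmatched)} case(s) left unmatched", stacklevel=2)
    if not replacement and pairs_df["control_id"].duplicated().any():
        raise AssertionError("control reused without replacement")  # pragma: no cover
    return MatchedCohort(pairs=pairs_df, unmatched_cases=unmatched)


def build_matched_frame(cohort: pd.DataFrame, matched: MatchedCohort) -> pd.DataFrame:
    """Episode rows of the matched sample with ``pair_id`` and ``is_case``."""
    by_id = cohort.set_index("episode_id", drop=False)
    n = len(matched.pairs)
    cases = by_id.loc[matched.pairs["case_id"].to_numpy()].copy()
    controls = by_id.loc[matched.pairs["control_id"].to_numpy()].copy()
    cases["pair_id"] = np.arange(n)
    controls["pair_id"] = np.arange(n)
    cases["is_case"] = 1
    controls["is_case"] = 0
    return pd.concat([cases, controls], ignore_index=True)


def _indicator_columns(df: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        s = df[cov]
        if s.dtype == object or str(s.dtype) == "category":
            for level in sorted(s.astype(str).unique()):
                cols[f"{cov}[{level}]"] = (s.astype(str) == level).to_numpy(float)
        else:
            cols[cov] = pd.to_numeric(s).to_numpy(float)
    return pd.DataFrame(cols, index=df.index)


def balance_table(matched_frame: pd.DataFrame, covariates) -> pd.DataFrame:
    """Case %, control % and standardized mean difference per covariate.

    SMD = (mean1 - mean0) / sqrt((s1^2 + s0^2) / 2) with sample variances;
    reported as 0 when both arms have zero variance.  |SMD| > 0.1 flagged.
    """
    if len(matched_frame) == 0:
        raise ValueError("matched sample is empty")
    ind = _indicator_columns(matched_frame, covariates)
    is_case = matched_frame["is_case"].to_numpy(bool)
    rows = {}
    for col in ind.columns:
        x1 = ind[col].to_numpy()[is_case]
        x0 = ind[col].to_numpy()[~is_case]
        m1, m0 = x1.mean(), x0.mean()
        v1 = x1.var(ddof=1) if len(x1) > 1 else 0.0
        v0 = x0.var(ddof=1) if len(x0) > 1 else 0.0
        denom = np.sqrt((v1 + v0) / 2.0)
        smd = 0.0 if denom == 0 else (m1 - m0) / denom
        rows[col] = {
            "case_pct": round(100.0 * m1, 2),
            "control_pct": round(100.0 * m0, 2),
            "smd": smd,
            "imbalanced": bool(abs(smd) > 0.1),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
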