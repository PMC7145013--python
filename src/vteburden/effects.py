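"""Adjusted excess outcomes and costs of postoperative VTE on the matched cohort.

The estimation strategy is counterfactual standardization ("recycled
predictions"): every matched episode is predicted twice — once with the VTE
exposure switched on, once off — and the mean difference is the adjusted
excess.  Event rates use logistic models (average marginal effect); costs use
OLS on log cost retransformed to dollars with the Duan smearing factor
(mean of exponentiated residuals); hospital days use a linear model.
Standard errors come from a seeded nonparametric bootstrap over matched pairs
(the model is refitted and re-smeared in every resample).

Component costs that are exactly zero when the triggering event is absent are
handled with a two-part model: logistic "any cost" times log-linear "cost
given positive", combined in the counterfactual prediction.  This reduces to
the plain log-linear method when all costs are positive, as for total cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .cohort import COST_COLUMNS, total_90day_cost
from .glm import DesignSpec, ModelFit, build_design, fit_logistic, fit_ols, _newton_binary
from .params import VTE_CLASSES

__all__ = [
    "DEFAULT_ADJUSTMENT_TERMS",
    "SmearingCostModel",
    "smearing_factor",
    "fit_smearing_model",
    "outcome_odds_ratios",
    "excess_event_rate",
    "excess_cost",
    "excess_hospital_days",
    "excess_table",
    "cumulative_cost_curve",
]

#: covariates the matched-sample outcome/cost models adjust for
DEFAULT_ADJUSTMENT_TERMS = ("age_group", "sex", "region", "surgery_type")

_CLASS_SPEC_LEVELS = ("NONE",) + VTE_CLASSES


def smearing_factor(residuals) -> float:
    """Duan's smearing estimator: the mean of exp(residual).

    >= 1 for residuals from an intercept-containing OLS fit (Jensen).
    """
    r = np.asarray(residuals, float)
    if r.size == 0:
        raise ValueError("smearing factor requires a non-empty residual vector")
    return float(np.mean(np.exp(r)))


@dataclass
class SmearingCostModel:
    """Log-cost OLS fit plus its retransformation factor."""

    fit: ModelFit
    smearing: float

    def predict_dollars(self, X) -> np.ndarray:
        Xm = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return self.smearing * np.exp(Xm @ self.fit.params.to_numpy())


def fit_smearing_model(X, cost) -> SmearingCostModel:
    cost = np.asarray(cost, float)
    if (cost <= 0).any():
        raise ValueError(
            "log-cost model requires strictly positive costs; zero-valued "
            "components must go through the two-part route (see excess_cost)"
        )
    fit = fit_ols(X, np.log(cost))
    return SmearingCostModel(fit=fit, smearing=smearing_factor(fit.residuals))


# ---------------------------------------------------------------------------
# design workspace shared by the point estimators and the pair bootstrap

def _exposure_columns(vte_class: str) -> tuple[list[str], str]:
    """(all exposure dummy columns, the column toggled to 1) for a class."""
    if vte_class in ("ALL", "ANY", "vte"):
        return ["vte"], "vte"
    if vte_class not in VTE_CLASSES:
        raise ValueError(f"unknown VTE class {vte_class!r}")
    cols = [f"vte_class[{c}]" for c in VTE_CLASSES]
    return cols, f"vte_class[{vte_class}]"


def _design_for(df: pd.DataFrame, vte_class: str, terms) -> pd.DataFrame:
    if vte_class in ("ALL", "ANY", "vte"):
        spec = DesignSpec(response="vte", terms=["vte", *terms])
    else:
        spec = DesignSpec(
            response="vte",
            terms=["vte_class", *terms],
            categories={
                "vte_class": _CLASS_SPEC_LEVELS,
                **{k: v for k, v in DesignSpec("y", []).categories.items()},
            },
        )
    X, _ = build_design(df, spec)
    # drop empty / constant dummies (e.g. a class or region unobserved in a
    # bootstrap resample) so the fit stays full rank; a dropped exposure dummy
    # simply makes that class's cells unavailable on this frame
    keep = [c for c in X.columns if c == "intercept" or X[c].nunique() > 1]
    return X[keep]


def _counterfactual(X: pd.DataFrame, vte_class: str) -> tuple[np.ndarray, np.ndarray]:
    """Design copies with the exposure set to the given class vs none."""
    cols, target = _exposure_columns(vte_class)
    X1 = X.copy()
    X0 = X.copy()
    for c in cols:
        if c in X1.columns:
            X1[c] = 0.0
            X0[c] = 0.0
    X1[target] = 1.0
    return X1.to_numpy(float), X0.to_numpy(float)


def _require_class(X: pd.DataFrame, vte_class: str) -> None:
    _, target = _exposure_columns(vte_class)
    if target not in X.columns:
        raise ValueError(f"exposure column {target!r} absent from the fitted design")


def _ame_from_fit(fit: ModelFit, X: pd.DataFrame, vte_class: str) -> float:
    _require_class(X, vte_class)
    X1, X0 = _counterfactual(X, vte_class)
    b = fit.params.to_numpy()
    return float(np.mean(special.expit(X1 @ b) - special.expit(X0 @ b)))


def _pair_bootstrap(df: pd.DataFrame, stat_fn, n_boot: int, seed: int) -> pd.Series:
    """SE of each statistic under resampling of matched pairs.

    ``stat_fn(frame) -> dict[str, float]``; resamples where a statistic is
    undefined (degenerate subsample) contribute NaN and are dropped.
    """
    rng = np.random.default_rng(seed)
    rows_of = df.groupby("pair_id").indices
    pair_ids = np.array(list(rows_of))
    stats = []
    for _ in range(n_boot):
        take = rng.choice(pair_ids, size=len(pair_ids), replace=True)
        idx = np.concatenate([rows_of[p] for p in take])
        boot = df.iloc[idx].reset_index(drop=True)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stats.append(stat_fn(boot))
        except (ValueError, np.linalg.LinAlgError):
            stats.append({})
    table = pd.DataFrame(stats)
    return table.std(ddof=1, skipna=True)


def outcome_odds_ratios(
    matched: pd.DataFrame,
    outcome: str,
    terms=DEFAULT_ADJUSTMENT_TERMS,
    by_class: bool = True,
) -> pd.DataFrame:
    """Adjusted odds ratios for a 90-day outcome (RMPO or OVP) with Wald
    p-values; VTE enters as class dummies (reference: no VTE)."""
    X = _design_for(matched, "PE" if by_class else "ALL", list(terms))
    fit = fit_logistic(X, matched[outcome])
    table = fit.odds_ratios()
    table["significant"] = table["p_value"] < 0.05
    return table


def excess_event_rate(
    matched: pd.DataFrame,
    outcome: str,
    vte_class: str = "ALL",
    terms=DEFAULT_ADJUSTMENT_TERMS,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Adjusted excess event probability (average marginal effect) and its
    matched-pair bootstrap SE."""

    def stat(frame):
        X = _design_for(frame, vte_class, list(terms))
        fit = _newton_binary(X, frame[outcome], "logit")
        return {"ame": _ame_from_fit(fit, X, vte_class)}

    X = _design_for(matched, vte_class, list(terms))
    fit = fit_logistic(X, matched[outcome])
    point = _ame_from_fit(fit, X, vte_class)
    se = float(_pair_bootstrap(matched, stat, n_boot, seed)["ame"]) if n_boot else float("nan")
    return point, se


def _two_part_excess(frame: pd.DataFrame, cost_col: str, vte_class: str, terms) -> float:
    """Counterfactual excess for one cost quantity on one frame.

    Total cost (all positive) uses the plain smearing model; components with
    zeros use logistic(any cost) x log-linear(cost | positive).
    """
    X = _design_for(frame, vte_class, list(terms))
    _require_class(X, vte_class)
    if cost_col == "total":
        cost = total_90day_cost(frame).to_numpy(float)
    else:
        cost = frame[cost_col].to_numpy(float)
    if (cost < 0).any():
        raise ValueError("negative costs are invalid")
    pos = cost > 0
    X1, X0 = _counterfactual(X, vte_class)
    if pos.all():
        model = fit_smearing_model(X, cost)
        b = model.fit.params.to_numpy()
        return float(np.mean(model.smearing * (np.exp(X1 @ b) - np.exp(X0 @ b))))
    if not pos.any():
        return 0.0
    # part 1: probability of incurring any cost
    fit1 = _newton_binary(X, pos.astype(float), "logit")
    g = fit1.params.to_numpy()
    p1 = special.expit(X1 @ g)
    p0 = special.expit(X0 @ g)
    # part 2: dollars given positive, with Duan retransformation
    if pos.sum() <= X.shape[1]:
        raise ValueError(f"too few positive observations for {cost_col!r}")
    model = fit_smearing_model(X.loc[pos], cost[pos])
    b = model.fit.params.to_numpy()
    mu1 = model.smearing * np.exp(X1 @ b)
    mu0 = model.smearing * np.exp(X0 @ b)
    return float(np.mean(p1 * mu1 - p0 * mu0))


def excess_cost(
    matched: pd.DataFrame,
    cost_col: str = "total",
    vte_class: str = "ALL",
    terms=DEFAULT_ADJUSTMENT_TERMS,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Adjusted excess 90-day cost (US$) due to the VTE class, with pair
    bootstrap SE.  ``cost_col`` is "total" or one of the component columns."""

    def stat(frame):
        return {"d": _two_part_excess(frame, cost_col, vte_class, terms)}

    point = _two_part_excess(matched, cost_col, vte_class, terms)
    se = float(_pair_bootstrap(matched, stat, n_boot, seed)["d"]) if n_boot else float("nan")
    return point, se


def excess_hospital_days(
    matched: pd.DataFrame,
    vte_class: str = "ALL",
    terms=DEFAULT_ADJUSTMENT_TERMS,
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[float, float]:
    """Adjusted excess hospital days (linear-model recycled prediction)."""

    def point_fn(frame):
        X = _design_for(frame, vte_class, list(terms))
        _require_class(X, vte_class)
        fit = fit_ols(X, frame["hospital_days"])
        X1, X0 = _counterfactual(X, vte_class)
        b = fit.params.to_numpy()
        return {"d": float(np.mean(X1 @ b - X0 @ b))}

    point = point_fn(matched)["d"]
    se = float(_pair_bootstrap(matched, point_fn, n_boot, seed)["d"]) if n_boot else float("nan")
    return point, se


_COMPONENT_LABELS = {
    "cost_rmpo": "excess_rmpo_cost",
    "cost_rmpo_drug": "excess_rmpo_drug_cost",
    "cost_ovp": "excess_ovp_cost",
    "cost_ovp_drug": "excess_ovp_drug_cost",
}


def excess_table(
    matched: pd.DataFrame,
    classes=("ALL",) + VTE_CLASSES,
    terms=DEFAULT_ADJUSTMENT_TERMS,
    n_boot: int = 500,
    seed: int = 0,
    components: bool = True,
) -> pd.DataFrame:
    """Adjusted excess outcomes and payments per VTE class, with one shared
    matched-pair bootstrap for every cell's SE.

    One model per outcome/cost quantity is fitted per exposure coding (binary
    "any VTE" for the ALL row, class dummies for the class rows) and every
    class's cells are read off that fit by recycled prediction.
    """

    def stats(frame):
        out = {}
        class_rows = [c for c in classes if c != "ALL"]
        designs = []
        if "ALL" in classes:
            designs.append((["ALL"], _design_for(frame, "ALL", list(terms))))
        if class_rows:
            designs.append((class_rows, _design_for(frame, class_rows[0], list(terms))))
        for cls_group, X in designs:
            # shared fits for this exposure coding
            fits: dict[str, object] = {}
            for outcome in ("rmpo", "ovp"):
                try:
                    fits[outcome] = _newton_binary(X, frame[outcome], "logit")
                except ValueError:
                    fits[outcome] = None
            total = total_90day_cost(frame).to_numpy(float)
            fits["total"] = fit_smearing_model(X, total) if (total > 0).all() else None
            comp_fits = {}
            if components:
                for col in _COMPONENT_LABELS:
                    cost = frame[col].to_numpy(float)
                    pos = cost > 0
                    try:
                        if pos.all():
                            comp_fits[col] = (None, fit_smearing_model(X, cost))
                        elif pos.sum() > X.shape[1]:
                            comp_fits[col] = (
                                _newton_binary(X, pos.astype(float), "logit"),
                                fit_smearing_model(X.loc[pos], cost[pos]),
                            )
                        else:
                            comp_fits[col] = None
                    except ValueError:
                        comp_fits[col] = None
            fits["hosp"] = fit_ols(X, frame["hospital_days"])

            for cls in cls_group:
                _, target = _exposure_columns(cls)
                if target not in X.columns:
                    continue  # class unobserved on this frame
                X1, X0 = _counterfactual(X, cls)
                for outcome, label in (("rmpo", "excess_rmpo_rate"), ("ovp", "excess_ovp_rate")):
                    if fits[outcome] is not None:
                        b = fits[outcome].params.to_numpy()
                        out[f"{cls}.{label}"] = float(
                            np.mean(special.expit(X1 @ b) - special.expit(X0 @ b))
                        )
                if fits["total"] is not None:
                    m = fits["total"]
                    b = m.fit.params.to_numpy()
                    out[f"{cls}.excess_total_cost"] = float(
                        np.mean(m.smearing * (np.exp(X1 @ b) - np.exp(X0 @ b)))
                    )
                for col, label in _COMPONENT_LABELS.items():
                    if not components or comp_fits.get(col) is None:
                        continue
                    part1, part2 = comp_fits[col]
                    b = part2.fit.params.to_numpy()
                    mu1 = part2.smearing * np.exp(X1 @ b)
                    mu0 = part2.smearing * np.exp(X0 @ b)
                    if part1 is None:
                        p1 = p0 = 1.0
                    else:
                        g = part1.params.to_numpy()
                        p1, p0 = special.expit(X1 @ g), special.expit(X0 @ g)
                    out[f"{cls}.{label}"] = float(np.mean(p1 * mu1 - p0 * mu0))
                b = fits["hosp"].params.to_numpy()
                out[f"{cls}.excess_hospital_days"] = float(np.mean((X1 - X0) @ b))
        return out

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        point = stats(matched)
    se = _pair_bootstrap(matched, stats, n_boot, seed) if n_boot else pd.Series(dtype=float)
    rows = {}
    for key, val in point.items():
        cls, label = key.split(".", 1)
        rows.setdefault(cls, {})[label] = val
        rows[cls][f"{label}_se"] = float(se.get(key, np.nan))
    return pd.DataFrame.from_dict(rows, orient="index")


def cumulative_cost_curve(matched: pd.DataFrame, horizon: int = 90) -> pd.DataFrame:
    """Cumulative mean cost per arm by day since surgery.

    Surgery payment accrues at day 0; readmission and outpatient components at
    their recorded event days.  Events dated outside [0, horizon] are excluded
    with a warning.  Curves are monotone non-decreasing, and when nothing is
    excluded the day-``horizon`` gap equals the difference in arm mean totals.
    """
    events = [
        ("cost_surgery", np.zeros(len(matched), int)),
        ("cost_rmpo", matched["rmpo_day"].to_numpy(int)),
        ("cost_rmpo_drug", matched["rmpo_day"].to_numpy(int)),
        ("cost_ovp", matched["ovp_day"].to_numpy(int)),
        ("cost_ovp_drug", matched["ovp_day"].to_numpy(int)),
    ]
    is_case = matched["is_case"].to_numpy(bool)
    curves = {}
    excluded = 0
    for arm, mask in (("vte", is_case), ("control", ~is_case)):
        daily = np.zeros(horizon + 1)
        n_arm = max(int(mask.sum()), 1)
        for col, day in events:
            amt = matched[col].to_numpy(float)[mask]
            d = day[mask]
            active = amt > 0
            bad = active & ((d < 0) | (d > horizon))
            excluded += int(bad.sum())
            keep = active & ~bad
            np.add.at(daily, d[keep], amt[keep])
        curves[arm] = np.cumsum(daily) / n_arm
    if excluded:
        warnings.warn(
            f"excluded {excluded} cost event(s) dated outside [0, {horizon}]",
            stacklevel=2,
        )
    return pd.DataFrame(
        {"day": np.arange(horizon + 1), "vte": curves["vte"], "control": curves["control"]}
    )
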