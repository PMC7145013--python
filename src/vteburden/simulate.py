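"""Synthetic surgical-claims cohorts with known ground truth.

One row per surgical episode.  Covariates are drawn independently at their
configured prevalences (age group, region and surgery type as mutually
exclusive categories), postoperative VTE is assigned by a latent probit on
those covariates, diagnosis codes consistent with the drawn VTE class are
emitted with day offsets inside the 90-day window, the five cost components
are log-normal with a multiplicative VTE effect, readmission (RMPO) and
outpatient-visit (OVP) outcomes are logistic, and hospital days are gamma with
an additive VTE shift.

Column dictionary of the episode table (all flags 0/1 integers):

========================  =====================================================
episode_id                integer identifier
age, age_group            years; one of 18-59 / 60-69 / 70-79 / 80+
sex, region, surgery_type categorical strings (see :mod:`vteburden.params`)
emergency                 emergency admission flag
pregnant                  pregnancy flag (eligibility exclusion)
anticoagulant_contraindicated   contraindication flag (eligibility exclusion)
cc_*                      the 30 chronic-condition flags
diagnoses                 "CODE:day;CODE:day" ICD-10 codes with day offsets
rmpo, ovp                 90-day readmission / outpatient-visit-with-problem
rmpo_day, ovp_day         day offset of the event (-1 when absent)
cost_surgery, cost_rmpo, cost_rmpo_drug, cost_ovp, cost_ovp_drug   US$
hospital_days             total hospital days over the 90-day window
========================  =====================================================
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, special

from .params import (
    AGE_LEVELS,
    CHRONIC_FLAGS,
    COST_COMPONENTS,
    REGION_LEVELS,
    SURGERY_LEVELS,
    VTE_CLASSES,
    CohortParams,
)

__all__ = [
    "SyntheticCohort",
    "generate_cohort",
    "linear_predictor",
    "calibrate_probit_intercept",
    "analytic_outcome_ame",
    "analytic_excess_total_cost",
    "write_cohort",
    "read_cohort",
    "write_params",
    "read_params",
]

_AGE_RANGES = {"18-59": (18, 59), "60-69": (60, 69), "70-79": (70, 79), "80+": (80, 95)}

# representative ICD-10 codes per VTE class (DVT_PE pairs a deep-vein code
# with a pulmonary-embolism code)
_CLASS_CODES = {
    "PE": ("I26.0", "I26.9"),
    "PTP": ("I80.1", "I80.2", "I80.3", "I80.8"),
    "VET": ("I82", "I82.9"),
}
_NOISE_CODES = ("J18.9", "K35.8", "S72.0", "E11.9")


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated episode table together with the generating parameters."""

    episodes: pd.DataFrame
    truth: CohortParams


def linear_predictor(df: pd.DataFrame, coefs, vte=None) -> np.ndarray:
    """Evaluate sum(coef * covariate) over episodes.

    Keys: ``intercept``; ``vte`` (uses the supplied 0/1 exposure vector);
    ``term[level]`` for categorical dummies; otherwise a numeric column name.
    """
    eta = np.zeros(len(df))
    for name, c in coefs.items():
        if c == 0.0:
            continue
        if name == "intercept":
            eta += c
        elif name == "vte":
            if vte is None:
                raise ValueError("coefficient on 'vte' given but no exposure vector supplied")
            eta += c * np.asarray(vte, float)
        elif name.endswith("]") and "[" in name:
            col, level = name[:-1].split("[", 1)
            eta += c * (df[col].astype(str) == level).to_numpy(float)
        else:
            eta += c * pd.to_numeric(df[name]).to_numpy(float)
    return eta


def _draw_categorical(rng, levels, probs_map, n):
    levels = list(levels)
    p = np.array([probs_map[lv] for lv in levels], float)
    p = p / p.sum()
    return rng.choice(levels, size=n, p=p)


def _draw_covariates(params: CohortParams, rng: np.random.Generator) -> pd.DataFrame:
    n = params.n_episodes
    df = pd.DataFrame({"episode_id": np.arange(n, dtype=int)})
    df["age_group"] = _draw_categorical(rng, AGE_LEVELS, params.age_group_probs, n)
    age = np.empty(n, int)
    for g, (lo, hi) in _AGE_RANGES.items():
        mask = (df["age_group"] == g).to_numpy()
        age[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    df["age"] = age
    prev = params.covariate_prevalences
    female = rng.random(n) < prev["female"]
    df["sex"] = np.where(female, "female", "male")
    df["region"] = _draw_categorical(rng, REGION_LEVELS, params.region_probs, n)
    df["surgery_type"] = _draw_categorical(rng, SURGERY_LEVELS, params.surgery_probs, n)
    df["emergency"] = (rng.random(n) < prev["emergency"]).astype(int)
    for flag in CHRONIC_FLAGS:
        df[flag] = (rng.random(n) < prev[flag]).astype(int)
    df["pregnant"] = (female & (rng.random(n) < params.pregnancy_rate)).astype(int)
    df["anticoagulant_contraindicated"] = (
        rng.random(n) < params.contraindication_rate
    ).astype(int)
    return df


def generate_cohort(params: CohortParams) -> SyntheticCohort:
    """Draw one cohort; bit-identical for identical params (seed included)."""
    rng = np.random.default_rng(params.seed)
    df = _draw_covariates(params, rng)
    n = params.n_episodes

    # VTE assignment through the latent probit
    eta = linear_predictor(df, params.vte_probit_coefs)
    vte = (rng.random(n) < special.ndtr(eta)).astype(int)
    classes = np.array(["NONE"] * n, dtype=object)
    n_vte = int(vte.sum())
    if n_vte:
        cls_levels = list(VTE_CLASSES)
        p = np.array([params.vte_class_probs[c] for c in cls_levels], float)
        classes[vte == 1] = rng.choice(cls_levels, size=n_vte, p=p / p.sum())

    # diagnosis strings: VTE codes within the 90-day window plus sparse noise
    diagnoses = [""] * n
    vte_idx = np.flatnonzero(vte == 1)
    days = rng.integers(0, 91, size=n_vte)
    for k, i in enumerate(vte_idx):
        cls = classes[i]
        day = int(days[k])
        if cls == "DVT_PE":
            deep = _CLASS_CODES["PTP"][int(rng.integers(0, 3))]  # I80.1-I80.3
            pe = _CLASS_CODES["PE"][int(rng.integers(0, 2))]
            codes = [(deep, day), (pe, min(90, day + int(rng.integers(0, 5))))]
        else:
            pool = _CLASS_CODES[cls]
            codes = [(pool[int(rng.integers(0, len(pool)))], day)]
        diagnoses[i] = ";".join(f"{c}:{d}" for c, d in codes)
    noise = rng.random(n) < 0.05
    noise_code = rng.choice(_NOISE_CODES, size=n)
    noise_day = rng.integers(0, 91, size=n)
    for i in np.flatnonzero(noise):
        extra = f"{noise_code[i]}:{noise_day[i]}"
        diagnoses[i] = f"{diagnoses[i]};{extra}" if diagnoses[i] else extra
    df["diagnoses"] = diagnoses

    # 90-day outcomes (logistic, VTE enters as a single exposure shift)
    for outcome in ("rmpo", "ovp"):
        eta_o = linear_predictor(df, params.outcome_logit_coefs[outcome], vte=vte)
        df[outcome] = (rng.random(n) < special.expit(eta_o)).astype(int)
    df["rmpo_day"] = np.where(df["rmpo"] == 1, rng.integers(1, 91, size=n), -1)
    df["ovp_day"] = np.where(df["ovp"] == 1, rng.integers(1, 91, size=n), -1)

    # cost components: log-normal conditional on the event, exact zero otherwise;
    # VTE multiplies every incurred component
    log_mult = np.log(params.vte_cost_multiplier) * vte
    gate = {
        "surgery": np.ones(n, bool),
        "rmpo": df["rmpo"].to_numpy(bool),
        "rmpo_drug": df["rmpo"].to_numpy(bool),
        "ovp": df["ovp"].to_numpy(bool),
        "ovp_drug": df["ovp"].to_numpy(bool),
    }
    for comp in COST_COMPONENTS:
        mu = params.cost_log_means[comp]
        sd = params.cost_log_sds[comp]
        draw = np.exp(rng.normal(mu, sd, size=n) + log_mult)
        df[f"cost_{comp}"] = np.where(gate[comp], draw, 0.0)

    # hospital days: gamma with additive VTE mean shift
    k = params.los_params["shape"]
    mean = params.los_params["mean"] + params.los_params["vte_effect"] * vte
    df["hospital_days"] = rng.gamma(k, mean / k)

    return SyntheticCohort(episodes=df, truth=params)


def calibrate_probit_intercept(
    params: CohortParams, target_prevalence: float, n_mc: int = 400_000, seed: int = 20_170_101
) -> float:
    """Intercept giving the requested marginal VTE prevalence under the
    configured covariate mix (Monte-Carlo average of the probit link)."""
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must be in (0, 1)")
    mc = params.replace(n_episodes=n_mc, seed=seed)
    rng = np.random.default_rng(seed)
    df = _draw_covariates(mc, rng)
    coefs = dict(params.vte_probit_coefs)
    b0 = coefs.pop("intercept", 0.0)
    eta0 = linear_predictor(df, coefs)

    def gap(b):
        return special.ndtr(eta0 + b).mean() - target_prevalence

    return float(optimize.brentq(gap, b0 - 10.0, b0 + 10.0, xtol=1e-10))


# ---------------------------------------------------------------------------
# closed-form truths under the generating model (oracles for recovery tests)

def analytic_outcome_ame(params: CohortParams, episodes: pd.DataFrame, outcome: str) -> float:
    """True average marginal effect of VTE on the outcome probability over the
    supplied episodes' covariates."""
    coefs = dict(params.outcome_logit_coefs[outcome])
    gamma = coefs.pop("vte", 0.0)
    eta0 = linear_predictor(episodes, coefs)
    return float(np.mean(special.expit(eta0 + gamma) - special.expit(eta0)))


def analytic_excess_total_cost(params: CohortParams, episodes: pd.DataFrame) -> float:
    """True counterfactual mean difference in 90-day total cost, VTE vs no VTE,
    averaged over the supplied episodes' covariates.

    E[T | v, x] = m^v * (E_surgery + p_rmpo(v, x) (E_rmpo + E_rmpo_drug)
                          + p_ovp(v, x) (E_ovp + E_ovp_drug))
    with E_c = exp(mu_c + sd_c^2 / 2) and m the VTE cost multiplier.
    """
    m = params.vte_cost_multiplier
    e = {
        c: np.exp(params.cost_log_means[c] + params.cost_log_sds[c] ** 2 / 2.0)
        for c in COST_COMPONENTS
    }
    out = {}
    for outcome in ("rmpo", "ovp"):
        coefs = dict(params.outcome_logit_coefs[outcome])
        gamma = coefs.pop("vte", 0.0)
        eta0 = linear_predictor(episodes, coefs)
        out[outcome] = (special.expit(eta0), special.expit(eta0 + gamma))
    t0 = e["surgery"] + out["rmpo"][0] * (e["rmpo"] + e["rmpo_drug"]) + out["ovp"][0] * (
        e["ovp"] + e["ovp_drug"]
    )
    t1 = m * (
        e["surgery"]
        + out["rmpo"][1] * (e["rmpo"] + e["rmpo_drug"])
        + out["ovp"][1] * (e["ovp"] + e["ovp_drug"])
    )
    return float(np.mean(t1 - t0))


# ---------------------------------------------------------------------------
# I/O

def write_cohort(episodes: pd.DataFrame, path) -> None:
    episodes.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    if "diagnoses" in df.columns:
        df["diagnoses"] = df["diagnoses"].astype(str)
    return df


def write_params(params: CohortParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(params), sort_keys=True))


def read_params(path) -> CohortParams:
    return CohortParams(**yaml.safe_load(Path(path).read_text()))
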