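"""Parameterisation of the synthetic surgical-claims generator.

The defaults emulate a large national-claims surgical cohort: covariate
prevalences follow the raw-sample column of the study population table
(rounded to the printed percentages), postoperative venous thromboembolism
(VTE) is assigned through a latent probit on those covariates, 90-day cost
components are log-normal with a multiplicative VTE effect, and
readmission / outpatient-visit outcomes are logistic with a VTE log-odds
shift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

AGE_LEVELS = ("18-59", "60-69", "70-79", "80+")
SEX_LEVELS = ("male", "female")
REGION_LEVELS = (
    "north",
    "red_river_delta",
    "central_coast",
    "central_highlands",
    "southeast",
    "southwest",
)
SURGERY_LEVELS = (
    "neurosurgery",
    "cardiothoracic",
    "vascular",
    "gastrointestinal",
    "urologic",
    "orthopedic",
    "plastic",
)

#: the 30 chronic-condition (Elixhauser-derived) flag columns, in table order
CHRONIC_FLAGS = (
    "cc_heart_failure",
    "cc_peripheral_vascular",
    "cc_paralysis",
    "cc_rheumatoid_arthritis",
    "cc_gastric_ulcer",
    "cc_diabetes",
    "cc_diabetes_complications",
    "cc_cancer",
    "cc_metastatic_cancer",
    "cc_liver_disease",
    "cc_liver_failure",
    "cc_renal_failure",
    "cc_dementia",
    "cc_alcohol_abuse",
    "cc_drug_abuse",
    "cc_deficiency_anemia",
    "cc_weight_loss",
    "cc_electrolyte_disorders",
    "cc_lymphoma",
    "cc_hypothyroidism",
    "cc_depression",
    "cc_aplastic_anemia",
    "cc_arrhythmia",
    "cc_valvular_disease",
    "cc_pulmonary_vascular",
    "cc_hypertension",
    "cc_hypertension_complications",
    "cc_coagulopathy",
    "cc_chronic_pulmonary",
    "cc_cerebral_circulatory",
)

#: 90-day cost components (episode columns are ``cost_<name>``)
COST_COMPONENTS = ("surgery", "rmpo", "rmpo_drug", "ovp", "ovp_drug")

VTE_CLASSES = ("PE", "PTP", "VET", "DVT_PE")

# raw-sample prevalences of the binary covariates (non-VTE column)
_DEFAULT_BINARY_PREV = {
    "female": 0.4017,
    "emergency": 0.1946,
    "cc_heart_failure": 0.0062,
    "cc_peripheral_vascular": 0.0019,
    "cc_paralysis": 0.0010,
    "cc_rheumatoid_arthritis": 0.0101,
    "cc_gastric_ulcer": 0.0836,
    "cc_diabetes": 0.0306,
    "cc_diabetes_complications": 0.0005,
    "cc_cancer": 0.0444,
    "cc_metastatic_cancer": 0.0033,
    "cc_liver_disease": 0.0202,
    "cc_liver_failure": 0.0009,
    "cc_renal_failure": 0.0047,
    "cc_dementia": 0.0002,
    "cc_alcohol_abuse": 0.0015,
    "cc_drug_abuse": 0.0001,
    "cc_deficiency_anemia": 0.0026,
    "cc_weight_loss": 0.0071,
    "cc_electrolyte_disorders": 0.0012,
    "cc_lymphoma": 0.0015,
    "cc_hypothyroidism": 0.0009,
    "cc_depression": 0.0003,
    "cc_aplastic_anemia": 0.0031,
    "cc_arrhythmia": 0.0052,
    "cc_valvular_disease": 0.0039,
    "cc_pulmonary_vascular": 0.0005,
    "cc_hypertension": 0.0735,
    "cc_hypertension_complications": 0.0014,
    "cc_coagulopathy": 0.0005,
    "cc_chronic_pulmonary": 0.0123,
    "cc_cerebral_circulatory": 0.0227,
}

_DEFAULT_AGE_PROBS = {"18-59": 0.7775, "60-69": 0.1277, "70-79": 0.0571, "80+": 0.0377}
_DEFAULT_REGION_PROBS = {
    "north": 0.1373,
    "red_river_delta": 0.2293,
    "central_coast": 0.2567,
    "central_highlands": 0.0608,
    "southeast": 0.1764,
    "southwest": 0.1395,
}
_DEFAULT_SURGERY_PROBS = {
    "neurosurgery": 0.0628,
    "cardiothoracic": 0.0170,
    "vascular": 0.0071,
    "gastrointestinal": 0.3355,
    "urologic": 0.0232,
    "orthopedic": 0.5220,
    "plastic": 0.0324,
}

# Latent probit coefficients for VTE assignment.  Signs and rough sizes mirror
# the case/control contrasts of the study-population table (older age, female
# sex, vascular surgery and vascular/renal comorbidity strongly enriched among
# cases).  The intercept is calibrated numerically so that the marginal VTE
# prevalence is ~0.002 under the default covariate mix (see
# ``simulate.calibrate_probit_intercept``).
_DEFAULT_PROBIT_COEFS = {
    "intercept": -3.5318,
    "sex[female]": 0.25,
    "age_group[60-69]": 0.50,
    "age_group[70-79]": 0.65,
    "age_group[80+]": 0.80,
    "region[red_river_delta]": -0.10,
    "region[central_coast]": 0.15,
    "region[central_highlands]": 0.00,
    "region[southeast]": 0.30,
    "region[southwest]": 0.20,
    "surgery_type[cardiothoracic]": 0.40,
    "surgery_type[vascular]": 1.30,
    "surgery_type[gastrointestinal]": -0.15,
    "surgery_type[urologic]": 0.35,
    "surgery_type[orthopedic]": -0.10,
    "surgery_type[plastic]": 0.00,
    "cc_heart_failure": 0.60,
    "cc_peripheral_vascular": 1.30,
    "cc_renal_failure": 0.80,
    "cc_diabetes": 0.45,
    "cc_hypertension": 0.45,
    "cc_gastric_ulcer": 0.25,
    "cc_arrhythmia": 0.50,
    "cc_cerebral_circulatory": 0.40,
    "cc_chronic_pulmonary": 0.30,
    "cc_deficiency_anemia": 0.50,
}

# Log-normal cost-component parameters, moment-matched to the printed non-VTE
# means/SDs and interpreted as conditional-on-event amounts (surgery payment is
# always incurred; readmission/outpatient components only when the event
# occurs, otherwise exact zero).
_DEFAULT_COST_LOG_MEANS = {
    "surgery": 5.705,
    "rmpo": 5.805,
    "rmpo_drug": 3.669,
    "ovp": 2.056,
    "ovp_drug": 0.805,
}
_DEFAULT_COST_LOG_SDS = {
    "surgery": 1.055,
    "rmpo": 1.089,
    "rmpo_drug": 1.508,
    "ovp": 1.828,
    "ovp_drug": 2.074,
}

# Logistic coefficients for the two 90-day outcomes; "vte" is the class-level
# exposure effect applied to any VTE episode.
_DEFAULT_OUTCOME_COEFS = {
    "rmpo": {
        "intercept": -2.60,
        "vte": 1.80,
        "age_group[60-69]": 0.20,
        "age_group[70-79]": 0.25,
        "age_group[80+]": 0.10,
        "sex[female]": -0.10,
        "cc_heart_failure": 0.40,
        "cc_cancer": 0.30,
    },
    "ovp": {
        "intercept": -0.35,
        "vte": 0.90,
        "sex[female]": 0.15,
        "region[southeast]": 0.40,
        "age_group[80+]": -0.30,
    },
}

_DEFAULT_LOS = {"mean": 7.0, "vte_effect": 1.9, "shape": 2.0}

_DEFAULT_CLASS_PROBS = {"PE": 0.15, "PTP": 0.45, "VET": 0.30, "DVT_PE": 0.10}


class ParamError(ValueError):
    """A cohort parameter failed validation; the message names the field."""


@dataclass(frozen=True)
class CohortParams:
    """Full specification of one synthetic claims cohort."""

    n_episodes: int = 10_000
    covariate_prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_BINARY_PREV)
    )
    age_group_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_AGE_PROBS)
    )
    region_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_PROBS)
    )
    surgery_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_SURGERY_PROBS)
    )
    vte_probit_coefs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROBIT_COEFS)
    )
    vte_class_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CLASS_PROBS)
    )
    cost_log_means: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COST_LOG_MEANS)
    )
    cost_log_sds: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_COST_LOG_SDS)
    )
    vte_cost_multiplier: float = 2.0
    outcome_logit_coefs: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_OUTCOME_COEFS.items()}
    )
    los_params: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_LOS))
    pregnancy_rate: float = 0.005
    contraindication_rate: float = 0.003
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_episodes <= 0:
            raise ParamError(f"n_episodes must be positive, got {self.n_episodes}")
        for name, p in self.covariate_prevalences.items():
            if name not in _DEFAULT_BINARY_PREV:
                raise ParamError(f"unknown covariate name in covariate_prevalences: {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ParamError(f"covariate_prevalences[{name!r}] = {p} outside [0, 1]")
        for label, probs, levels in (
            ("age_group_probs", self.age_group_probs, AGE_LEVELS),
            ("region_probs", self.region_probs, REGION_LEVELS),
            ("surgery_probs", self.surgery_probs, SURGERY_LEVELS),
        ):
            unknown = set(probs) - set(levels)
            if unknown:
                raise ParamError(f"unknown level(s) in {label}: {sorted(unknown)}")
            if any(not 0.0 <= p <= 1.0 for p in probs.values()):
                raise ParamError(f"{label} has probabilities outside [0, 1]")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-6:
                raise ParamError(f"{label} must sum to 1, got {total:.6f}")
        known_coef_names = self._design_names() | {"intercept", "emergency"}
        for name in self.vte_probit_coefs:
            if name not in known_coef_names:
                raise ParamError(f"unknown covariate name in vte_probit_coefs: {name!r}")
        for outcome, coefs in self.outcome_logit_coefs.items():
            if outcome not in ("rmpo", "ovp"):
                raise ParamError(f"unknown outcome in outcome_logit_coefs: {outcome!r}")
            for name in coefs:
                if name not in known_coef_names | {"vte"}:
                    raise ParamError(
                        f"unknown covariate name in outcome_logit_coefs[{outcome!r}]: {name!r}"
                    )
        for comp in COST_COMPONENTS:
            if comp not in self.cost_log_means:
                raise ParamError(f"cost_log_means missing component {comp!r}")
            if self.cost_log_sds.get(comp, -1.0) <= 0:
                raise ParamError(f"cost_log_sds[{comp!r}] must be > 0")
        if self.vte_cost_multiplier <= 0:
            raise ParamError(f"vte_cost_multiplier must be > 0, got {self.vte_cost_multiplier}")
        if abs(sum(self.vte_class_probs.values()) - 1.0) > 1e-6:
            raise ParamError("vte_class_probs must sum to 1")
        if set(self.vte_class_probs) - set(VTE_CLASSES):
            raise ParamError("unknown VTE class in vte_class_probs")
        if self.los_params.get("mean", -1.0) < 0 or self.los_params.get("shape", -1.0) <= 0:
            raise ParamError("los_params requires mean >= 0 and shape > 0")
        for label, p in (
            ("pregnancy_rate", self.pregnancy_rate),
            ("contraindication_rate", self.contraindication_rate),
        ):
            if not 0.0 <= p <= 1.0:
                raise ParamError(f"{label} = {p} outside [0, 1]")

    @staticmethod
    def _design_names() -> set[str]:
        names = {"sex[female]"}
        names |= {f"age_group[{a}]" for a in AGE_LEVELS[1:]}
        names |= {f"region[{r}]" for r in REGION_LEVELS[1:]}
        names |= {f"surgery_type[{s}]" for s in SURGERY_LEVELS[1:]}
        names |= set(CHRONIC_FLAGS)
        return names

    def replace(self, **changes) -> "CohortParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **changes)

    def null_effects(self) -> "CohortParams":
        """Copy with every VTE effect removed (cost multiplier 1, outcome and
        length-of-stay VTE coefficients 0) — the sharp null for coverage tests."""
        out_coefs = {
            o: {k: (0.0 if k == "vte" else v) for k, v in c.items()}
            for o, c in self.outcome_logit_coefs.items()
        }
        los = dict(self.los_params)
        los["vte_effect"] = 0.0
        return self.replace(
            vte_cost_multiplier=1.0, outcome_logit_coefs=out_coefs, los_params=los
        )
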