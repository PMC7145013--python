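"""Build the analysis cohort from raw surgical-episode records.

Covers eligibility filtering (adults, not pregnant, no anticoagulant
contraindication), ICD-10 classification of postoperative venous
thromboembolism within a 90-day window, 90-day cost aggregation, regional
cost adjustment, and Elixhauser chronic-condition flags.
"""

from __future__ import annotations

import logging
import re
import warnings
from importlib import resources

import numpy as np
import pandas as pd

from .params import CHRONIC_FLAGS, COST_COMPONENTS

__all__ = [
    "COST_COLUMNS",
    "VTE_CLASS_LEVELS",
    "apply_eligibility",
    "parse_diagnoses",
    "classify_vte",
    "classify_cohort",
    "total_90day_cost",
    "adjust_regional_costs",
    "load_elixhauser_map",
    "build_elixhauser_flags",
]

logger = logging.getLogger(__name__)

COST_COLUMNS = tuple(f"cost_{c}" for c in COST_COMPONENTS)
VTE_CLASS_LEVELS = ("NONE", "PE", "PTP", "VET", "DVT_PE")

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]*$")

# ICD-10 code groups (dotless prefixes).  Deep-vein codes are the
# lower-extremity thrombophlebitis codes; their co-occurrence with any
# pulmonary-embolism code within the window defines the DVT+PE class.
PE_PREFIXES = ("I26",)
PTP_PREFIXES = ("I801", "I802", "I803", "I808")
VET_PREFIXES = ("I82",)
DEEP_VEIN_PREFIXES = ("I801", "I802", "I803")

#: precedence when several VTE code groups co-occur (most severe first)
CLASS_PRECEDENCE = ("DVT_PE", "PE", "VET", "PTP")


def apply_eligibility(episodes: pd.DataFrame) -> pd.DataFrame:
    """Retain adult (age >= 18), non-pregnant episodes without anticoagulant
    contraindication; order preserved; logs counts removed per criterion."""
    if len(episodes) == 0:
        return episodes.copy()
    underage = episodes["age"] < 18
    pregnant = episodes["pregnant"].astype(bool)
    contra = episodes["anticoagulant_contraindicated"].astype(bool)
    logger.info(
        "eligibility: removed %d under-18, %d pregnant, %d anticoagulant-contraindicated "
        "(criteria counted independently); %d of %d retained",
        int(underage.sum()),
        int(pregnant.sum()),
        int(contra.sum()),
        int((~(underage | pregnant | contra)).sum()),
        len(episodes),
    )
    return episodes.loc[~(underage | pregnant | contra)].copy()


def _normalize_code(code: str) -> str | None:
    c = str(code).strip().upper().replace(".", "")
    if not _CODE_RE.match(c):
        return None
    return c


def parse_diagnoses(field: str) -> list[tuple[str, int]]:
    """Parse the ``"CODE:day;CODE:day"`` episode-table encoding."""
    if field is None or str(field).strip() in ("", "nan"):
        return []
    out = []
    for item in str(field).split(";"):
        item = item.strip()
        if not item:
            continue
        code, _, day = item.rpartition(":")
        out.append((code, int(day)))
    return out


def classify_vte(
    diagnoses,
    window_days: int = 90,
    deep_vein_prefixes=DEEP_VEIN_PREFIXES,
    precedence=CLASS_PRECEDENCE,
) -> str:
    """Classify an episode's VTE status from (ICD-10 code, day-offset) pairs.

    Only diagnoses with ``0 <= day <= window_days`` count.  Returns one of
    PE (I26.x), PTP (I80.1-I80.3, I80.8), VET (I82.x), DVT_PE (a deep-vein
    code co-occurring with a PE code), or NONE; when several groups co-occur
    the configured precedence applies.  Malformed codes are ignored with a
    warning.
    """
    if isinstance(diagnoses, str):
        diagnoses = parse_diagnoses(diagnoses)
    seen = {"PE": False, "PTP": False, "VET": False, "deep": False}
    for code, day in diagnoses:
        norm = _normalize_code(code)
        if norm is None:
            warnings.warn(f"ignoring malformed ICD-10 code {code!r}", stacklevel=2)
            continue
        if not 0 <= day <= window_days:
            continue
        if norm.startswith(PE_PREFIXES):
            seen["PE"] = True
        if norm.startswith(tuple(PTP_PREFIXES)):
            seen["PTP"] = True
        if norm.startswith(VET_PREFIXES):
            seen["VET"] = True
        if norm.startswith(tuple(deep_vein_prefixes)):
            seen["deep"] = True
    present = {
        "DVT_PE": seen["PE"] and seen["deep"],
        "PE": seen["PE"],
        "VET": seen["VET"],
        "PTP": seen["PTP"],
    }
    for cls in precedence:
        if present[cls]:
            return cls
    return "NONE"


def classify_cohort(episodes: pd.DataFrame, window_days: int = 90) -> pd.DataFrame:
    """Add ``vte_class`` and the 0/1 ``vte`` exposure column."""
    out = episodes.copy()
    out["vte_class"] = [
        classify_vte(d, window_days=window_days) for d in out["diagnoses"]
    ]
    out["vte"] = (out["vte_class"] != "NONE").astype(int)
    return out


def total_90day_cost(e):
    """Sum of the five 90-day cost components (row, dict or DataFrame)."""
    if isinstance(e, pd.DataFrame):
        comp = e[list(COST_COLUMNS)]
        if (comp.to_numpy() < 0).any():
            raise ValueError("cost components must be non-negative")
        return comp.sum(axis=1)
    vals = [float(e[c]) for c in COST_COLUMNS]
    if any(v < 0 for v in vals):
        raise ValueError("cost components must be non-negative")
    return float(sum(vals))


def adjust_regional_costs(episodes: pd.DataFrame, wage_index: dict) -> pd.DataFrame:
    """Deflate each cost component by its provider region's wage index."""
    missing = sorted(set(episodes["region"].astype(str)) - set(wage_index))
    if missing:
        raise KeyError(f"wage_index missing region(s): {missing}")
    out = episodes.copy()
    idx = episodes["region"].astype(str).map(wage_index).astype(float)
    if (idx <= 0).any():
        raise ValueError("wage index values must be positive")
    for col in COST_COLUMNS:
        out[col] = out[col] / idx
    return out


def load_elixhauser_map() -> dict[str, tuple[str, ...]]:
    """Chronic-condition flag -> ICD-10 prefixes, from the packaged table.

    The shipped table follows the standard Quan et al. ICD-10 coding of the
    Elixhauser conditions, with condition names matched to the 30 flags this
    analysis uses; it is a plain CSV and can be edited or replaced.
    """
    text = resources.files("vteburden").joinpath("data/elixhauser_icd10.csv").read_text()
    mapping: dict[str, tuple[str, ...]] = {}
    for line in text.strip().splitlines()[1:]:
        flag, codes = line.split(",", 1)
        mapping[flag.strip()] = tuple(codes.strip().split())
    return mapping


def build_elixhauser_flags(diagnoses, code_map: dict | None = None) -> dict[str, bool]:
    """Set the 30 chronic-condition flags from an ICD-10 diagnosis list.

    Unknown codes set no flag; duplicate codes are idempotent.
    """
    if code_map is None:
        code_map = load_elixhauser_map()
    if isinstance(diagnoses, str):
        diagnoses = parse_diagnoses(diagnoses)
    codes = []
    for item in diagnoses:
        code = item[0] if isinstance(item, (tuple, list)) else item
        norm = _normalize_code(code)
        if norm is not None:
            codes.append(norm)
    flags = {}
    for flag in CHRONIC_FLAGS:
        prefixes = tuple(code_map.get(flag, ()))
        flags[flag] = bool(prefixes) and any(c.startswith(prefixes) for c in codes)
    return flags
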