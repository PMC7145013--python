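import numpy as np
import pandas as pd
import pytest

import vteburden as vb
from vteburden.cohort import apply_eligibility, classify_cohort
from vteburden.matching import (
    build_matched_frame,
    estimate_propensity,
    match_nearest_neighbor,
)
from vteburden.simulate import calibrate_probit_intercept


@pytest.fixture(scope="session")
def powered_params():
    """Default generator conditions with the probit intercept recalibrated to a
    2% VTE prevalence (power for matched-sample estimation tests)."""
    base = vb.CohortParams()
    coefs = dict(base.vte_probit_coefs)
    coefs["intercept"] = calibrate_probit_intercept(base, 0.02)
    return base.replace(vte_probit_coefs=coefs)


@pytest.fixture(scope="session")
def small_cohort(powered_params):
    """Classified eligible cohort of 8,000 episodes (~160 VTE cases)."""
    params = powered_params.replace(n_episodes=8_000, seed=42)
    cohort = vb.generate_cohort(params)
    return classify_cohort(apply_eligibility(cohort.episodes)), params


@pytest.fixture(scope="session")
def matched_frame(small_cohort):
    cohort, _ = small_cohort
    prop = estimate_propensity(cohort)
    matched = match_nearest_neighbor(
        prop.scores,
        cohort.loc[cohort["vte"] == 1, "episode_id"].to_numpy(),
        cohort.loc[cohort["vte"] == 0, "episode_id"].to_numpy(),
    )
    return build_matched_frame(cohort, matched)


def make_two_arm_frame(n1, k1, n0, k0, seed=0):
    """Minimal matched-style frame: n1 exposed (k1 events), n0 unexposed (k0)."""
    rows = []
    for i in range(n1):
        rows.append({"vte": 1, "vte_class": "PE", "y": int(i < k1)})
    for i in range(n0):
        rows.append({"vte": 0, "vte_class": "NONE", "y": int(i < k0)})
    df = pd.DataFrame(rows)
    df["episode_id"] = np.arange(len(df))
    df["pair_id"] = np.arange(len(df)) % max(n1, n0)
    df["is_case"] = df["vte"]
    return df
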