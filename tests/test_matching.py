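"""Propensity estimation, greedy nearest-neighbor matching, balance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vteburden as vb
from vteburden.matching import (
    balance_table,
    build_matched_frame,
    estimate_propensity,
    match_nearest_neighbor,
)
from vteburden.params import CHRONIC_FLAGS


def scores_series(cases, controls):
    ids = list(range(len(cases))) + [100 + i for i in range(len(controls))]
    return (
        pd.Series(list(cases) + list(controls), index=ids),
        ids[: len(cases)],
        ids[len(cases):],
    )


class TestNearestNeighbor:
    def test_picks_nearest(self):
        s, case_ids, control_ids = scores_series([0.5], [0.40, 0.55])
        m = match_nearest_neighbor(s, case_ids, control_ids)
        assert list(m.pairs["control_id"]) == [101]  # score 0.55

    def test_without_replacement_greedy(self):
        s, case_ids, control_ids = scores_series([0.9, 0.3], [0.89, 0.31, 0.50])
        m = match_nearest_neighbor(s, case_ids, control_ids)
        got = dict(zip(m.pairs["case_id"], m.pairs["control_id"]))
        assert got == {0: 100, 1: 101}  # 0.9->0.89, 0.3->0.31

    def test_tie_goes_to_lowest_id(self):
        s, case_ids, control_ids = scores_series([0.5], [0.45, 0.55])
        m = match_nearest_neighbor(s, case_ids, control_ids)
        assert list(m.pairs["control_id"]) == [100]

    def test_no_controls_warns_all_unmatched(self):
        s, case_ids, _ = scores_series([0.5, 0.2], [])
        with pytest.warns(UserWarning, match="no controls"):
            m = match_nearest_neighbor(s, case_ids, [])
        assert len(m.pairs) == 0 and len(m.unmatched_cases) == 2

    def test_caliper_excludes_far_cases(self):
        s, case_ids, control_ids = scores_series([0.5, 0.9], [0.52, 0.1])
        m = match_nearest_neighbor(s, case_ids, control_ids, caliper=0.05)
        assert list(m.pairs["case_id"]) == [0]
        assert m.unmatched_cases == [1]

    @staticmethod
    def optimal_total(case_scores, control_scores):
        """Brute-force minimal total |score difference| over all 1:1 assignments."""
        k = min(len(case_scores), len(control_scores))
        best = np.inf
        for sub in itertools.combinations(range(len(case_scores)), k):
            for perm in itertools.permutations(range(len(control_scores)), k):
                tot = sum(abs(case_scores[i] - control_scores[j]) for i, j in zip(sub, perm))
                best = min(best, tot)
        return best

    @given(
        case_scores=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=6),
        control_scores=st.lists(st.floats(0.01, 0.99), min_size=1, max_size=8),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_no_control_reuse_and_greedy_vs_optimal(self, case_scores, control_scores):
        s, case_ids, control_ids = scores_series(case_scores, control_scores)
        m = match_nearest_neighbor(s, case_ids, control_ids)
        # without replacement: controls are used at most once
        assert not m.pairs["control_id"].duplicated().any()
        assert len(m.pairs) == min(len(case_scores), len(control_scores))
        # brute-force optimal assignment lower-bounds the greedy total distance
        best = self.optimal_total(case_scores, control_scores)
        assert m.pairs["distance"].sum() >= best - 1e-9

    def test_greedy_equals_optimal_on_separated_fixture(self):
        # clusters far apart: greedy and optimal assignments coincide
        s, case_ids, control_ids = scores_series(
            [0.1, 0.5, 0.9], [0.12, 0.52, 0.88, 0.3]
        )
        m = match_nearest_neighbor(s, case_ids, control_ids)
        got = dict(zip(m.pairs["case_id"], m.pairs["control_id"]))
        assert got == {0: 100, 1: 101, 2: 102}
        assert np.isclose(m.pairs["distance"].sum(), 0.02 + 0.02 + 0.02)


class TestPropensity:
    def test_intercept_only_scores_equal_prevalence(self):
        n = 40
        df = pd.DataFrame(
            {
                "episode_id": range(n),
                "vte": [1] * 10 + [0] * 30,
                "sex": ["male"] * n,
                "age_group": ["18-59"] * n,
                "region": ["north"] * n,
                "surgery_type": ["neurosurgery"] * n,
                **{f: [0] * n for f in CHRONIC_FLAGS},
            }
        )
        prop = estimate_propensity(df)
        assert np.allclose(prop.scores.to_numpy(), 0.25, atol=1e-6)

    def test_scores_strictly_inside_unit_interval(self, small_cohort):
        cohort, _ = small_cohort
        prop = estimate_propensity(cohort)
        s = prop.scores.to_numpy()
        assert (s > 0).all() and (s < 1).all()
        assert len(s) == len(cohort)

    def test_coefficient_recovery_against_simulation_truth(self, powered_params):
        """Probit coefficient estimates fall within 3 reported SEs of the
        generating values for >= 90% of coefficients across seeds."""
        from vteburden.cohort import apply_eligibility, classify_cohort

        hits = total = 0
        for seed in range(6):
            p = powered_params.replace(n_episodes=50_000, seed=300 + seed)
            cohort = classify_cohort(apply_eligibility(vb.generate_cohort(p).episodes))
            prop = estimate_propensity(cohort)
            se = prop.model.bse
            for name, est in prop.model.params.items():
                if name == "intercept":
                    continue
                truth = p.vte_probit_coefs.get(name, 0.0)
                total += 1
                hits += abs(est - truth) <= 3 * se[name]
        assert hits / total >= 0.90

    def test_matching_improves_chronic_flag_balance(self, small_cohort, matched_frame):
        cohort, _ = small_cohort
        raw = cohort.copy()
        raw["is_case"] = raw["vte"]
        raw["pair_id"] = 0
        raw_bal = balance_table(raw, CHRONIC_FLAGS)
        matched_bal = balance_table(matched_frame, CHRONIC_FLAGS)
        assert matched_bal["smd"].abs().mean() < raw_bal["smd"].abs().mean()


class TestBalance:
    def test_self_match_gives_zero_smd(self, matched_frame):
        both = pd.concat(
            [matched_frame.assign(is_case=1), matched_frame.assign(is_case=0)],
            ignore_index=True,
        )
        bal = balance_table(both, ["age_group", "sex", *CHRONIC_FLAGS])
        assert np.allclose(bal["smd"], 0.0)

    def test_four_pair_fixture_matches_hand_arithmetic(self):
        df = pd.DataFrame(
            {
                "is_case": [1, 1, 1, 1, 0, 0, 0, 0],
                "x": [1, 1, 0, 0, 1, 0, 0, 0],
            }
        )
        bal = balance_table(df, ["x"])
        # p1=0.5, p0=0.25; s1^2=1/3, s0^2=0.25 -> smd=(0.25)/sqrt((1/3+1/4)/2)
        hand = 0.25 / np.sqrt((1 / 3 + 1 / 4) / 2)
        assert np.isclose(bal.loc["x", "smd"], hand)
        assert bal.loc["x", "case_pct"] == 50.0 and bal.loc["x", "control_pct"] == 25.0

    def test_zero_variance_reports_zero(self):
        df = pd.DataFrame({"is_case": [1, 0, 1, 0], "x": [1, 1, 1, 1]})
        bal = balance_table(df, ["x"])
        assert bal.loc["x", "smd"] == 0.0

    def test_printed_matched_female_share(self):
        # 828 women among the 1,612 matched controls -> 51.36%
        from vteburden.reporting import rate_pct

        assert rate_pct(828, 1612) == 51.36
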