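"""Smearing retransformation, recycled-prediction excess estimates, curves."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_two_arm_frame
from vteburden.effects import (
    cumulative_cost_curve,
    excess_cost,
    excess_event_rate,
    excess_hospital_days,
    excess_table,
    fit_smearing_model,
    outcome_odds_ratios,
    smearing_factor,
)


class TestSmearing:
    def test_zero_residuals_give_one(self):
        assert smearing_factor(np.zeros(10)) == 1.0

    def test_symmetric_log_residuals(self):
        assert np.isclose(smearing_factor([np.log(2), -np.log(2)]), 1.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            smearing_factor([])

    def test_at_least_one_with_intercept(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        cost = np.exp(rng.normal(4.0, 1.0, size=200))
        model = fit_smearing_model(X, cost)
        assert model.smearing >= 1.0  # Jensen on mean-zero residuals

    def test_positive_costs_required(self):
        with pytest.raises(ValueError, match="two-part"):
            fit_smearing_model(np.ones((3, 1)), np.array([1.0, 0.0, 2.0]))


class TestExcessEventRate:
    def test_equal_rates_give_zero_ame(self):
        df = make_two_arm_frame(n1=20, k1=10, n0=20, k0=10)
        ame, _ = excess_event_rate(df.rename(columns={"y": "rmpo"}), "rmpo", "ALL",
                                   terms=(), n_boot=0)
        assert abs(ame) < 1e-8

    def test_covariate_free_closed_form(self):
        # p(exposed)=0.8, p(unexposed)=0.5 -> AME 0.3
        df = make_two_arm_frame(n1=10, k1=8, n0=10, k0=5)
        ame, _ = excess_event_rate(df.rename(columns={"y": "rmpo"}), "rmpo", "ALL",
                                   terms=(), n_boot=0)
        assert np.isclose(ame, 0.3, atol=1e-6)

    def test_class_specific_toggle(self):
        df = make_two_arm_frame(n1=10, k1=8, n0=10, k0=5)
        ame, _ = excess_event_rate(df.rename(columns={"y": "rmpo"}), "rmpo", "PE",
                                   terms=(), n_boot=0)
        assert np.isclose(ame, 0.3, atol=1e-6)

    def test_missing_class_errors(self):
        df = make_two_arm_frame(n1=10, k1=8, n0=10, k0=5)
        with pytest.raises(ValueError, match="VET"):
            excess_event_rate(df.rename(columns={"y": "rmpo"}), "rmpo", "VET",
                              terms=(), n_boot=0)

    def test_bootstrap_se_positive(self):
        df = make_two_arm_frame(n1=30, k1=20, n0=30, k0=10)
        _, se = excess_event_rate(df.rename(columns={"y": "rmpo"}), "rmpo", "ALL",
                                  terms=(), n_boot=50, seed=1)
        assert se > 0


class TestExcessCost:
    def _cost_frame(self):
        df = make_two_arm_frame(n1=12, k1=12, n0=12, k0=12)
        df["cost_total"] = np.where(df["vte"] == 1, 200.0, 100.0)
        return df

    def test_saturated_doubling_gives_exact_difference(self):
        # beta0 = ln 100, exposure coefficient ln 2, zero residuals, phi = 1
        df = self._cost_frame()
        d, _ = excess_cost(df, "cost_total", "ALL", terms=(), n_boot=0)
        assert np.isclose(d, 100.0, atol=1e-6)

    def test_no_effect_gives_zero(self):
        df = self._cost_frame()
        df["cost_total"] = 100.0
        d, _ = excess_cost(df, "cost_total", "ALL", terms=(), n_boot=0)
        assert abs(d) < 1e-8

    def test_constant_covariate_leaves_excess_invariant(self):
        df = self._cost_frame()
        df["emergency"] = 1
        d0, _ = excess_cost(df, "cost_total", "ALL", terms=(), n_boot=0)
        d1, _ = excess_cost(df, "cost_total", "ALL", terms=("emergency",), n_boot=0)
        assert np.isclose(d0, d1, atol=1e-9)

    def test_two_part_component_with_zeros(self):
        # exposed: all incur 200; unexposed: half incur 100 -> excess = 200 - 50
        df = make_two_arm_frame(n1=20, k1=20, n0=20, k0=10)
        df["cost_rmpo"] = np.where(
            df["vte"] == 1, 200.0, np.where(df["y"] == 1, 100.0, 0.0)
        )
        d, _ = excess_cost(df, "cost_rmpo", "ALL", terms=(), n_boot=0)
        assert np.isclose(d, 150.0, atol=1e-4)

    def test_negative_cost_rejected(self):
        df = self._cost_frame()
        df["cost_total"] = -1.0
        with pytest.raises(ValueError):
            excess_cost(df, "cost_total", "ALL", terms=(), n_boot=0)


class TestExcessHospitalDays:
    def test_additive_effect_recovered_exactly(self):
        df = make_two_arm_frame(n1=15, k1=0, n0=15, k0=0)
        df["hospital_days"] = np.where(df["vte"] == 1, 9.5, 7.0)
        d, _ = excess_hospital_days(df, "ALL", terms=(), n_boot=0)
        assert np.isclose(d, 2.5, atol=1e-10)

    def test_null_effect_zero(self):
        df = make_two_arm_frame(n1=15, k1=0, n0=15, k0=0)
        df["hospital_days"] = 7.0
        d, _ = excess_hospital_days(df, "ALL", terms=(), n_boot=0)
        assert abs(d) < 1e-10


class TestOddsRatios:
    def test_cross_product_fixture(self):
        # exposed events 40/100, unexposed 10/100 -> OR (40*90)/(60*10) = 6
        df = make_two_arm_frame(n1=100, k1=40, n0=100, k0=10)
        tab = outcome_odds_ratios(df.rename(columns={"y": "rmpo"}), "rmpo", terms=())
        assert np.isclose(tab.loc["vte_class[PE]", "or"], 6.0, atol=1e-6)

    def test_significance_flag(self):
        df = make_two_arm_frame(n1=100, k1=40, n0=100, k0=10)
        tab = outcome_odds_ratios(df.rename(columns={"y": "rmpo"}), "rmpo", terms=())
        assert bool(tab.loc["vte_class[PE]", "significant"])


class TestExcessTable:
    def test_shapes_and_se_nonnegative(self, matched_frame):
        tab = excess_table(matched_frame, n_boot=20, seed=5)
        assert "ALL" in tab.index
        assert {"excess_rmpo_rate", "excess_total_cost", "excess_hospital_days"} <= set(tab.columns)
        ses = tab[[c for c in tab.columns if c.endswith("_se")]].to_numpy(float)
        assert np.nanmin(ses) >= 0


class TestCumulativeCurve:
    def _frame(self, n_pairs=5):
        df = make_two_arm_frame(n1=n_pairs, k1=0, n0=n_pairs, k0=0)
        for c in ("cost_surgery", "cost_rmpo", "cost_rmpo_drug", "cost_ovp", "cost_ovp_drug"):
            df[c] = 0.0
        df["rmpo_day"] = -1
        df["ovp_day"] = -1
        return df

    def test_zero_costs_flat_zero(self):
        curve = cumulative_cost_curve(self._frame())
        assert (curve[["vte", "control"]].to_numpy() == 0).all()
        assert len(curve) == 91

    def test_single_event_step_function(self):
        df = self._frame(n_pairs=5)
        df.loc[df.index[df["is_case"] == 1][0], ["cost_rmpo", "rmpo_day"]] = [100.0, 10]
        curve = cumulative_cost_curve(df)
        assert (curve.loc[curve["day"] < 10, "vte"] == 0).all()
        assert np.allclose(curve.loc[curve["day"] >= 10, "vte"], 100.0 / 5)
        assert (curve["control"] == 0).all()

    def test_monotone_and_final_gap_equals_mean_total_difference(self, matched_frame):
        curve = cumulative_cost_curve(matched_frame)
        assert (np.diff(curve["vte"]) >= -1e-9).all()
        assert (np.diff(curve["control"]) >= -1e-9).all()
        from vteburden.cohort import total_90day_cost

        tot = total_90day_cost(matched_frame)
        gap = (
            tot[matched_frame["is_case"] == 1].mean()
            - tot[matched_frame["is_case"] == 0].mean()
        )
        assert np.isclose(curve["vte"].iloc[-1] - curve["control"].iloc[-1], gap, atol=1e-9)

    def test_out_of_window_events_excluded_with_warning(self):
        df = self._frame()
        df.loc[df.index[0], ["cost_rmpo", "rmpo_day"]] = [50.0, 95]
        with pytest.warns(UserWarning, match="outside"):
            curve = cumulative_cost_curve(df)
        assert curve["vte"].iloc[-1] == 0.0
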