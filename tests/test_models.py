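import numpy as np
import pandas as pd
import pytest

from dayspace.config import EffectTruth, ModelSpec
from dayspace.models import (
    assemble_panel,
    fit_interaction_model,
    fit_main_model,
    fit_null_icc,
    inverse_transform_outcome,
    modifier_levels,
    person_mean_center,
    predicted_trajectories,
    simple_slopes,
    transform_outcome,
)
from dayspace.synthetic import simulate_panel

EXPOSURE_ONLY = ModelSpec(covariates=())


def centered_panel(n=40, days=8, truth=None, seed=1):
    truth = truth or EffectTruth(within_park_effect=1.0, within_walkability_effect=1.0)
    panel = simulate_panel(n, days, truth, seed)
    panel["log_mvpa"] = transform_outcome(panel["mvpa_minutes"])
    return person_mean_center(panel, ["green_pct", "park_distance_m", "walkability", "parks_any"])


class TestTransform:
    def test_values_and_round_trip(self):
        assert transform_outcome(0.0) == 0.0
        assert transform_outcome(np.e - 1) == pytest.approx(1.0)
        y = np.array([0.0, 3.7, 120.0])
        np.testing.assert_allclose(inverse_transform_outcome(transform_outcome(y)), y,
                                   atol=1e-12)

    def test_negative_minutes_rejected(self):
        with pytest.raises(ValueError):
            transform_outcome(-0.5)


class TestPersonMeanCenter:
    def test_two_person_arithmetic(self):
        panel = pd.DataFrame(
            {"participant_id": ["a"] * 2 + ["b"] * 2, "x": [9.0, 11.0, 19.0, 21.0]}
        )
        out = person_mean_center(panel, ["x"])
        np.testing.assert_allclose(out["x_bs"], [-5, -5, 5, 5])
        np.testing.assert_allclose(out["x_ws"], [-1, 1, -1, 1])

    def test_constant_person_has_zero_ws(self):
        panel = pd.DataFrame({"participant_id": ["a"] * 3, "x": [4.0, 4.0, 4.0],
                              "participant_id2": 0})
        panel["participant_id"] = "a"
        out = person_mean_center(panel, ["x"])
        assert (out["x_ws"] == 0).all()

    def test_ws_sums_to_zero_within_person(self):
        panel = centered_panel()
        for var in ("green_pct", "walkability", "park_distance_m"):
            sums = panel.groupby("participant_id")[f"{var}_ws"].sum()
            np.testing.assert_allclose(sums, 0.0, atol=1e-9)

    def test_binary_ws_is_raw_indicator(self):
        panel = centered_panel()
        assert set(panel["parks_any_ws"].unique()) <= {0, 1}
        np.testing.assert_array_equal(panel["parks_any_ws"], panel["parks_any"])

    def test_decomposition_reconstructs_exactly(self):
        panel = centered_panel()
        grand = panel.groupby("participant_id")["walkability"].mean().mean()
        recon = panel["walkability_bs"] + panel["walkability_ws"] + grand
        np.testing.assert_allclose(recon, panel["walkability"], atol=1e-9)

    def test_missing_variable_rejected(self):
        with pytest.raises(KeyError):
            person_mean_center(pd.DataFrame({"participant_id": ["a"]}), ["nope"])


class TestAssemblePanel:
    @staticmethod
    def tables():
        key = {"participant_id": ["P0", "P0", "P1"], "wave": ["T1"] * 3,
               "date": ["2017-01-09", "2017-01-10", "2017-01-09"]}
        expo = pd.DataFrame({**key, "day_type": ["weekday"] * 3, "method": "kde",
                             "green_pct": [20.0, 25.0, 30.0], "park_distance_m": 500.0,
                             "parks_any": [1, 0, 1], "walkability": 15.0})
        act = pd.DataFrame({**key, "day_type": ["weekday"] * 3,
                            "mvpa_minutes": [30.0, 40.0, 20.0],
                            "wear_hours": [12.0, 9.0, 13.0], "valid": [True, False, True]})
        roster = pd.DataFrame({"participant_id": ["P0", "P1"], "age": [28.0, 31.0],
                               "bmi_category": ["normal", "obese"]})
        return expo, act, roster

    def test_invalid_accel_day_excluded(self):
        expo, act, roster = self.tables()
        panel = assemble_panel(expo, act, roster)
        assert len(panel) == 2  # the 9-h wear day drops
        assert set(panel["mvpa_minutes"]) == {30.0, 20.0}
        assert "log_mvpa" in panel and "wave_T3" in panel and "bmi_obese" in panel

    def test_day_without_exposure_excluded(self):
        expo, act, roster = self.tables()
        panel = assemble_panel(expo.iloc[:1], act, roster)
        assert len(panel) == 1

    def test_duplicate_keys_rejected(self):
        expo, act, roster = self.tables()
        with pytest.raises(ValueError):
            assemble_panel(pd.concat([expo, expo]), act, roster)


class TestNullIcc:
    def test_matches_balanced_anova_oracle(self, rng):
        # balanced two-level data: REML equals the classic ANOVA estimators
        n_g, n_per = 30, 6
        b = rng.normal(0, 0.7, n_g)
        y = (b[:, None] + rng.normal(0, 0.5, (n_g, n_per))).ravel()
        panel = pd.DataFrame({"participant_id": np.repeat(np.arange(n_g), n_per),
                              "log_mvpa": y})
        vc = fit_null_icc(panel)
        groups = y.reshape(n_g, n_per)
        msw = groups.var(axis=1, ddof=1).mean()
        msb = n_per * groups.mean(axis=1).var(ddof=1)
        sigma_b = (msb - msw) / n_per
        assert vc.within_var == pytest.approx(msw, rel=1e-3)
        assert vc.between_var == pytest.approx(sigma_b, rel=1e-3)
        assert 0 <= vc.icc <= 1

    def test_zero_between_variance_gives_small_icc(self, rng):
        panel = pd.DataFrame({"participant_id": np.repeat(np.arange(100), 10),
                              "log_mvpa": rng.normal(3.0, 0.6, 1000)})
        assert fit_null_icc(panel).icc <= 0.05

    def test_insufficient_grouping_rejected(self):
        panel = pd.DataFrame({"participant_id": ["a", "b"], "log_mvpa": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_null_icc(panel)


class TestMainModel:
    def test_affine_invariance_of_slopes(self):
        panel = centered_panel()
        r1 = fit_main_model(panel, EXPOSURE_ONLY)
        shifted = panel.copy()
        shifted["green_pct_bs"] = shifted["green_pct_bs"] + 10.0
        r2 = fit_main_model(shifted, EXPOSURE_ONLY)
        keep = [t for t in r1.terms.index if t != "const"]
        np.testing.assert_allclose(r1.terms.loc[keep, "estimate_log"],
                                   r2.terms.loc[keep, "estimate_log"], atol=1e-5)

    def test_ci_brackets_estimate_exponentiated_after(self):
        r = fit_main_model(centered_panel(), EXPOSURE_ONLY)
        t = r.terms
        assert ((t["ci_low"] <= t["estimate_exp"]) & (t["estimate_exp"] <= t["ci_high"])).all()
        np.testing.assert_allclose(t["estimate_exp"], np.exp(t["estimate_log"]), rtol=1e-12)

    def test_row_order_invariance(self):
        panel = centered_panel()
        shuffled = panel.sample(frac=1.0, random_state=3).reset_index(drop=True)
        r1 = fit_main_model(panel, EXPOSURE_ONLY)
        r2 = fit_main_model(shuffled, EXPOSURE_ONLY)
        np.testing.assert_allclose(r1.terms["estimate_log"], r2.terms["estimate_log"],
                                   atol=1e-6)

    def test_rank_deficient_design_names_columns(self):
        panel = centered_panel()
        panel["dup"] = panel["walkability_ws"]
        spec = ModelSpec(covariates=("dup",))
        with pytest.raises(ValueError, match="dup|walkability_ws"):
            fit_main_model(panel, spec)


class TestInteractions:
    @staticmethod
    def panel_with_modifier(seed=2, n=40):
        panel = centered_panel(n=n, seed=seed)
        rng = np.random.default_rng(seed + 100)
        mod = pd.Series(rng.integers(0, 2, panel["participant_id"].nunique()),
                        index=sorted(panel["participant_id"].unique()))
        panel["mod"] = panel["participant_id"].map(mod).astype(float)
        return panel

    def test_binary_modifier_main_effect_is_reference_slope(self):
        panel = self.panel_with_modifier()
        r = fit_interaction_model(panel, "parks_any_ws", "mod", EXPOSURE_ONLY)
        slopes = simple_slopes(r, "parks_any_ws", "mod", {"ref": 0.0, "other": 1.0})
        assert slopes.loc[slopes.level == "ref", "slope_log"].iloc[0] == pytest.approx(
            r.terms.loc["parks_any_ws", "estimate_log"]
        )

    def test_centering_modifier_preserves_interaction_coefficient(self):
        panel = self.panel_with_modifier()
        r1 = fit_interaction_model(panel, "parks_any_ws", "mod", EXPOSURE_ONLY)
        panel2 = panel.copy()
        panel2["mod"] = panel2["mod"] - panel2["mod"].mean()
        r2 = fit_interaction_model(panel2, "parks_any_ws", "mod", EXPOSURE_ONLY)
        assert r1.terms.loc["parks_any_ws:mod", "estimate_log"] == pytest.approx(
            r2.terms.loc["parks_any_ws:mod", "estimate_log"], abs=1e-4
        )

    def test_constant_modifier_rejected(self):
        panel = centered_panel()
        panel["mod"] = 1.0
        with pytest.raises(ValueError):
            fit_interaction_model(panel, "parks_any_ws", "mod", EXPOSURE_ONLY)

    def test_stratum_specific_effects_detected(self):
        # two strata with true multiplicative park effects 1.0 vs 1.45
        rng = np.random.default_rng(5)
        detected = 0
        for rep in range(10):
            a = simulate_panel(28, 8, EffectTruth(within_park_effect=1.0), [6, rep])
            b = simulate_panel(28, 8, EffectTruth(within_park_effect=1.45), [7, rep])
            b["participant_id"] = "B" + b["participant_id"]
            panel = pd.concat([a.assign(mod=0.0), b.assign(mod=1.0)], ignore_index=True)
            panel["log_mvpa"] = transform_outcome(panel["mvpa_minutes"])
            panel = person_mean_center(
                panel, ["green_pct", "park_distance_m", "walkability", "parks_any"]
            )
            r = fit_interaction_model(panel, "parks_any_ws", "mod", EXPOSURE_ONLY)
            if r.terms.loc["parks_any_ws:mod", "p"] < 0.05:
                detected += 1
        assert detected >= 6  # majority of replicates


class TestSimpleSlopes:
    @staticmethod
    def fitted():
        panel = centered_panel(seed=9)
        rng = np.random.default_rng(11)
        cont = pd.Series(rng.normal(3.0, 0.7, panel["participant_id"].nunique()),
                         index=sorted(panel["participant_id"].unique()))
        panel["mod"] = panel["participant_id"].map(cont)
        return panel, fit_interaction_model(panel, "walkability_ws", "mod", EXPOSURE_ONLY)

    def test_slope_at_zero_equals_main_effect(self):
        _, r = self.fitted()
        s = simple_slopes(r, "walkability_ws", "mod", {"zero": 0.0})
        assert s["slope_log"].iloc[0] == pytest.approx(
            r.terms.loc["walkability_ws", "estimate_log"]
        )
        assert s["se"].iloc[0] == pytest.approx(r.terms.loc["walkability_ws", "se"])

    def test_delta_method_matches_reparameterized_refit(self):
        panel, r = self.fitted()
        levels = modifier_levels(panel, "mod")
        s = simple_slopes(r, "walkability_ws", "mod", levels)
        # oracle: shift the modifier so that each level becomes zero and refit
        for _, row in s.iterrows():
            shifted = panel.copy()
            shifted["mod"] = shifted["mod"] - row.modifier_value
            r2 = fit_interaction_model(shifted, "walkability_ws", "mod", EXPOSURE_ONLY)
            assert row.slope_log == pytest.approx(
                r2.terms.loc["walkability_ws", "estimate_log"], abs=5e-4
            )
            assert row.se == pytest.approx(r2.terms.loc["walkability_ws", "se"], abs=5e-4)

    def test_symmetric_levels_symmetric_about_mean(self):
        panel, r = self.fitted()
        m, sd = panel["mod"].mean(), panel["mod"].std()
        s = simple_slopes(r, "walkability_ws", "mod",
                          {"-1SD": m - sd, "mean": m, "+1SD": m + sd})
        lo, mid, hi = s["slope_log"]
        assert (hi - mid) == pytest.approx(mid - lo, abs=1e-10)


class TestPredictedTrajectories:
    def test_flat_model_constant_and_nonnegative(self):
        panel = centered_panel()
        r = fit_main_model(panel, EXPOSURE_ONLY)
        flat = r.terms.copy()
        flat.loc[flat.index != "const", "estimate_log"] = 0.0
        r.terms = flat
        out = predicted_trajectories(r, "walkability_ws", np.linspace(-2, 2, 5))
        assert out["pred_mvpa_minutes"].nunique() == 1
        assert (out["pred_mvpa_minutes"] >= 0).all()
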