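import datetime as dt

import numpy as np
import pandas as pd
import pytest

from dayspace.accelerometry import process_accel_day
from dayspace.config import EffectTruth, SyntheticConfig
from dayspace.gps import gps_day_valid
from dayspace.synthetic import (
    day_exposure_truth,
    generate_accel_day,
    generate_environment,
    generate_gps_day,
    generate_participant_roster,
    generate_study,
    simulate_panel,
    study_dates,
)


class TestEnvironment:
    def test_deterministic_under_fixed_seed(self, small_config, small_env):
        env2 = generate_environment(small_config)
        np.testing.assert_array_equal(
            small_env.walkability_layer.values, env2.walkability_layer.values
        )
        np.testing.assert_array_equal(
            np.nan_to_num(small_env.greenspace_layer.values, nan=-1),
            np.nan_to_num(env2.greenspace_layer.values, nan=-1),
        )

    def test_walkability_scores_within_index_range(self, small_env):
        vals = small_env.walkability_layer.values
        defined = vals[~np.isnan(vals)]
        assert defined.min() >= 1 and defined.max() <= 20

    def test_greenspace_percentages_and_distances_in_range(self, small_env):
        g = small_env.greenspace_layer.values
        assert np.nanmin(g) >= 0 and np.nanmax(g) <= 100
        assert np.nanmin(small_env.park_distance_layer.values) >= 0

    def test_entrances_on_park_boundaries(self, small_env):
        for park, ent in zip(small_env.park_polygons, small_env.park_entrances):
            assert park.boundary.distance(ent) < 1e-6

    def test_zero_parks_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_parks=0)

    def test_region_too_small_rejected(self):
        with pytest.raises(ValueError):
            generate_environment(SyntheticConfig(region_extent=200.0, cell_size=50.0))


class TestRoster:
    def test_reproducible_and_eligibility(self, small_config, small_roster):
        again = generate_participant_roster(small_config)
        pd.testing.assert_frame_equal(small_roster, again)
        assert (small_roster["age"] >= 18).all()
        assert small_roster["deprivation_index"].between(1, 10).all()
        assert small_roster["cohesion_safety"].between(1, 5).all()

    def test_row_count_matches_config(self):
        roster = generate_participant_roster(SyntheticConfig(n_participants=55, seed=3))
        assert len(roster) == 55

    def test_large_sample_age_moments(self):
        # oracle: closed-form moments of Normal(29.0, 6.1) truncated at 18
        from scipy import stats

        dist = stats.truncnorm((18 - 29.0) / 6.1, np.inf, loc=29.0, scale=6.1)
        roster = generate_participant_roster(
            SyntheticConfig(n_participants=10_000, seed=12)
        )
        assert roster["age"].mean() == pytest.approx(dist.mean(), abs=0.2)
        assert roster["age"].std() == pytest.approx(dist.std(), abs=0.2)

    def test_homes_on_street_lattice(self, small_config, small_roster):
        b = small_config.block_size
        on_lattice = (
            (small_roster["home_x"] % b == 0) | (small_roster["home_y"] % b == 0)
        )
        assert on_lattice.all()


class TestGpsDay:
    def test_epochs_in_region_and_spacing(self, small_config, small_env, small_roster):
        cfg = small_config
        track = generate_gps_day(small_roster.iloc[0], "T1", dt.date(2017, 1, 9),
                                 small_env, cfg, [1, 2, 3])
        ext = cfg.region_extent
        assert np.all((track.x >= 0) & (track.x <= ext))
        assert np.all((track.y >= 0) & (track.y <= ext))
        assert np.all(np.diff(track.t) % 10 == 0)

    def test_missing_seed_rejected(self, small_config, small_env, small_roster):
        with pytest.raises(ValueError):
            generate_gps_day(small_roster.iloc[0], "T1", dt.date(2017, 1, 9),
                             small_env, small_config, None)

    def test_heavy_deletion_fails_validity(self, small_config, small_env, small_roster):
        import dataclasses

        cfg = dataclasses.replace(small_config, gps_lowcov_frac=1.0)
        track = generate_gps_day(small_roster.iloc[1], "T1", dt.date(2017, 1, 10),
                                 small_env, cfg, [4, 5, 6])
        valid, hours = gps_day_valid(track)
        assert not valid and hours < 6

    def test_park_visit_day_enters_park(self, small_config, small_env, small_roster):
        import dataclasses

        import shapely
        from shapely.ops import unary_union

        cfg = dataclasses.replace(small_config, park_visit_prob=1.0, gps_jitter_sd=0.0,
                                  gps_lowcov_frac=0.0)
        track = generate_gps_day(small_roster.iloc[2], "T3", dt.date(2017, 5, 8),
                                 small_env, cfg, [9, 9, 9])
        parks = unary_union(small_env.park_polygons)
        inside = shapely.intersects_xy(parks, track.x, track.y)
        assert inside.any()


class TestAccelDay:
    @staticmethod
    def gps_day(small_config, small_env, small_roster, seed=(1, 2, 3)):
        import dataclasses

        cfg = dataclasses.replace(small_config, gps_lowcov_frac=0.0)
        return cfg, generate_gps_day(small_roster.iloc[0], "T1", dt.date(2017, 1, 9),
                                     small_env, cfg, list(seed))

    def test_noise_free_limit_recovers_baseline(self, small_config, small_env, small_roster):
        cfg, track = self.gps_day(small_config, small_env, small_roster)
        truth = EffectTruth(within_park_effect=1.0, within_walkability_effect=1.0,
                            within_sd=1e-9, between_sd=0.5, mean_log_mvpa=3.4)
        _, mvpa = generate_accel_day(track, truth, 0.0, [5, 5], parks_any=False,
                                     walkability=15.0, walkability_ref=15.0, config=cfg)
        assert mvpa == pytest.approx(np.exp(3.4), abs=1 / 6 + 1e-9)

    def test_inserted_zero_block_detected_as_nonwear(self, small_config, small_env,
                                                     small_roster):
        from dayspace.accelerometry import detect_nonwear

        cfg, track = self.gps_day(small_config, small_env, small_roster)
        series, _ = generate_accel_day(track, cfg.truth, 0.0, [6, 6], parks_any=False,
                                       walkability=15.0, walkability_ref=15.0, config=cfg,
                                       insert_nonwear=True)
        assert not detect_nonwear(series).all()

    def test_low_wear_day_fails_wear_rule(self, small_config, small_env, small_roster):
        cfg, track = self.gps_day(small_config, small_env, small_roster)
        series, _ = generate_accel_day(track, cfg.truth, 0.0, [7, 7], parks_any=False,
                                       walkability=15.0, walkability_ref=15.0, config=cfg,
                                       low_wear=True)
        assert not process_accel_day(series).valid

    def test_window_matches_gps_day(self, small_config, small_env, small_roster):
        cfg, track = self.gps_day(small_config, small_env, small_roster)
        series, _ = generate_accel_day(track, cfg.truth, 0.0, [8, 8], parks_any=False,
                                       walkability=15.0, walkability_ref=15.0, config=cfg)
        assert series.t[0] == 8 * 3600
        assert len(series) == int(cfg.waking_hours * 360)


class TestGenerateStudy:
    @pytest.fixture(scope="class")
    @staticmethod
    def study(tmp_path_factory):
        cfg = SyntheticConfig(n_participants=3, days_per_wave=2, region_extent=2000.0,
                              block_size=200.0, tract_size=500.0, n_parks=2, seed=21)
        return cfg, generate_study(cfg, tmp_path_factory.mktemp("study") / "s")

    def test_person_day_arithmetic(self, study):
        cfg, ds = study
        assert len(ds.truth) == 3 * 3 * 2 == cfg.n_days
        assert len(list((ds.out_dir / "gps").glob("*.csv"))) == cfg.n_days

    def test_truth_roundtrip_on_clean_days(self, study):
        from dayspace.accelerometry import read_accel_csv

        cfg, ds = study
        clean = ds.truth[~ds.truth["accel_low_wear"] & ~ds.truth["accel_nonwear_inserted"]]
        assert len(clean) > 0
        for _, row in clean.iterrows():
            stem = f"{row.participant_id}_{row.wave}_{row.date}"
            rec = process_accel_day(read_accel_csv(ds.out_dir / "accel" / f"{stem}.csv"))
            assert rec.mvpa_minutes == pytest.approx(row.mvpa_minutes_truth, abs=1 / 6)

    def test_same_seed_byte_identical_tree(self, study, tmp_path):
        import filecmp

        cfg, ds = study
        ds2 = generate_study(cfg, tmp_path / "s2")
        for rel in ["roster.csv", "truth.csv", "temperature.csv", "env/walkability.asc"]:
            assert filecmp.cmp(ds.out_dir / rel, ds2.out_dir / rel, shallow=False), rel
        for sub in ["gps", "accel"]:
            names = sorted(p.name for p in (ds.out_dir / sub).iterdir())
            assert names == sorted(p.name for p in (ds2.out_dir / sub).iterdir())
            for n in names:
                assert filecmp.cmp(ds.out_dir / sub / n, ds2.out_dir / sub / n,
                                   shallow=False), n

    def test_non_empty_output_dir_rejected(self, study):
        cfg, ds = study
        with pytest.raises(FileExistsError):
            generate_study(cfg, ds.out_dir)

    def test_temperature_written_per_date(self, study):
        cfg, ds = study
        dates = {d for ds_ in study_dates(cfg).values() for d in ds_}
        assert len(ds.temperature) == len(dates)


class TestSimulatePanel:
    def test_park_effect_geometric_mean_ratio(self):
        # brute-force oracle on the generated truth labels: with a 1.25
        # multiplicative park effect, the geometric-mean MVPA ratio between
        # park and non-park days approaches 1.25
        truth = EffectTruth(within_park_effect=1.25, within_walkability_effect=1.0,
                            between_sd=0.0, within_sd=0.3)
        panel = simulate_panel(100, 5, truth, seed=31)  # 500 simulated days
        logm = np.log(panel["mvpa_minutes"])
        ratio = np.exp(logm[panel["parks_any"] == 1].mean()
                       - logm[panel["parks_any"] == 0].mean())
        se = 0.3 * np.sqrt(1 / (panel.parks_any == 1).sum() + 1 / (panel.parks_any == 0).sum())
        assert abs(np.log(ratio) - np.log(1.25)) < 3 * se

    def test_temperature_and_exposure_moments(self):
        truth = EffectTruth()
        panel = simulate_panel(400, 8, truth, seed=32)
        assert panel["walkability"].between(1, 20).all()
        assert panel["green_pct"].between(0, 100).all()
        assert panel["parks_any"].mean() == pytest.approx(0.70, abs=0.05)
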