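import json

import numpy as np
import pytest

from mwmaze import (
    MEASURES,
    PoolGeometry,
    build_feature_table,
    compute_zone_features,
    heading_series,
    make_annuli,
    make_quadrants,
    segment_visits,
    simulate_cohort,
    write_feature_table,
)
from mwmaze.features import ConfigMismatch, feature_columns
from mwmaze.synthetic import default_cohort_spec

from conftest import make_traj
from oracles import oracle_zone_features


class TestVisits:
    def test_two_crossings(self, geom, quadrants):
        # in zone 1 (x>0, y<0), out, back in, out again
        pts = np.array(
            [[0.3, -0.3], [0.3, -0.2], [-0.3, -0.2], [0.4, -0.4], [-0.4, -0.4]]
        )
        visits = segment_visits(make_traj(pts), quadrants, 1)
        assert len(visits) == 2
        assert all(not v.censored for v in visits)

    def test_ending_inside_censors_last_exit(self, geom, quadrants):
        pts = np.array([[-0.3, 0.3], [0.3, -0.3], [0.35, -0.35]])
        visits = segment_visits(make_traj(pts), quadrants, 1)
        assert len(visits) == 1
        assert visits[0].censored

    def test_random_walks_match_run_oracle(self, geom, quadrants, random_walk_trials):
        from oracles import quadrant_index

        for traj in random_walk_trials[:100]:
            for z in range(1, 5):
                visits = segment_visits(traj, quadrants, z)
                mask = [
                    quadrant_index(p, geom.platform_center_m) == z
                    for p in traj.points_m
                ]
                runs = sum(
                    1
                    for i, m in enumerate(mask)
                    if m and (i == 0 or not mask[i - 1])
                )
                exits = sum(
                    1
                    for i, m in enumerate(mask)
                    if m and i + 1 < len(mask) and not mask[i + 1]
                )
                assert len(visits) == runs
                assert sum(not v.censored for v in visits) == exits


class TestHeadings:
    def test_cardinal_conventions(self):
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [0.1, 0.1]])
        h, valid = heading_series(make_traj(pts))
        assert valid.all()
        assert h[0] == pytest.approx(0.0)    # east
        assert h[1] == pytest.approx(90.0)   # north

    def test_full_circle_turn_sums_to_360(self, geom, annuli):
        # 361 steps of 1 degree each -> 360 turn increments of 1 degree
        th = np.deg2rad(np.arange(362))
        c = np.asarray(geom.platform_center_m)
        pts = c + 0.05 * np.stack([np.cos(th), np.sin(th)], axis=1)
        f = compute_zone_features(make_traj(pts), geom, annuli, 1)
        assert f["absolute_turn_angle"] == pytest.approx(360.0, abs=1e-6)

    def test_motionless_segment_has_no_headings(self):
        pts = np.vstack([np.tile([0.1, 0.1], (10, 1)), [[0.2, 0.1]]])
        _, valid = heading_series(make_traj(pts))
        assert valid.sum() == 1


class TestZoneFeatures:
    def test_oracle_equivalence_spot_check(self, geom, quadrants, annuli, random_walk_trials):
        traj = random_walk_trials[0]
        for part in (quadrants, annuli):
            for z in (1, part.n_zones):
                ours = compute_zone_features(traj, geom, part, z)
                ref = oracle_zone_features(traj, geom, part, z)
                for k in MEASURES:
                    assert ours[k] == pytest.approx(ref[k], rel=1e-9, abs=1e-9), k

    def test_never_visited_zone_censoring(self, geom, quadrants):
        # path confined to zone 1 (x>0, y<0)
        pts = np.linspace([0.1, -0.5], [0.5, -0.1], 80)
        traj = make_traj(pts)
        duration = traj.duration_s
        f3 = compute_zone_features(traj, geom, quadrants, 3)
        assert f3["n_entries"] == 0.0
        assert f3["total_time_in_zone"] == 0.0
        assert f3["latency_first_entry"] == pytest.approx(duration)
        assert f3["latency_first_exit"] == pytest.approx(duration)
        assert f3["distance_until_first_entry"] == pytest.approx(traj.path_length_m())
        # distance stats fall back to all samples -> finite, positive
        assert f3["avg_distance_to_center"] > 0
        assert np.isfinite(f3["max_distance_to_border"])

    def test_conservation_over_zones(self, geom, quadrants, annuli, random_walk_trials):
        for traj in random_walk_trials[:20]:
            frame = 1.0 / traj.frame_rate_hz
            for part in (quadrants, annuli):
                feats = [
                    compute_zone_features(traj, geom, part, z)
                    for z in range(1, part.n_zones + 1)
                ]
                t_sum = sum(f["total_time_in_zone"] for f in feats)
                assert t_sum == pytest.approx(traj.duration_s, abs=frame + 1e-9)
                d_sum = sum(f["distance_in_zone"] for f in feats)
                assert d_sum == pytest.approx(traj.path_length_m(), abs=1e-9)
                for f in feats:
                    assert f["n_entries"] - f["n_exits"] in (0.0, 1.0)
                    if f["total_time_in_zone"] > 0:
                        assert f["avg_speed"] * f["total_time_in_zone"] == pytest.approx(
                            f["distance_in_zone"], rel=0.2, abs=0.05
                        )


class TestFeatureTable:
    @pytest.fixture(scope="class")
    def cohort(self):
        return simulate_cohort(default_cohort_spec(4, 4), seed=11)

    def test_occupancy_preset_has_eight_columns(self, cohort):
        table = build_feature_table(
            cohort.trials,
            cohort.geom,
            partitions={"quadrant": make_quadrants(cohort.geom)},
            measure_subset=("n_entries", "total_time_in_zone"),
        )
        assert len(feature_columns(table)) == 8

    def test_combined_preset_column_count(self, cohort):
        table = build_feature_table(cohort.trials, cohort.geom)
        K = make_annuli(cohort.geom, 1.0).n_zones
        assert len(feature_columns(table)) == 32 * (4 + K)

    def test_column_order_deterministic(self, cohort):
        t1 = build_feature_table(cohort.trials[:3], cohort.geom)
        t2 = build_feature_table(cohort.trials[:3], cohort.geom)
        assert list(t1.columns) == list(t2.columns)

    def test_empty_measure_subset_rejected(self, cohort):
        with pytest.raises(ValueError):
            build_feature_table(cohort.trials, cohort.geom, measure_subset=())

    def test_frame_rate_mismatch_rejected(self, cohort):
        bad_geom = PoolGeometry(frame_rate_hz=30.0)
        with pytest.raises(ConfigMismatch):
            build_feature_table(cohort.trials[:1], bad_geom)

    def test_no_missing_cells(self, cohort):
        table = build_feature_table(cohort.trials, cohort.geom)
        assert not table[feature_columns(table)].isna().any().any()

    def test_csv_and_sidecar(self, cohort, tmp_path):
        table = build_feature_table(
            cohort.trials[:2],
            cohort.geom,
            partitions={"quadrant": make_quadrants(cohort.geom)},
        )
        csv = tmp_path / "features.csv"
        write_feature_table(table, csv)
        meta = json.loads((tmp_path / "features.csv.meta.json").read_text())
        assert len(meta) == 128
        sample = meta["quadrant_z1_avg_speed"]
        assert sample["unit"] == "m/s" and sample["zone"] == 1

    def test_cohort_contrast_direction(self):
        # young escape faster and swim faster, as reported for aged cohorts
        cohort = simulate_cohort(default_cohort_spec(6, 6), seed=5)
        lab = cohort.labels()
        lab["esc"] = lab["escape_time_s"].fillna(60.0)
        esc = lab.groupby("label")["esc"].mean()
        assert esc["young"] < esc["old"]
        speeds = {"young": [], "old": []}
        for t in cohort.trials:
            speeds[t.label].append(
                t.trajectory.path_length_m() / t.trajectory.duration_s
            )
        assert np.mean(speeds["young"]) > np.mean(speeds["old"])
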