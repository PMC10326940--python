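"""Behaviour-class crossing, segment building, glide ratio, airspeed, filters."""

import numpy as np
import pandas as pd
import pytest

from soarharness.gps_kinematics import GpsTrack
from soarharness.segmentation import (
    airspeed_from_wind,
    build_segments,
    combine_classes,
    filter_glide_validity,
    filter_high_speed,
    glide_ratio,
)

EAST = np.pi / 2


def labelled_track(behaviour_runs, vert_rate=None, speed=10.0, vedba=0.1):
    """Build a classified 1 Hz track from (activity, movement, length) runs."""
    activity, movement = [], []
    for act, mov, length in behaviour_runs:
        activity += [act] * length
        movement += [mov] * length
    n = len(activity)
    rate = np.full(n, -1.0 if vert_rate is None else vert_rate)
    rate[np.array(movement) == "soaring"] = 1.0
    height = 500 + np.concatenate([[0.0], np.cumsum(rate)[:-1]])
    step = speed  # metres per second east
    lon = 1.6 + np.degrees(np.arange(n) * step / (6_371_000 * np.cos(np.radians(44.8))))
    df = pd.DataFrame({
        "time": pd.date_range("2018-06-25T10:00:00", periods=n, freq="s", tz="UTC"),
        "lon": lon, "lat": 44.8, "height": height,
        "step_length": np.append(np.full(n - 1, step), np.nan),
        "horiz_speed": np.append(np.full(n - 1, step), np.nan),
        "vert_speed": np.append(rate[:-1], np.nan),
        "activity": activity, "movement": movement,
        "vedba": vedba,
    })
    return GpsTrack(df, 1.0, {"session_id": "s1", "individual_id": "ind01",
                              "species": "griffon_vulture", "harness": "backpack",
                              "date": "2018-06-25"})


class TestCombineClasses:
    def test_four_way_cross(self):
        track = labelled_track([("passive", "soaring", 3), ("active", "gliding", 3)])
        out = combine_classes(track).data
        assert out["behaviour"].iloc[0] == "passive_soaring"
        assert out["behaviour"].iloc[-1] == "active_gliding"

    def test_missing_label_excluded(self):
        track = labelled_track([("passive", "soaring", 4)])
        track.data.loc[1, "activity"] = pd.NA
        out = combine_classes(track).data
        assert pd.isna(out["behaviour"].iloc[1])
        assert out["behaviour"].notna().sum() == 3


class TestBuildSegments:
    def test_short_runs_dropped(self):
        track = combine_classes(labelled_track(
            [("passive", "soaring", 7), ("passive", "gliding", 3), ("passive", "soaring", 9)]
        ))
        segments = build_segments(track)
        assert len(segments) == 2
        assert segments["n_fixes"].tolist() == [7, 9]
        assert (segments["behaviour"] == "passive_soaring").all()

    def test_homogeneous_track_single_segment(self):
        track = combine_classes(labelled_track([("passive", "soaring", 100)]))
        segments = build_segments(track)
        assert len(segments) == 1
        assert segments["n_fixes"].iloc[0] == 100

    def test_boundaries_match_run_length_encoding_oracle(self):
        rng = np.random.default_rng(17)
        runs = [("passive" if rng.random() < 0.7 else "active",
                 "soaring" if rng.random() < 0.5 else "gliding",
                 int(rng.integers(1, 12))) for _ in range(30)]
        track = combine_classes(labelled_track(runs))
        segments = build_segments(track, min_fixes=5)

        # independent run-length encoder over the behaviour sequence
        beh = track.data["behaviour"].tolist()
        oracle = []
        start = 0
        for i in range(1, len(beh) + 1):
            if i == len(beh) or beh[i] != beh[start]:
                if i - start >= 5 and not pd.isna(beh[start]):
                    oracle.append((start, i - start, beh[start]))
                start = i
        assert len(segments) == len(oracle)
        for (_, row), (start, length, label) in zip(segments.iterrows(), oracle):
            assert row["n_fixes"] == length
            assert row["behaviour"] == label
            assert row["start"] == track.data["time"].iloc[start]

    def test_fix_count_partition_invariant(self):
        rng = np.random.default_rng(23)
        runs = [("passive", "soaring" if rng.random() < 0.5 else "gliding",
                 int(rng.integers(1, 10))) for _ in range(40)]
        track = combine_classes(labelled_track(runs))
        segments = build_segments(track, min_fixes=5)
        beh = track.data["behaviour"]
        classified = int(beh.notna().sum())
        key = beh.fillna("-")
        run_lengths = key.groupby((key != key.shift()).cumsum()).size()
        run_labels = key.groupby((key != key.shift()).cumsum()).first()
        dropped = int(run_lengths[(run_lengths < 5) & (run_labels != "-")].sum())
        assert segments["n_fixes"].sum() + dropped == classified

    def test_hour_centred_from_centroid(self):
        track = combine_classes(labelled_track([("passive", "soaring", 61)]))
        segments = build_segments(track)
        # centroid at 10:00:30 UTC -> hour_centred = 10 + 30/3600 - 12
        assert segments["hour_centred"].iloc[0] == pytest.approx(10 + 30 / 3600 - 12, abs=1e-6)


class TestGlideRatio:
    def test_simple_division_and_guard(self):
        assert glide_ratio(150.0, 10.0) == pytest.approx(15.0)
        assert np.isnan(glide_ratio(150.0, 0.0))
        assert np.isnan(glide_ratio(150.0, -5.0))

    def test_commanded_rates_reproduced_exactly(self):
        # noise-free glide at 12 m/s horizontal, -1.5 m/s vertical
        track = combine_classes(labelled_track(
            [("passive", "gliding", 40)], vert_rate=-1.5, speed=12.0
        ))
        segments = build_segments(track)
        assert segments["glide_ratio"].iloc[0] == pytest.approx(12.0 / 1.5, rel=1e-9)

    def test_time_dilation_invariance(self):
        # doubling both distances leaves the ratio unchanged
        a = glide_ratio(240.0, 30.0)
        b = glide_ratio(480.0, 60.0)
        assert a == b

    def test_soaring_segment_has_no_glide_ratio(self):
        track = combine_classes(labelled_track([("passive", "soaring", 10)]))
        assert np.isnan(build_segments(track)["glide_ratio"].iloc[0])


class TestAirspeed:
    def test_no_wind_equals_ground_speed(self):
        assert airspeed_from_wind(10.0, EAST, 0.0, 0.0) == pytest.approx(10.0)

    def test_pure_tailwind_subtracts(self):
        assert airspeed_from_wind(10.0, EAST, 2.0, 0.0) == pytest.approx(8.0)

    def test_pure_crosswind_vector_oracle(self):
        assert airspeed_from_wind(10.0, EAST, 0.0, 3.0) == pytest.approx(np.sqrt(109))

    def test_undefined_bearing_gives_nan(self):
        assert np.isnan(airspeed_from_wind(10.0, float("nan"), 2.0, 0.0))

    def test_matches_vector_subtraction_on_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            vg = rng.uniform(1, 20)
            brg = rng.uniform(0, 2 * np.pi)
            u, v = rng.normal(0, 5, 2)
            ground = np.array([vg * np.sin(brg), vg * np.cos(brg)])
            oracle = np.linalg.norm(ground - np.array([u, v]))
            assert airspeed_from_wind(vg, brg, u, v) == pytest.approx(oracle, abs=1e-9)


class TestFilters:
    def _seg(self, speeds):
        return pd.DataFrame({"mean_horiz_speed": speeds,
                             "behaviour": "passive_gliding",
                             "mean_vert_speed": -1.0})

    def test_speed_split_keeps_high_speed_only(self):
        # observed extremes of the bimodal speed distribution
        kept = filter_high_speed(self._seg([0.35, 3.28, 4.59, 11.4]))
        assert kept["mean_horiz_speed"].tolist() == [4.59, 11.4]

    def test_empty_and_zero_threshold(self):
        assert len(filter_high_speed(self._seg([]))) == 0
        kept = filter_high_speed(self._seg([0.35, 3.28]), threshold=0.0)
        assert len(kept) == 2

    def test_glide_validity_threshold(self):
        segments = pd.DataFrame({
            "behaviour": ["passive_gliding", "passive_gliding", "passive_gliding"],
            "mean_vert_speed": [-0.1, -0.2, -1.5],
            "glide_ratio": [300.0, 80.0, 12.0],
        })
        kept, n_excluded = filter_glide_validity(segments)
        assert kept["glide_ratio"].tolist() == [12.0]
        assert n_excluded == 2
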