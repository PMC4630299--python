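"""Difference filter, feature detection, track linking, motion reports."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from mitoflow import (Calibration, DTParams, Movie, detect_features,
                      difference_filter, link_tracks, track_statistics,
                      treatment_ratio_report)
from mitoflow.tracker import REPORT_FIELDS, Feature, MotionReport, tracks_to_frame

CAL = Calibration(0.432, 3.5)

# Printed combined-output columns for the worked control/nocodazole pair.
CONTROL_COLUMN = pd.Series(
    [2334480, 6213, 0.28, 45767, 142, 0.32, 411, 22, 5.17, 4.5, 1.03, 2.2],
    index=REPORT_FIELDS, dtype=float)
NOCODAZOLE_COLUMN = pd.Series(
    [2551856, 2796, 0.12, 48047, 73, 0.16, 240, 13, 5.21, 4.1, 0.85, 1.9],
    index=REPORT_FIELDS, dtype=float)


def movie8(data):
    return Movie(np.asarray(data, dtype=np.uint8), CAL)


class TestDifferenceFilter:
    def test_static_movie_no_moving_output(self):
        frame = (np.random.default_rng(0).random((32, 32)) * 200).astype(np.uint8)
        moving, stats = difference_filter(movie8(np.stack([frame] * 8)))
        assert stats.moving_intensity == 0
        assert stats.moving_count == 0
        np.testing.assert_array_equal(moving.data, 0)

    def test_moving_block_detected_with_offset_pairing(self):
        data = np.zeros((10, 24, 24), dtype=np.uint8)
        for t in range(10):
            data[t, 10:13, 2 + 2 * t:5 + 2 * t] = 200
        moving, stats = difference_filter(movie8(data))
        assert stats.moving_intensity > 0
        # the block is fully displaced after 4 frames, so its pixels move
        assert moving.data[5, 11, 12 + 0] > 0 or moving.data[5].sum() > 0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        data = (rng.random((10, 32, 32)) * 255).astype(np.uint8)
        m = movie8(data)
        prev = np.inf
        for min_diff in (10, 40, 120):
            _, stats = difference_filter(m, DTParams(min_difference=min_diff))
            assert stats.moving_intensity <= prev
            prev = stats.moving_intensity

    def test_speed_floor_arithmetic(self):
        # 1 effective pixel per 4-frame offset window of stretched frames
        cal = Calibration(0.108, 3.5, bin_factor=4, time_stretch=2)
        floor = cal.effective_pixel_um / (4 * cal.effective_interval_s)
        assert floor == pytest.approx(0.06, abs=0.005)

    def test_subthreshold_speed_invisible(self):
        # mover displacing 0.2 px per offset window stays below min_difference
        y, x = np.mgrid[:32, :32]
        data = np.zeros((12, 32, 32))
        for t in range(12):
            cx = 16 + 0.05 * t
            data[t] = 40 * np.exp(-((x - cx) ** 2 + (y - 16) ** 2) / (2 * 1.5**2))
        _, stats = difference_filter(movie8(np.rint(data)))
        assert stats.moving_count == 0

    def test_requires_8bit(self):
        with pytest.raises(ValueError, match="8-bit"):
            difference_filter(Movie(np.zeros((6, 8, 8)), CAL))


class TestDetectFeatures:
    def test_empty_frame(self):
        assert detect_features(np.zeros((16, 16))) == []

    def test_single_block_centroid_and_area(self):
        frame = np.zeros((16, 16))
        frame[4:7, 8:11] = 30.0
        feats = detect_features(frame, 3)
        assert len(feats) == 1
        f = feats[0]
        assert (f.area, f.frame) == (9, 3)
        assert (f.x, f.y) == (9.0, 5.0)
        assert f.total_intensity == 270.0

    def test_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(2)
        frame = np.zeros((48, 48))
        for _ in range(12):
            r, c = rng.integers(0, 44, 2)
            frame[r:r + rng.integers(1, 4), c:c + rng.integers(1, 4)] = 25.0
        feats = detect_features(frame)
        labels, n = ndimage.label(frame > 0, structure=np.ones((3, 3)))
        expected = 0
        for lab in range(1, n + 1):
            mask = labels == lab
            if mask.sum() >= 2 and frame[mask].sum() >= 20:
                expected += 1
        assert len(feats) == expected

    def test_filters_small_and_faint(self):
        frame = np.zeros((16, 16))
        frame[2, 2] = 100.0  # area 1 < min_feature_size
        frame[8:10, 8:10] = 4.0  # total 16 < min_tracked_intensity
        assert detect_features(frame) == []


def make_features(paths):
    """paths: list of per-mover [(frame, x, y), ...] -> per-frame features."""
    n_frames = max(f for path in paths for f, _, _ in path) + 1
    per_frame = [[] for _ in range(n_frames)]
    for path in paths:
        for f, x, y in path:
            per_frame[f].append(Feature(frame=f, x=x, y=y, area=4,
                                        total_intensity=100.0))
    return per_frame


class TestLinkTracks:
    def test_empty_stream(self):
        assert link_tracks([[], [], []]) == []

    def test_single_constant_velocity_mover(self):
        path = [(t, 5.0 + 1.5 * t, 10.0) for t in range(12)]
        tracks = link_tracks(make_features([path]))
        assert len(tracks) == 1
        tr = tracks[0]
        assert tr.duration == 12
        assert tr.mean_speed_umps(CAL) == pytest.approx(CAL.pf_to_umps(1.5), rel=1e-6)

    def test_short_tracks_discarded(self):
        path = [(t, 5.0 + t, 5.0) for t in range(3)]  # below min_track_length
        assert link_tracks(make_features([path])) == []

    def test_track_terminates_on_gap(self):
        path = [(t, 5.0 + t, 5.0) for t in range(5)] + \
               [(t, 5.0 + t, 5.0) for t in range(7, 12)]
        tracks = link_tracks(make_features([path]))
        durations = sorted(tr.duration for tr in tracks)
        assert durations == [5, 5]
        for tr in tracks:
            frames = [f.frame for f in tr.features]
            assert frames == list(range(frames[0], frames[0] + len(frames)))

    def test_feature_exclusivity(self):
        paths = [[(t, 10.0 + 1.2 * t, 10.0) for t in range(8)],
                 [(t, 10.0 + 1.2 * t, 16.0) for t in range(8)]]
        tracks = link_tracks(make_features(paths))
        seen = set()
        for tr in tracks:
            for f in tr.features:
                key = (f.frame, f.x, f.y)
                assert key not in seen
                seen.add(key)

    @pytest.mark.parametrize("n_movers", [2, 3])
    def test_matches_brute_force_assignment_oracle(self, n_movers):
        rng = np.random.default_rng(n_movers)
        paths = []
        for i in range(n_movers):
            x0, y0 = 8.0 + 20 * i, 10.0 + 7 * i
            vx, vy = 1.0 + 0.3 * i, 0.4 * (i - 1)
            paths.append([(t, x0 + vx * t, y0 + vy * t) for t in range(9)])
        per_frame = make_features(paths)
        tracks = link_tracks(per_frame)
        oracle = brute_force_tracks(per_frame, DTParams())
        got = sorted(tuple((f.frame, f.x, f.y) for f in tr.features)
                     for tr in tracks)
        want = sorted(tuple(path) for path in oracle)
        assert got == want


def brute_force_tracks(per_frame, params):
    """Exhaustive per-frame assignment: enumerate all feature-to-track
    assignments each frame and keep the one minimizing total prediction
    error, subject to the same search radii; tracks below min_track_length
    are dropped."""
    tracks = []  # list of [(frame, x, y), ...], active flag parallel
    active = []

    def prediction(path):
        if len(path) == 1:
            return np.array(path[0][1:]), params.initial_flexibility
        (f1, x1, y1), (f2, x2, y2) = path[-2], path[-1]
        return np.array([2 * x2 - x1, 2 * y2 - y1]), params.subsequent_flexibility

    for feats in per_frame:
        pts = [np.array([f.x, f.y]) for f in feats]
        best = None
        k = len(active)
        for perm in itertools.permutations(range(len(pts) + k), k):
            # track i takes feature perm[i] if perm[i] < len(pts) else nothing
            used = [p for p in perm if p < len(pts)]
            if len(set(used)) != len(used):
                continue
            cost, feasible = 0.0, True
            for ti, p in enumerate(perm):
                if p >= len(pts):
                    cost += 100.0  # missing a feature is expensive
                    continue
                pred, radius = prediction(active[ti])
                d = np.linalg.norm(pts[p] - pred)
                if d > radius:
                    feasible = False
                    break
                cost += d
            if feasible and (best is None or cost < best[0]):
                best = (cost, perm)
        new_active = []
        claimed = set()
        if best is not None:
            for ti, p in enumerate(best[1]):
                if p < len(pts):
                    active[ti].append((feats[p].frame, feats[p].x, feats[p].y))
                    new_active.append(active[ti])
                    claimed.add(p)
                else:
                    tracks.append(active[ti])
        else:
            tracks.extend(active)
        for p, f in enumerate(feats):
            if p not in claimed:
                new_active.append([(f.frame, f.x, f.y)])
        active = new_active
    tracks.extend(active)
    return [t for t in tracks if len(t) >= params.min_track_length]


class TestMotionReport:
    def test_single_track_duration(self):
        path = [(t, 2.0 + t, 2.0) for t in range(5)]
        per_frame = make_features([path])
        tracks = link_tracks(per_frame)
        from mitoflow.tracker import DifferenceStats
        rep = track_statistics(tracks, per_frame, DifferenceStats(), CAL)
        assert rep.average_track_duration == 5
        assert rep.total_track_count == 1

    def test_zero_tracks_report(self):
        from mitoflow.tracker import DifferenceStats
        rep = track_statistics([], [[]], DifferenceStats(), CAL)
        assert rep.total_track_count == 0
        assert np.isnan(rep.average_speed_per_track)

    def test_tracks_to_frame_columns(self):
        path = [(t, 2.0 + t, 2.0) for t in range(5)]
        tracks = link_tracks(make_features([path]))
        df = tracks_to_frame(tracks)
        assert list(df.columns) == ["track_id", "frame", "x", "y", "area", "intensity"]
        assert len(df) == 5


def test_track_overlay_colors_by_direction(tmp_path):
    from mitoflow.tracker import render_track_overlay

    right = [(t, 5.0 + 2 * t, 10.0) for t in range(5)]
    left = [(t, 25.0 - 2 * t, 20.0) for t in range(5)]
    per_frame = make_features([right, left])
    tracks = link_tracks(per_frame)
    movie = Movie(np.zeros((5, 32, 32)), CAL)
    rgb = render_track_overlay(movie, tracks, tmp_path / "overlay.png")
    assert rgb.shape == (32, 32, 3)
    assert tuple(rgb[10, 9]) == (255, 255, 0)  # rightward: yellow
    assert tuple(rgb[20, 21]) == (0, 128, 255)  # leftward: blue
    assert (tmp_path / "overlay.png").exists()


class TestTreatmentRatios:
    def test_identical_reports_all_ones(self):
        table = treatment_ratio_report(CONTROL_COLUMN, CONTROL_COLUMN)
        np.testing.assert_allclose(table["Treated/Control"], 1.0)

    def test_printed_table_ratios(self):
        table = treatment_ratio_report(CONTROL_COLUMN, NOCODAZOLE_COLUMN)
        r = table["Treated/Control"]
        assert r["Moving Intensity"] == pytest.approx(0.45, abs=0.005)
        assert r["Moving Count"] == pytest.approx(0.51, abs=0.005)
        assert r["Total Track Count"] == pytest.approx(0.58, abs=0.005)
        assert r["Static Intensity"] == pytest.approx(1.09, abs=0.005)
        assert r["Count Percentage Moving"] == pytest.approx(0.50, abs=0.005)

    def test_zero_denominator_missing_with_warning(self):
        zero = CONTROL_COLUMN.copy()
        zero["Moving Count"] = 0.0
        with pytest.warns(UserWarning, match="zero control"):
            table = treatment_ratio_report(zero, NOCODAZOLE_COLUMN)
        assert np.isnan(table.loc["Moving Count", "Treated/Control"])

    def test_report_round_trip(self):
        rep = MotionReport.from_series(CONTROL_COLUMN)
        np.testing.assert_allclose(rep.to_series().to_numpy(),
                                   CONTROL_COLUMN.to_numpy())
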