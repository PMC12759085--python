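"""Elongation/migration decomposition, gap handling and direction
histograms."""

import numpy as np
import pytest

from morphlineage import (
    CellTrack,
    Trajectory,
    compute_elongation_trajectory,
    compute_migration_trajectory,
    decompose_tracks,
    fit_circle_radius,
    movement_directions,
    resample_gaps,
    simulate_explant_tracks,
    TrackSimSpec,
)


def track(tid, positions, times=None, role="deep"):
    positions = np.asarray(positions, dtype=float)
    if times is None:
        times = np.arange(len(positions))
    return CellTrack(tid, times, positions, role=role)


class TestElongationTrajectory:
    def test_static_anchors_give_constant_et(self):
        anchors = [
            track(f"A{i}", [[i, 0, 0]] * 5, role="anchor") for i in range(3)
        ]
        et = compute_elongation_trajectory(anchors)
        assert np.ptp(et.positions, axis=0).max() == 0.0

    def test_translating_anchors_centroid_velocity(self):
        anchors = [
            track(f"A{i}", [[i + t, 0, 0] for t in range(4)], role="anchor")
            for i in range(3)
        ]
        et = compute_elongation_trajectory(anchors)
        np.testing.assert_allclose(np.diff(et.positions, axis=0), [[1, 0, 0]] * 3)

    def test_hand_centroid(self):
        anchors = [
            track("A0", [[0, 0, 0], [0, 0, 0]], role="anchor"),
            track("A1", [[2, 0, 0], [2, 0, 0]], role="anchor"),
            track("A2", [[1, 3, 0], [1, 3, 0]], role="anchor"),
        ]
        et = compute_elongation_trajectory(anchors)
        np.testing.assert_allclose(et.positions[0], [1, 1, 0])

    def test_fewer_than_three_anchors_raises(self):
        anchors = [track(f"A{i}", [[0, 0, 0]] * 3, role="anchor") for i in range(2)]
        with pytest.raises(ValueError, match="3 anchors"):
            compute_elongation_trajectory(anchors)

    def test_no_common_support_raises(self):
        a = track("A0", [[0, 0, 0]] * 2, times=[0, 1], role="anchor")
        b = track("A1", [[0, 0, 0]] * 2, times=[2, 3], role="anchor")
        c = track("A2", [[0, 0, 0]] * 2, times=[0, 1], role="anchor")
        with pytest.raises(ValueError, match="common"):
            compute_elongation_trajectory([a, b, c])


class TestMigrationTrajectory:
    def test_cell_moving_with_tissue_has_constant_mt(self):
        et = Trajectory(np.arange(5), np.outer(np.arange(5), [2.0, 0, 1.0]))
        ot = track("c", [[3 + 2 * t, 1, 5 + t] for t in range(5)])
        mt = compute_migration_trajectory(ot, et)
        assert np.ptp(mt.positions, axis=0).max() < 1e-12

    def test_constant_et_leaves_ot_unchanged(self):
        et = Trajectory(np.arange(4), np.tile([7.0, 7.0, 7.0], (4, 1)))
        ot = track("c", [[t, t**2, 0] for t in range(4)])
        mt = compute_migration_trajectory(ot, et)
        np.testing.assert_allclose(mt.positions, ot.positions)

    def test_decomposition_identity(self):
        spec = TrackSimSpec(n_anchor=4, n_deep=10, n_frames=50, noise_sd=0.5, seed=3)
        tracks, _, _ = simulate_explant_tracks(spec)
        dec = decompose_tracks(tracks)
        et = dec.elongation
        delta_et = et.positions - et.positions[0]
        for tr in tracks:
            mt = dec.migration[tr.track_id]
            # OT(t) == MT(t) + (ET(t) - ET(t0)) at every index
            np.testing.assert_allclose(
                tr.positions, mt.positions + delta_et, atol=1e-9
            )

    def test_circle_recovery_from_synthetic_deep_cells(self):
        spec = TrackSimSpec(
            n_anchor=3, n_deep=6, n_frames=60, rotation_radius=5.0,
            rotation_period=20, noise_sd=0.0, seed=4,
        )
        tracks, _, _ = simulate_explant_tracks(spec)
        dec = decompose_tracks(tracks)
        for tr in tracks:
            if tr.role == "deep":
                r = fit_circle_radius(dec.migration[tr.track_id].positions)
                assert r == pytest.approx(5.0, rel=1e-6)

    def test_no_overlap_raises(self):
        et = Trajectory(np.arange(3), np.zeros((3, 3)))
        ot = track("c", [[0, 0, 0], [1, 0, 0]], times=[10, 11])
        with pytest.raises(ValueError, match="overlap"):
            compute_migration_trajectory(ot, et)


class TestResampleGaps:
    def test_short_gap_linearly_interpolated(self):
        tr = track("c", [[0, 0, 0], [3, 6, 9]], times=[0, 3])
        (filled,) = resample_gaps(tr, max_gap=3)
        np.testing.assert_array_equal(filled.times, [0, 1, 2, 3])
        np.testing.assert_allclose(filled.positions[1], [1, 2, 3])
        np.testing.assert_allclose(filled.positions[2], [2, 4, 6])
        assert filled.interpolated.tolist() == [False, True, True, False]

    def test_long_gap_splits_track(self):
        tr = track(
            "c",
            [[0, 0, 0], [1, 0, 0], [9, 0, 0], [10, 0, 0]],
            times=[0, 1, 7, 8],  # 5 missing frames between 1 and 7
        )
        segs = resample_gaps(tr, max_gap=3)
        assert len(segs) == 2
        assert segs[0].times.tolist() == [0, 1]
        assert segs[1].times.tolist() == [7, 8]
        assert segs[0].track_id != segs[1].track_id

    def test_gapless_track_unchanged(self):
        tr = track("c", [[t, 0, 0] for t in range(5)])
        (out,) = resample_gaps(tr)
        assert out.track_id == "c"
        np.testing.assert_array_equal(out.positions, tr.positions)
        assert not out.interpolated.any()


class TestMovementDirections:
    def test_cardinal_directions_fall_in_expected_bins(self):
        tr_east = track("e", [[0, 0, 0], [1, 0, 0]])
        tr_north = track("n", [[0, 0, 0], [0, 1, 0]])
        h = movement_directions([tr_east, tr_north], window=1, plane="xy", n_bins=16)
        assert h.counts.sum() == 2
        assert h.counts[0] == 1  # 0 deg -> first bin [0, 22.5)
        assert h.counts[4] == 1  # 90 deg -> bin [90, 112.5)

    def test_matches_brute_force_binning(self, rng):
        steps = rng.normal(size=(100, 3))
        pos = np.vstack([[0, 0, 0], np.cumsum(steps, axis=0)])
        tr = track("c", pos)
        h = movement_directions([tr], window=1, plane="xy", n_bins=16)
        angles = np.degrees(np.arctan2(steps[:, 1], steps[:, 0])) % 360
        expected, _ = np.histogram(angles, bins=np.linspace(0, 360, 17))
        np.testing.assert_array_equal(h.counts, expected)

    def test_zero_projection_excluded_and_counted(self):
        tr = track("c", [[0, 0, 0], [0, 0, 5], [1, 0, 5]])  # first step pure z
        h = movement_directions([tr], window=1, plane="xy")
        assert h.n_zero == 1
        assert h.counts.sum() == 1
        assert h.n_steps == 2  # conservation: binned + excluded = total

    def test_window_displacement(self):
        tr = track("c", [[0, 0, 0], [1, 1, 0], [2, 0, 0]])
        h = movement_directions([tr], window=2, plane="xy")
        # single step (2, 0): angle 0
        assert h.counts.sum() == 1 and h.counts[0] == 1

    def test_invalid_plane_rejected(self):
        tr = track("c", [[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError, match="plane"):
            movement_directions([tr], plane="xq")

    def test_histogram_conservation_on_synthetic_tracks(self):
        spec = TrackSimSpec(n_anchor=3, n_deep=10, n_frames=30, noise_sd=0.3, seed=5)
        tracks, _, _ = simulate_explant_tracks(spec)
        h = movement_directions(tracks, window=1)
        total_steps = sum(len(tr.times) - 1 for tr in tracks)
        assert h.n_steps == total_steps


class TestCircleFit:
    def test_exact_circle_radius(self, rng):
        theta = rng.uniform(0, 2 * np.pi, size=50)
        pts = np.column_stack(
            [3 + 4 * np.cos(theta), -1 + 4 * np.sin(theta), np.full(50, 2.0)]
        )
        assert fit_circle_radius(pts) == pytest.approx(4.0, rel=1e-9)

    def test_tilted_circle_in_3d(self, rng):
        u1 = np.array([1.0, 1.0, 0]) / np.sqrt(2)
        u2 = np.array([0, 0, 1.0])
        theta = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = 2.5 * (np.outer(np.cos(theta), u1) + np.outer(np.sin(theta), u2))
        assert fit_circle_radius(pts + [5, 6, 7]) == pytest.approx(2.5, rel=1e-9)
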