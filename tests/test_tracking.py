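"""Background estimation, single-frame detection, and whole-video tracking."""

import numpy as np
import pytest

import arenatrack as at
from arenatrack.tracking import BackgroundModel


def _blob_frame(shape=(60, 80), level=255):
    return np.full(shape, level, dtype=np.uint8)


class TestEstimateBackground:
    def test_leader_equals_rendered_background(self, single_arena_scene):
        scene, paths, frames, truth = single_arena_scene
        bg = at.estimate_background(frames, (0, truth.first_frame), "leader_frame")
        assert (bg.image == scene.background_level).all()

    def test_median_stack_removes_transient_blob(self):
        # blob occupies each pixel in < 50% of the frames -> median is clean
        frames = np.stack([_blob_frame() for _ in range(5)])
        frames[0, 10:20, 10:20] = 0
        frames[1, 30:40, 30:40] = 0
        bg = at.estimate_background(frames, (0, 5), "median_stack")
        assert (bg.image == 255).all()

    def test_median_of_single_frame_equals_leader(self, single_arena_scene):
        _, _, frames, _ = single_arena_scene
        a = at.estimate_background(frames, (3, 4), "median_stack")
        b = at.estimate_background(frames, (3, 4), "leader_frame")
        np.testing.assert_array_equal(a.image, b.image)

    def test_out_of_bounds_range_rejected(self, single_arena_scene):
        _, _, frames, _ = single_arena_scene
        with pytest.raises(IndexError):
            at.estimate_background(frames, (0, len(frames) + 1), "median_stack")


class TestDetectInFrame:
    settings = at.DetectionSettings(threshold=50, min_blob_area_px=10)
    bg = BackgroundModel(image=np.full((60, 80), 255.0), source="leader_frame")
    arena = (0.0, 0.0, 79.0, 59.0)

    def test_centroid_of_rendered_ellipse(self, single_arena_scene):
        scene, paths, frames, truth = single_arena_scene
        bg = at.estimate_background(frames, (0, 1), "leader_frame")
        settings = at.DetectionSettings(threshold=50)
        n = len(truth.positions[0])
        for i in (0, n // 2, n - 1):
            x, y = truth.positions[0][i]
            got = at.detect_in_frame(frames[truth.first_frame + i], bg, settings, scene.arenas[0])
            assert got is not None
            assert np.hypot(got[0] - x, got[1] - y) < 0.5

    def test_blob_free_frame_gives_none(self):
        frame = _blob_frame()
        assert at.detect_in_frame(frame, self.bg, self.settings, self.arena) is None

    def test_small_blob_ignored_largest_kept(self):
        frame = _blob_frame()
        frame[10:14, 10:14] = 0  # 16 px: above min area, the animal
        frame[40:42, 60:62] = 0  # 4 px: a dropping, below min area
        got = at.detect_in_frame(frame, self.bg, self.settings, self.arena)
        # hand-computed centroid of the 4x4 block at rows/cols 10..13
        assert got == pytest.approx((11.5, 11.5))

    def test_polarity_lighter(self):
        bg = BackgroundModel(image=np.zeros((60, 80)), source="leader_frame")
        frame = np.zeros((60, 80), dtype=np.uint8)
        frame[20:28, 30:38] = 200
        s = at.DetectionSettings(threshold=50, min_blob_area_px=10, polarity="lighter")
        got = at.detect_in_frame(frame, bg, s, self.arena)
        assert got == pytest.approx((33.5, 23.5))


class TestTrackVideo:
    def test_noiseless_rmse_below_half_pixel(self, tracked_single):
        scene, paths, frames, truth, tracks = tracked_single
        tr = tracks[0]
        err = np.hypot(*(tr.samples - truth.positions[0]).T)
        assert np.sqrt((err**2).mean()) <= 0.5
        assert tr.detected.all()

    def test_four_arenas_no_identity_swaps(self, four_arena_scene):
        from conftest import track_scene

        scene, paths, frames, truth = four_arena_scene
        tracks = track_scene(scene, frames, truth)
        assert set(tracks) == {0, 1, 2, 3}
        for arena_id, tr in tracks.items():
            err = np.hypot(*(tr.samples - truth.positions[arena_id]).T)
            assert err.max() < 0.5, f"arena {arena_id}"

    def test_detections_stay_inside_arena(self, four_arena_scene):
        from conftest import track_scene

        scene, paths, frames, truth = four_arena_scene
        for arena_id, tr in track_scene(scene, frames, truth).items():
            x0, y0, x1, y1 = scene.arenas[arena_id]
            xy = tr.samples[tr.detected]
            assert (xy[:, 0] >= x0).all() and (xy[:, 0] <= x1).all()
            assert (xy[:, 1] >= y0).all() and (xy[:, 1] <= y1).all()

    def test_single_frame_window(self, tracked_single):
        scene, paths, frames, truth, _ = tracked_single
        bg = at.estimate_background(frames, (0, 1), "leader_frame")
        tracks = at.track_video(
            frames, {0: scene.arenas[0]}, at.DetectionSettings(), bg,
            truth.first_frame, truth.first_frame + 1, fps=truth.fps,
        )
        assert len(tracks[0]) == 1

    def test_tracking_is_deterministic(self, single_arena_scene):
        from conftest import track_scene

        scene, paths, frames, truth = single_arena_scene
        a = track_scene(scene, frames, truth)[0]
        b = track_scene(scene, frames, truth)[0]
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.detected, b.detected)

    def test_noise_below_third_of_threshold_high_detection_rate(self):
        scene = at.SceneSpec(
            frame_size=(160, 120), arenas=((10, 10, 150, 110),), noise_sigma=50 / 3, seed=9
        )
        path = at.ScriptedPath(waypoints=((30, 30), (120, 90)), duration_s=5.0, fps=10.0)
        frames, truth = at.render_video(scene, {0: path})
        bg = at.estimate_background(frames, (0, truth.first_frame), "median_stack")
        tracks = at.track_video(
            frames, {0: scene.arenas[0]}, at.DetectionSettings(threshold=50), bg,
            truth.first_frame, len(frames), fps=truth.fps,
        )
        assert tracks[0].detected.mean() >= 0.99

    def test_empty_arena_warns_not_crashes(self, single_arena_scene):
        scene, paths, frames, truth = single_arena_scene
        bg = at.estimate_background(frames, (0, 1), "leader_frame")
        with pytest.warns(UserWarning, match="no detections"):
            tracks = at.track_video(
                frames, {0: scene.arenas[0]}, at.DetectionSettings(), bg, 0,
                truth.first_frame, fps=truth.fps,
            )
        assert tracks[0].is_empty

    def test_missing_fps_rejected(self, single_arena_scene):
        scene, paths, frames, truth = single_arena_scene
        bg = at.estimate_background(frames, (0, 1), "leader_frame")
        with pytest.raises(ValueError, match="fps"):
            at.track_video(frames, {0: scene.arenas[0]}, at.DetectionSettings(), bg, 0, 5)


class TestFillGaps:
    def _track_with_gaps(self, detected_frames, n=10):
        xy = np.full((n, 2), np.nan)
        det = np.zeros(n, dtype=bool)
        for f in detected_frames:
            xy[f] = (float(f), 2.0 * f)
            det[f] = True
        # carry-forward as the tracker does
        for i in range(1, n):
            if not det[i] and np.isfinite(xy[i - 1, 0]):
                xy[i] = xy[i - 1]
        return at.Track(arena_id=0, fps=10.0, start_frame=0, end_frame=n, samples=xy, detected=det)

    def test_short_gap_midpoint(self):
        tr = self._track_with_gaps([0, 2], n=3)
        out = at.fill_gaps(tr, max_gap_frames=1)
        np.testing.assert_allclose(out.samples[1], (1.0, 2.0))
        assert out.interpolated[1] and not out.detected[1]

    def test_long_gap_keeps_carry_forward(self):
        tr = self._track_with_gaps([0, 6], n=7)
        out = at.fill_gaps(tr, max_gap_frames=3)
        np.testing.assert_array_equal(out.samples[1:6], np.tile(tr.samples[0], (5, 1)))
        assert not out.interpolated.any()

    def test_gapless_track_unchanged(self):
        tr = self._track_with_gaps(list(range(5)), n=5)
        out = at.fill_gaps(tr, max_gap_frames=2)
        np.testing.assert_array_equal(out.samples, tr.samples)
        assert not out.interpolated.any()


class TestTrackIO:
    def test_csv_roundtrip(self, tmp_path, tracked_single):
        *_, tracks = tracked_single
        tr = tracks[0]
        p = tmp_path / "track.csv"
        tr.to_csv(p)
        import pandas as pd

        back = at.Track.from_frame(pd.read_csv(p), fps=tr.fps)
        np.testing.assert_allclose(back.samples, tr.samples)
        assert back.start_frame == tr.start_frame and back.end_frame == tr.end_frame
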