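"""Blob extraction (moments) and track association (gating, determinism)."""

import numpy as np
import pytest
from skimage.draw import disk

import weirtrack as wt
from weirtrack.blobs import Blob, extract_blobs
from weirtrack.tracking import (
    SequencingError,
    Track,
    TrackingParams,
    associate,
    track_video,
    tracks_from_table,
    tracks_to_table,
)

from conftest import match_tracks_to_truth
from oracles import best_assignment, moment_axes


def make_blob(frame, row, col, area=100):
    return Blob(frame, (row, col), area, float(area), (0, 0, 1, 1), 10.0, 10.0, 1.0, 0.0)


class TestExtractBlobs:
    def test_empty_mask(self):
        assert extract_blobs(np.zeros((20, 20), bool), 1.0) == []

    def test_disk_area_and_roundness(self):
        mask = np.zeros((40, 40), bool)
        rr, cc = disk((20, 20), 10.0)
        mask[rr, cc] = True
        rasterized = int(mask.sum())
        (blob,) = extract_blobs(mask, 1.0)
        assert abs(blob.pixel_area - 314) / 314 < 0.05
        assert abs(blob.pixel_area - rasterized) <= 8  # opening+closing nearly neutral
        assert 1.0 <= blob.aspect_ratio <= 1.1
        assert blob.area == pytest.approx(blob.pixel_area)
        assert not blob.touches_border

    def test_rectangle_axes_match_bruteforce_moments(self):
        mask = np.zeros((60, 60), bool)
        mask[10:20, 5:45] = True  # 10 x 40 rectangle
        (blob,) = extract_blobs(mask, 1.0)
        coords = np.argwhere(mask)
        major, minor = moment_axes(coords)
        assert blob.major_axis == pytest.approx(major, rel=1e-6)
        assert blob.minor_axis == pytest.approx(minor, rel=1e-6)
        assert blob.aspect_ratio == pytest.approx(major / minor, rel=1e-6)

    def test_thin_diagonal_axes_match_bruteforce(self):
        mask = np.zeros((60, 60), bool)
        mask[20:23, 5:55] = True  # 3 px thick bar survives a 3x3 opening
        (blob,) = extract_blobs(mask, 1.0)
        cleaned_coords = np.argwhere(mask)  # opening+closing is identity here
        major, minor = moment_axes(cleaned_coords)
        assert blob.aspect_ratio == pytest.approx(major / minor, rel=1e-6)

    def test_small_specks_rejected(self):
        mask = np.zeros((30, 30), bool)
        mask[4:8, 4:8] = True  # 16 px < default min area
        mask[15, 15] = True  # single pixel: removed by opening
        assert extract_blobs(mask, 1.0, min_blob_area=30) == []

    def test_pixel_scale_scales_area_quadratically(self):
        mask = np.zeros((40, 40), bool)
        mask[10:20, 10:20] = True
        (b,) = extract_blobs(mask, 2.0)
        assert b.area == pytest.approx(b.pixel_area * 4.0)

    def test_border_touching_flagged(self):
        mask = np.zeros((30, 30), bool)
        rr, cc = disk((3, 15), 6)
        keep = rr >= 0
        mask[rr[keep].clip(0, 29), cc[keep]] = True
        (b,) = extract_blobs(mask, 1.0)
        assert b.touches_border


class TestAssociate:
    def test_single_candidate_matched_via_prediction(self):
        t = Track(0, [make_blob(0, 50, 45), make_blob(1, 50, 50)])
        tracks = associate([t], [make_blob(2, 50, 56)], gate_radius=10, max_misses=3)
        assert len(tracks) == 1
        assert len(t) == 3
        assert t.predicted_position() == (50, 62)

    def test_unambiguous_assignment_matches_bruteforce(self, rng):
        # well-separated pairs: every blob is in the gate of exactly one
        # track, so greedy must equal the exhaustive optimum
        for _ in range(20):
            pos = rng.uniform(10, 90, size=(4, 2))
            while np.min(
                np.linalg.norm(pos[:, None] - pos[None, :], axis=2) + np.eye(4) * 1e9
            ) < 25:
                pos = rng.uniform(10, 90, size=(4, 2))
            tracks = [Track(i, [make_blob(0, *pos[i])]) for i in range(4)]
            jitter = rng.uniform(-4, 4, size=(4, 2))
            blobs = sorted(
                (make_blob(1, *(pos[i] + jitter[i])) for i in range(4)),
                key=lambda b: b.centroid,
            )
            associate(tracks, blobs, gate_radius=10, max_misses=3)
            got = {(t.id, t.last.centroid) for t in tracks if len(t) == 2}
            expected = best_assignment(pos, [b.centroid for b in blobs], 10)
            want = {(pi, blobs[bi].centroid) for pi, bi in expected}
            assert got == want

    def test_out_of_gate_blob_starts_new_track_and_counts_miss(self):
        t = Track(0, [make_blob(0, 10, 10)])
        tracks = associate([t], [make_blob(1, 80, 80)], gate_radius=10, max_misses=3)
        assert len(tracks) == 2
        assert t.miss_count == 1
        assert tracks[1].id == 1 and tracks[1].last.centroid == (80, 80)

    def test_track_closes_after_miss_budget(self):
        t = Track(0, [make_blob(0, 10, 10)])
        tracks = [t]
        for f in range(1, 6):
            associate(tracks, [], gate_radius=10, max_misses=3)
        assert t.status == "closed"

    def test_out_of_order_frames_rejected(self):
        t = Track(0, [make_blob(5, 10, 10)])
        with pytest.raises(SequencingError):
            associate([t], [make_blob(5, 10, 12)], gate_radius=10, max_misses=3)


class TestTrackVideo:
    def test_empty_scene_no_tracks(self):
        cfg = wt.SceneConfig(frame_count=60, populations=[], noise_sigma=0.0)
        frames, _ = wt.generate_scene(cfg)
        assert track_video(frames, 1.0) == []

    def test_clean_scene_tracked_one_to_one(self, clean_scene, clean_scene_tracks):
        cfg, frames, truth = clean_scene
        tracks = clean_scene_tracks
        assert len(tracks) == len(truth) == 20
        matches = match_tracks_to_truth(tracks, truth)
        assert len(matches) == 20

    def test_noisy_scene_track_count_within_10pct(self, deform_scene, deform_scene_tracks):
        _, _, truth = deform_scene
        n = len(deform_scene_tracks)
        assert abs(n - len(truth)) <= 0.1 * len(truth)

    def test_partition_no_blob_reused(self, clean_scene_tracks):
        seen = set()
        for t in clean_scene_tracks:
            frames = [b.frame_index for b in t.observations]
            assert frames == sorted(frames) and len(set(frames)) == len(frames)
            for b in t.observations:
                key = (b.frame_index, b.centroid)
                assert key not in seen
                seen.add(key)

    def test_determinism_and_table_roundtrip(self):
        cfg = wt.SceneConfig(
            frame_count=220,
            populations=[wt.PopulationSpec("tumor", 3, 20, 1, 1.05, 0.03, 5.0, 0.95, 0.0, 1.0)],
            noise_sigma=5.0, seed=77, entry_spacing=25.0,
        )
        frames, _ = wt.generate_scene(cfg)
        t1 = tracks_to_table(track_video(frames, 1.0))
        t2 = tracks_to_table(track_video(frames, 1.0))
        assert t1.equals(t2)
        rebuilt = tracks_from_table(t1)
        assert tracks_to_table(rebuilt).equals(t1)

    def test_min_track_length_filter(self):
        params = TrackingParams(min_track_length=10**6)
        cfg = wt.SceneConfig(frame_count=150, populations=[], noise_sigma=0.0)
        frames, _ = wt.generate_scene(cfg)
        assert track_video(frames, 1.0, tracking_params=params) == []
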