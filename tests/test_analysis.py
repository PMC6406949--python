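"""Outlet assignment, morphometric classification and size histograms."""

import logging

import pytest

from weirtrack.analysis import (
    AnalysisThresholds,
    CellRecord,
    analyze_tracks,
    assign_outlet,
    size_histogram,
    summarize_track,
)
from weirtrack.blobs import Blob
from weirtrack.geometry import Rect, RoiSet, WeirBand
from weirtrack.tracking import Track

from conftest import match_tracks_to_truth

ROIS = RoiSet(
    separation=Rect(100, 118, 120, 160),
    waste=Rect(8, 146, 64, 160),
    weir=WeirBand((0.0, 20.0), (119.0, 139.0), 8.0),
)


def blob_at(frame, row, col, aspect=1.0, area=300.0, border=False):
    return Blob(frame, (row, col), int(area), area, (0, 0, 1, 1),
                20.0 * aspect, 20.0, aspect, 0.0, touches_border=border)


def track_through(points, aspects=None, areas=None, tid=0):
    aspects = aspects or [1.0] * len(points)
    areas = areas or [300.0] * len(points)
    return Track(tid, [blob_at(i, r, c, a, ar)
                       for i, ((r, c), a, ar) in enumerate(zip(points, aspects, areas))],
                 status="closed")


class TestAssignOutlet:
    def test_track_ending_in_separation(self):
        t = track_through([(50, 50), (105, 125), (110, 130)])
        assert assign_outlet(t, ROIS) == "separation"

    def test_waste_then_leaving_frame(self):
        t = track_through([(30, 100), (30, 150), (30, 158)])
        assert assign_outlet(t, ROIS) == "waste"

    def test_never_in_roi(self):
        t = track_through([(80, 10), (80, 30)])
        assert assign_outlet(t, ROIS) == "none"

    def test_first_entry_wins_and_warns(self, caplog):
        t = track_through([(30, 150), (80, 140), (110, 130)])
        with caplog.at_level(logging.WARNING, logger="weirtrack.analysis"):
            assert assign_outlet(t, ROIS) == "waste"
        assert any("first entry" in r.message for r in caplog.records)


class TestSummarizeTrack:
    def test_round_stiff_cell(self):
        # crosses the band (3+ in-band points) with constant aspect 1.0
        pts = [(40, 40), (40, 52), (40, 57), (40, 60), (40, 63), (40, 75), (40, 90)]
        rec = summarize_track(track_through(pts), ROIS, AnalysisThresholds())
        assert rec.morphology == "spherical"
        assert rec.deformability == "stiff"
        assert rec.aspect_ratio_baseline == 1.0

    def test_flexible_by_inband_gain(self):
        # baseline 1.1 outside, 1.5 inside the band; 1.5 >= 1.25 * 1.1
        pts = [(40, 30), (40, 40), (40, 52), (40, 57), (40, 60), (40, 63), (40, 80), (40, 95)]
        aspects = [1.1, 1.1, 1.3, 1.5, 1.4, 1.3, 1.1, 1.1]
        rec = summarize_track(track_through(pts, aspects), ROIS, AnalysisThresholds())
        assert rec.deformability == "flexible"
        assert rec.aspect_ratio_baseline == pytest.approx(1.1)
        assert rec.aspect_ratio_weir_max == pytest.approx(1.5)

    def test_band_never_visited_undetermined(self):
        pts = [(100, 5), (100, 10), (100, 15)]
        rec = summarize_track(track_through(pts), ROIS, AnalysisThresholds())
        assert rec.deformability == "undetermined"
        assert rec.aspect_ratio_weir_max is None

    def test_doublet_flag_at_printed_onset(self):
        pts = [(40, 40), (40, 45), (40, 50)]
        rec = summarize_track(
            track_through(pts, areas=[500.0, 600.0, 520.0]), ROIS, AnalysisThresholds()
        )
        assert rec.doublet_flag  # 600 >= 560 um^2
        rec2 = summarize_track(
            track_through(pts, areas=[500.0, 550.0, 520.0]), ROIS, AnalysisThresholds()
        )
        assert not rec2.doublet_flag

    def test_elongated_morphology(self):
        pts = [(100, 5), (100, 10), (100, 15)]
        rec = summarize_track(track_through(pts, aspects=[1.5, 1.6, 1.5]),
                              ROIS, AnalysisThresholds())
        assert rec.morphology == "elongated"

    def test_border_clipped_observations_excluded_from_shape(self):
        t = Track(0, [
            blob_at(0, 40, 40, aspect=1.0),
            blob_at(1, 40, 45, aspect=1.0),
            blob_at(2, 40, 50, aspect=1.0),
            blob_at(3, 40, 55, aspect=3.0, border=True),  # clipped artefact
        ], status="closed")
        rec = summarize_track(t, ROIS, AnalysisThresholds())
        assert rec.aspect_ratio_baseline == 1.0
        assert rec.morphology == "spherical"


def make_records(areas):
    return [CellRecord(i, "separation", a, a, 1.0, None, "spherical", "undetermined", False)
            for i, a in enumerate(areas)]


class TestSizeHistogram:
    def test_peak_bin_convention(self):
        hist = size_histogram(make_records([310, 320, 340, 120]), bin_width=50)
        assert hist.peak_bin == (300, 350)
        assert hist.counts[6] == 3

    def test_single_record(self):
        hist = size_histogram(make_records([42.0]), bin_width=50)
        assert hist.peak_bin == (0, 50)
        assert hist.counts.sum() == 1

    def test_empty(self):
        hist = size_histogram([], bin_width=50)
        assert hist.peak_bin is None
        assert hist.counts.size == 0

    def test_tie_broken_to_lower_bin(self):
        hist = size_histogram(make_records([10, 60]), bin_width=50)
        assert hist.peak_bin == (0, 50)


class TestThresholdMonotonicity:
    def test_classification_counts_monotone_in_thresholds(self, deform_scene, deform_scene_tracks):
        cfg, _, _ = deform_scene
        rois = cfg.roi_set()
        elong_prev = flex_prev = None
        for factor in (1.0, 1.1, 1.25, 1.5, 2.0):
            th = AnalysisThresholds(elongation_threshold=factor, deform_factor=factor)
            recs = analyze_tracks(deform_scene_tracks, rois, th)
            n_elong = sum(r.morphology == "elongated" for r in recs)
            n_flex = sum(r.deformability == "flexible" for r in recs)
            if elong_prev is not None:
                assert n_elong <= elong_prev
                assert n_flex <= flex_prev
            elong_prev, flex_prev = n_elong, n_flex


class TestDeformabilityRecovery:
    def test_labels_match_ground_truth_events(self, deform_scene, deform_scene_tracks):
        cfg, _, truth = deform_scene
        recs = analyze_tracks(deform_scene_tracks, cfg.roi_set(), AnalysisThresholds())
        rec_by_id = {r.track_id: r for r in recs}
        truth_by_id = {c.id: c for c in truth}
        matches = match_tracks_to_truth(deform_scene_tracks, truth)
        assert len(matches) >= 18
        correct = sum(
            (rec_by_id[tid].deformability == "flexible") == truth_by_id[cid].deform_event
            for tid, cid in matches
        )
        assert correct / len(matches) >= 0.9

    def test_record_count_matches_track_count(self, deform_scene, deform_scene_tracks):
        cfg, _, _ = deform_scene
        recs = analyze_tracks(deform_scene_tracks, cfg.roi_set(), AnalysisThresholds())
        assert len(recs) == len(deform_scene_tracks)
        n_out = sum(r.outlet != "none" for r in recs)
        counts = {"separation": 0, "waste": 0, "none": 0}
        for r in recs:
            counts[r.outlet] += 1
        assert counts["separation"] + counts["waste"] == n_out
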