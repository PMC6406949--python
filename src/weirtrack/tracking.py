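"""Temporal association of per-frame blobs into cell tracks.

Greedy gated nearest-neighbour matching with a constant-velocity prediction:
each active track predicts its next centroid as last centroid plus last
displacement; candidate (track, blob) pairs within ``gate_radius`` are
accepted in ascending distance order, ties broken by (track id, blob row,
blob col) so the result is fully deterministic. Unmatched blobs seed new
tracks; unmatched tracks accumulate misses and close when the miss budget is
exhausted. Cells follow the flow on near-parallel paths, so ambiguity is
rare and a global assignment solver is unnecessary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .background import BackgroundModel, MixtureParams
from .blobs import Blob, extract_blobs


class SequencingError(ValueError):
    """Blobs arrived with a frame index other than the next expected frame."""


@dataclass
class TrackingParams:
    gate_radius: float = 12.0  # ~1.5x the expected max per-frame displacement
    min_blob_area: int = 30  # px^2
    min_track_length: int = 3
    max_misses: int = 3

    def validate(self) -> None:
        if self.gate_radius <= 0:
            raise ValueError("gate_radius must be positive")
        if self.min_blob_area < 0:
            raise ValueError("min_blob_area must be >= 0")
        if self.min_track_length < 1:
            raise ValueError("min_track_length must be >= 1")
        if self.max_misses < 0:
            raise ValueError("max_misses must be >= 0")


@dataclass
class Track:
    id: int
    observations: List[Blob] = field(default_factory=list)
    status: str = "active"
    miss_count: int = 0

    @property
    def last(self) -> Blob:
        return self.observations[-1]

    def predicted_position(self) -> Tuple[float, float]:
        """Last centroid plus last displacement (zero for single-blob tracks)."""
        if len(self.observations) >= 2:
            (r1, c1), (r0, c0) = self.observations[-1].centroid, self.observations[-2].centroid
            return (2 * r1 - r0, 2 * c1 - c0)
        return self.last.centroid

    def add(self, blob: Blob) -> None:
        if self.observations and blob.frame_index <= self.last.frame_index:
            raise SequencingError("observations must be strictly increasing in frame index")
        self.observations.append(blob)
        self.miss_count = 0

    def __len__(self) -> int:
        return len(self.observations)


def associate(
    tracks: List[Track],
    blobs: Sequence[Blob],
    gate_radius: float,
    max_misses: int,
    next_id: Optional[int] = None,
) -> List[Track]:
    """One association step; mutates and returns ``tracks``.

    All blobs must share a frame index one past the last processed frame of
    every active track.
    """
    active = [t for t in tracks if t.status == "active"]
    if blobs:
        frame = blobs[0].frame_index
        if any(b.frame_index != frame for b in blobs):
            raise SequencingError("blobs of one association step must share a frame index")
        for t in active:
            if t.last.frame_index >= frame:
                raise SequencingError(
                    f"frame {frame} is not ahead of track {t.id} (at {t.last.frame_index})"
                )

    # candidate pairs inside the gate, sorted by (distance, track id, blob pos)
    candidates = []
    for t in active:
        pr, pc = t.predicted_position()
        for bi, b in enumerate(blobs):
            d = math.hypot(b.centroid[0] - pr, b.centroid[1] - pc)
            if d <= gate_radius:
                candidates.append((d, t.id, b.centroid[0], b.centroid[1], t, bi))
    candidates.sort(key=lambda item: item[:4])

    used_tracks: set = set()
    used_blobs: set = set()
    for d, tid, _r, _c, track, bi in candidates:
        if tid in used_tracks or bi in used_blobs:
            continue
        track.add(blobs[bi])
        used_tracks.add(tid)
        used_blobs.add(bi)

    for t in active:
        if t.id not in used_tracks:
            t.miss_count += 1
            if t.miss_count > max_misses:
                t.status = "closed"

    if next_id is None:
        next_id = max((t.id for t in tracks), default=-1) + 1
    # new tracks in deterministic blob order (blobs arrive sorted by centroid)
    for bi, b in enumerate(blobs):
        if bi not in used_blobs:
            tracks.append(Track(id=next_id, observations=[b]))
            next_id += 1
    return tracks


class Tracker:
    """Stateful frame-by-frame tracker."""

    def __init__(self, params: TrackingParams | None = None):
        self.params = params or TrackingParams()
        self.params.validate()
        self.tracks: List[Track] = []
        self._next_id = 0
        self._expected_frame: Optional[int] = None

    def step(self, blobs: Sequence[Blob]) -> None:
        if blobs:
            frame = blobs[0].frame_index
            if self._expected_frame is not None and frame != self._expected_frame:
                raise SequencingError(
                    f"expected frame {self._expected_frame}, got {frame}"
                )
            self._expected_frame = frame + 1
        elif self._expected_frame is not None:
            self._expected_frame += 1
        associate(self.tracks, blobs, self.params.gate_radius, self.params.max_misses,
                  next_id=self._next_id)
        if self.tracks:
            self._next_id = max(t.id for t in self.tracks) + 1

    def finish(self) -> List[Track]:
        """Close all tracks and return those meeting the length cut, by id."""
        for t in self.tracks:
            t.status = "closed"
        kept = [t for t in self.tracks if len(t) >= self.params.min_track_length]
        kept.sort(key=lambda t: t.id)
        return kept


def track_video(
    frames,
    pixel_scale: float,
    mixture_params: MixtureParams | None = None,
    tracking_params: TrackingParams | None = None,
) -> List[Track]:
    """Full detection pipeline: background subtraction -> blobs -> tracks.

    Masks flagged as burn-in feed the background model only; enumeration
    starts once the model has settled. Returns closed tracks with at least
    ``min_track_length`` observations, sorted by id.
    """
    tracking_params = tracking_params or TrackingParams()
    tracking_params.validate()
    model = BackgroundModel(mixture_params)
    tracker = Tracker(tracking_params)
    n = 0
    for i, frame in enumerate(frames):
        n += 1
        mask, burn_in = model.process(frame)
        if burn_in:
            continue
        blobs = extract_blobs(mask, pixel_scale, tracking_params.min_blob_area, frame_index=i)
        tracker.step(blobs)
    if n == 0:
        raise ValueError("track_video requires at least one frame")
    return tracker.finish()


def tracks_to_table(tracks: Sequence[Track]) -> pd.DataFrame:
    """One row per observation (the track CSV schema)."""
    rows = []
    for t in tracks:
        for b in t.observations:
            rows.append(
                (t.id, b.frame_index, b.centroid[0], b.centroid[1], b.pixel_area,
                 b.area, b.major_axis, b.minor_axis, b.aspect_ratio, b.orientation,
                 b.touches_border)
            )
    return pd.DataFrame(
        rows,
        columns=["track_id", "frame", "row", "col", "pixel_area", "area_um2",
                 "major", "minor", "aspect_ratio", "orientation", "touches_border"],
    )


def tracks_from_table(table: pd.DataFrame) -> List[Track]:
    """Rebuild Track objects from a track table (inverse of tracks_to_table)."""
    tracks: List[Track] = []
    for tid, group in table.groupby("track_id", sort=True):
        group = group.sort_values("frame")
        obs = [
            Blob(
                frame_index=int(r.frame),
                centroid=(float(r.row), float(r.col)),
                pixel_area=int(r.pixel_area),
                area=float(r.area_um2),
                bbox=(0, 0, 0, 0),
                major_axis=float(r.major),
                minor_axis=float(r.minor),
                aspect_ratio=float(r.aspect_ratio),
                orientation=float(r.orientation),
                touches_border=bool(getattr(r, "touches_border", False)),
            )
            for r in group.itertuples()
        ]
        tracks.append(Track(id=int(tid), observations=obs, status="closed"))
    return tracks
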