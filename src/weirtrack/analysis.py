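"""Per-track morphometry: outlet assignment, size, aspect ratio, morphology
and deformability classes, and size histograms.

Each track becomes one CellRecord. Outlet assignment is gate-style: the
first outlet ROI a track's centroid enters counts, so cells that leave the
field of view after passing an outlet are still enumerated. Deformability is
scored from the transient aspect-ratio gain while the centroid is inside the
weir band: a cell that elongates by at least ``deform_factor`` over its
out-of-band baseline (with enough in-band observations) is flexible, one
that visits the band without elongating is stiff, and one that never visits
the band is undetermined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import Rect, RoiSet, WeirBand  # noqa: F401  (RoiSet is part of this surface)
from .tracking import Track

logger = logging.getLogger(__name__)


@dataclass
class AnalysisThresholds:
    """Classification cutoffs.

    ``doublet_area_threshold`` defaults to 560 um^2, the area from which
    two touching tumor cells (doublets) become indistinguishable from one
    large blob; ``bin_width`` 50 um^2 reproduces the conventional
    300-350 um^2 peak-bin reporting for ~20 um tumor cells.
    """

    elongation_threshold: float = 1.4
    deform_factor: float = 1.25
    min_weir_obs: int = 3
    doublet_area_threshold: float = 560.0  # um^2
    bin_width: float = 50.0  # um^2

    def validate(self) -> None:
        if self.elongation_threshold < 1:
            raise ValueError("elongation_threshold must be >= 1")
        if self.deform_factor < 1:
            raise ValueError("deform_factor must be >= 1")
        if self.min_weir_obs < 1:
            raise ValueError("min_weir_obs must be >= 1")
        if self.doublet_area_threshold <= 0 or self.bin_width <= 0:
            raise ValueError("area thresholds must be positive")


@dataclass
class CellRecord:
    track_id: int
    outlet: str  # separation | waste | none
    area: float  # um^2, median over observations
    max_area: float  # um^2
    aspect_ratio_baseline: float  # median outside the weir band
    aspect_ratio_weir_max: Optional[float]  # max inside the band, None if never inside
    morphology: str  # spherical | elongated
    deformability: str  # stiff | flexible | undetermined
    doublet_flag: bool


def assign_outlet(track: Track, rois: RoiSet) -> str:
    """First-entry outlet label: separation, waste, or none.

    A track entering one outlet ROI and later the other is pathological
    (trajectories do not revisit outlets); the first entry wins and a
    warning is logged.
    """
    if not track.observations:
        raise ValueError("track has no observations")
    first: Optional[str] = None
    for blob in track.observations:
        label = rois.label_of(blob.centroid)
        if label is None:
            continue
        if first is None:
            first = label
        elif label != first:
            logger.warning(
                "track %d entered %s ROI after %s ROI; keeping first entry", track.id, label, first
            )
            break
    return first or "none"


def summarize_track(track: Track, rois: RoiSet, thresholds: AnalysisThresholds) -> CellRecord:
    """Reduce one track to its CellRecord descriptors."""
    thresholds.validate()
    # frame-border-clipped blobs distort moment shapes; exclude them from
    # shape statistics (fall back to all observations if none are interior)
    interior = [b for b in track.observations if not b.touches_border]
    obs = interior if interior else list(track.observations)
    areas = np.array([b.area for b in obs])
    aspects = np.array([b.aspect_ratio for b in obs])
    inside = np.array([rois.weir.contains(b.centroid) for b in obs])

    outside = aspects[~inside]
    # a track observed only inside the band has no out-of-band baseline;
    # fall back to its overall median
    baseline = float(np.median(outside)) if outside.size else float(np.median(aspects))
    n_in = int(inside.sum())
    weir_max = float(aspects[inside].max()) if n_in else None

    if n_in == 0:
        deformability = "undetermined"
    elif n_in >= thresholds.min_weir_obs and weir_max >= thresholds.deform_factor * baseline:
        deformability = "flexible"
    else:
        deformability = "stiff"

    max_area = float(areas.max())
    return CellRecord(
        track_id=track.id,
        outlet=assign_outlet(track, rois),
        area=float(np.median(areas)),
        max_area=max_area,
        aspect_ratio_baseline=baseline,
        aspect_ratio_weir_max=weir_max,
        morphology="elongated" if baseline > thresholds.elongation_threshold else "spherical",
        deformability=deformability,
        doublet_flag=max_area >= thresholds.doublet_area_threshold,
    )


def analyze_tracks(
    tracks: Sequence[Track], rois: RoiSet, thresholds: AnalysisThresholds | None = None
) -> List[CellRecord]:
    thresholds = thresholds or AnalysisThresholds()
    return [summarize_track(t, rois, thresholds) for t in tracks]


@dataclass
class SizeHistogram:
    """Counts per half-open area bin [k*w, (k+1)*w)."""

    bin_width: float
    bin_edges: np.ndarray  # length n_bins + 1, aligned at 0
    counts: np.ndarray
    peak_bin: Optional[Tuple[float, float]]  # lowest-index bin with maximal count

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def size_histogram(records: Sequence[CellRecord], bin_width: float = 50.0) -> SizeHistogram:
    """Histogram of median cell areas in fixed-width bins aligned at zero."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    areas = np.array([r.area for r in records], dtype=float)
    if areas.size == 0:
        return SizeHistogram(bin_width, np.array([0.0]), np.array([], dtype=int), None)
    idx = np.floor(areas / bin_width).astype(int)
    counts = np.bincount(idx)
    edges = np.arange(len(counts) + 1) * bin_width
    peak = int(np.argmax(counts))  # argmax returns the lowest maximal index
    return SizeHistogram(bin_width, edges, counts, (peak * bin_width, (peak + 1) * bin_width))


def records_to_table(records: Sequence[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "track_id": r.track_id,
                "outlet": r.outlet,
                "area_um2": r.area,
                "max_area_um2": r.max_area,
                "aspect_ratio_baseline": r.aspect_ratio_baseline,
                "aspect_ratio_weir_max": r.aspect_ratio_weir_max,
                "morphology": r.morphology,
                "deformability": r.deformability,
                "doublet_flag": r.doublet_flag,
            }
            for r in records
        ]
    )
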