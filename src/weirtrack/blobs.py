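"""Foreground-mask segmentation into per-frame blobs.

A blob is one 8-connected foreground component surviving a 3x3 opening
(speckle removal) followed by a 3x3 closing (hole filling) and a minimum
area cut. Shape descriptors come from second-order central moments via the
moment-equivalent ellipse: full major/minor axis lengths, orientation, and
their ratio as the aspect ratio used for spherical-vs-elongated morphology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure

_STRUCT3 = np.ones((3, 3), dtype=bool)


@dataclass
class Blob:
    frame_index: int
    centroid: Tuple[float, float]  # (row, col) px
    pixel_area: int  # px^2
    area: float  # um^2
    bbox: Tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    major_axis: float  # px, full length
    minor_axis: float  # px, full length
    aspect_ratio: float  # >= 1
    orientation: float  # degrees
    touches_border: bool = False  # clipped by the frame edge; excluded from shape stats


def clean_mask(mask: np.ndarray) -> np.ndarray:
    """One 3x3 binary opening then one 3x3 closing."""
    opened = ndimage.binary_opening(mask, structure=_STRUCT3)
    return ndimage.binary_closing(opened, structure=_STRUCT3)


def extract_blobs(
    mask: np.ndarray,
    pixel_scale: float,
    min_blob_area: int = 30,
    frame_index: int = 0,
) -> List[Blob]:
    """Segment a binary foreground mask into Blobs.

    Components with fewer than ``min_blob_area`` pixels are dropped. For
    degenerate (line-like) components the minor axis is floored at 1 px so
    the aspect ratio stays finite.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    cleaned = clean_mask(mask)
    labels = measure.label(cleaned, connectivity=2)
    h, w = mask.shape
    blobs: List[Blob] = []
    for region in measure.regionprops(labels):
        if region.area < min_blob_area:
            continue
        r0, c0, r1, c1 = (int(v) for v in region.bbox)
        # 1-px margin: the opening erodes the padded border row/col, so a
        # clipped blob's bbox can sit one pixel inside the frame edge
        touches = r0 <= 1 or c0 <= 1 or r1 >= h - 1 or c1 >= w - 1
        major = max(float(region.axis_major_length), 1.0)
        minor = max(float(region.axis_minor_length), 1.0)
        # skimage orientation: angle from the row axis, CCW, radians
        orientation = math.degrees(float(region.orientation))
        blobs.append(
            Blob(
                frame_index=frame_index,
                centroid=(float(region.centroid[0]), float(region.centroid[1])),
                pixel_area=int(region.area),
                area=float(region.area) * pixel_scale**2,
                bbox=tuple(int(v) for v in region.bbox),
                major_axis=major,
                minor_axis=minor,
                aspect_ratio=max(major / minor, 1.0),
                orientation=orientation,
                touches_border=touches,
            )
        )
    # deterministic order: by centroid (row, col)
    blobs.sort(key=lambda b: b.centroid)
    return blobs
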