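"""Synthetic slanted-weir microfluidic video generator with per-cell ground truth.

Emulates transmitted-light footage of a weir-based cell sorter: a bright
field, dark cells entering from the left in a sample stream, a weir crossing
the channel at a slant. Large/stiff cells contact the weir and roll along it
to the separation outlet; small or deformable hemocytes squeeze over the weir
gap and continue straight to the waste outlet. Flexible cells transiently
elongate while in contact with the weir band. The generator also adds
per-pixel Gaussian sensor noise and a slow linear illumination ramp - the two
disturbances an adaptive background model has to absorb.

Every simulated cell carries a full ground-truth trajectory (pose per frame,
routing, deformation event) so each downstream stage can be validated exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .geometry import Point, Rect, RoiSet, WeirBand

VALID_LABELS = ("tumor", "leukocyte", "erythrocyte")

# Frames over which a deformation event ramps the aspect ratio up (while the
# centroid is inside the weir band) and relaxes back after leaving it.
DEFORM_RAMP_FRAMES = 4

# Cells enter with their centroid at this column.
_ENTRY_COL = 2.0


class ConfigurationError(ValueError):
    """A SceneConfig violates its invariants."""


class GenerationError(RuntimeError):
    """A valid-looking config cannot be realized (too dense / too short)."""


@dataclass
class PopulationSpec:
    """One cell population: geometry, kinematics and routing behaviour.

    ``route_separation_prob`` is the per-cell probability of following the
    weir to the separation outlet (near 1 for tumor cells, near 0 for
    hemocytes, which cross the weir gap). ``deform_prob`` is the probability
    of a transient deformation event during weir contact and ``deform_gain``
    the multiplicative aspect-ratio increase at full deformation.
    """

    label: str
    count: int
    diameter_mean: float  # um
    diameter_sd: float  # um
    aspect_ratio_mean: float = 1.05
    aspect_ratio_sd: float = 0.05
    speed: float = 4.0  # px per frame
    route_separation_prob: float = 0.5
    deform_prob: float = 0.0
    deform_gain: float = 1.5

    def validate(self) -> None:
        if self.label not in VALID_LABELS:
            raise ConfigurationError(f"unknown population label {self.label!r}")
        if self.count < 0:
            raise ConfigurationError("population count must be >= 0")
        if self.diameter_mean <= 0:
            raise ConfigurationError("diameter_mean must be positive")
        if self.diameter_sd < 0:
            raise ConfigurationError("diameter_sd must be >= 0")
        if self.aspect_ratio_mean < 1:
            raise ConfigurationError("aspect_ratio_mean must be >= 1")
        if not 0 <= self.route_separation_prob <= 1:
            raise ConfigurationError("route_separation_prob must be in [0, 1]")
        if not 0 <= self.deform_prob <= 1:
            raise ConfigurationError("deform_prob must be in [0, 1]")
        if self.deform_gain < 1:
            raise ConfigurationError("deform_gain must be >= 1")
        if self.speed <= 0:
            raise ConfigurationError("speed must be positive")


@dataclass
class SceneConfig:
    """Full description of one synthetic video; identical configs (including
    ``seed``) produce bit-identical videos and ground truth."""

    frame_count: int = 400
    frame_height_px: int = 120
    frame_width_px: int = 160
    pixel_scale: float = 1.0  # um per px
    frame_interval: float = 0.01  # s per frame
    background_level: float = 200.0
    cell_level: float = 60.0
    noise_sigma: float = 5.0
    drift_amplitude: float = 6.0  # intensity units over the full video
    weir_origin_px: Tuple[float, float] = (0.0, 20.0)
    weir_angle: float = 45.0  # degrees from the channel (column) axis
    weir_band_halfwidth_px: float = 8.0
    roi_separation: Rect = field(default_factory=lambda: Rect(100, 118, 120, 160))
    roi_waste: Rect = field(default_factory=lambda: Rect(8, 146, 64, 160))
    populations: List[PopulationSpec] = field(default_factory=list)
    seed: int = 0
    entry_start_frame: int = 60
    entry_spacing: Optional[float] = None  # frames between cell entries; auto if None
    entry_end_frame: Optional[int] = None  # last admissible entry frame; auto if None

    def __post_init__(self) -> None:
        if not isinstance(self.roi_separation, Rect):
            self.roi_separation = Rect.from_sequence(self.roi_separation)
        if not isinstance(self.roi_waste, Rect):
            self.roi_waste = Rect.from_sequence(self.roi_waste)
        self.populations = [
            p if isinstance(p, PopulationSpec) else PopulationSpec(**p) for p in self.populations
        ]

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.frame_count <= 0 or self.frame_height_px <= 0 or self.frame_width_px <= 0:
            raise ConfigurationError("frame dimensions and frame_count must be positive")
        if self.pixel_scale <= 0:
            raise ConfigurationError("pixel_scale must be positive")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be positive")
        for name in ("background_level", "cell_level"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ConfigurationError(f"{name} must be within [0, 255]")
        if not self.cell_level < self.background_level:
            raise ConfigurationError("cell_level must be below background_level (dark cells on bright field)")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.weir_band_halfwidth_px <= 0:
            raise ConfigurationError("weir_band_halfwidth_px must be positive")
        if not (0 < self.weir_angle < 90):
            raise ConfigurationError("weir_angle must be in (0, 90) degrees")
        h, w = self.frame_height_px, self.frame_width_px
        for name, roi in (("roi_separation", self.roi_separation), ("roi_waste", self.roi_waste)):
            if not roi.inside_frame(h, w):
                raise ConfigurationError(f"{name} extends outside the frame")
        if self.roi_separation.intersects(self.roi_waste):
            raise ConfigurationError("roi_separation and roi_waste overlap")
        for pop in self.populations:
            pop.validate()

    # -- derived geometry ------------------------------------------------

    def weir_band(self) -> WeirBand:
        """Weir segment clipped to the frame, from the configured origin."""
        theta = math.radians(self.weir_angle)
        dr, dc = math.sin(theta), math.cos(theta)
        r0, c0 = self.weir_origin_px
        # extend until the segment leaves the frame
        t_max = min(
            (self.frame_height_px - 1 - r0) / dr if dr > 0 else math.inf,
            (self.frame_width_px - 1 - c0) / dc if dc > 0 else math.inf,
        )
        p1 = (r0 + t_max * dr, c0 + t_max * dc)
        return WeirBand((r0, c0), p1, self.weir_band_halfwidth_px)

    def roi_set(self) -> RoiSet:
        return RoiSet(self.roi_separation, self.roi_waste, self.weir_band())

    def weir_col_at_row(self, row: float) -> float:
        theta = math.radians(self.weir_angle)
        r0, c0 = self.weir_origin_px
        return c0 + (row - r0) * math.cos(theta) / math.sin(theta)

    # -- (de)serialisation ----------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roi_separation"] = list(asdict(self.roi_separation).values())
        d["roi_waste"] = list(asdict(self.roi_waste).values())
        d["weir_origin_px"] = list(self.weir_origin_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "weir_origin_px" in d:
            d["weir_origin_px"] = tuple(d["weir_origin_px"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_populations(
    n_tumor: int = 30, n_leukocyte: int = 20, n_erythrocyte: int = 40
) -> List[PopulationSpec]:
    """Typical study populations: ~20 um tumor cells routed along the weir,
    ~10 um leukocytes and ~7 um erythrocytes crossing to waste."""
    return [
        PopulationSpec("tumor", n_tumor, 20.0, 1.0, 1.05, 0.05, 4.0, 0.95, 0.3, 1.6),
        PopulationSpec("leukocyte", n_leukocyte, 10.0, 1.0, 1.05, 0.05, 4.0, 0.02, 0.7, 1.4),
        PopulationSpec("erythrocyte", n_erythrocyte, 7.0, 0.5, 1.2, 0.1, 4.0, 0.01, 0.8, 1.3),
    ]


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class CellTruth:
    """Per-cell ground truth: identity, routing and the full pose trajectory.

    Pose arrays are aligned: index ``i`` is frame ``entry_frame + i``. Axis
    lengths are full (not semi-) axes in pixels, matching moment-derived blob
    axis conventions.
    """

    id: int
    label: str
    route: str  # "separation" | "waste"
    entry_frame: int
    exit_frame: int
    rows: np.ndarray
    cols: np.ndarray
    major_px: np.ndarray
    minor_px: np.ndarray
    orientation_deg: np.ndarray
    in_band: np.ndarray
    deform_event: bool

    @property
    def n_frames(self) -> int:
        return len(self.rows)

    def centroid_at(self, frame: int) -> Optional[Point]:
        if self.entry_frame <= frame <= self.exit_frame:
            i = frame - self.entry_frame
            return (float(self.rows[i]), float(self.cols[i]))
        return None

    @property
    def final_centroid(self) -> Point:
        return (float(self.rows[-1]), float(self.cols[-1]))


@dataclass
class GroundTruth:
    """All cell truths of one scene."""

    cells: List[CellTruth]

    def __len__(self) -> int:
        return len(self.cells)

    def __iter__(self):
        return iter(self.cells)

    def route_counts(self) -> dict:
        counts = {"separation": 0, "waste": 0}
        for cell in self.cells:
            counts[cell.route] += 1
        return counts

    def to_frame_table(self) -> pd.DataFrame:
        """One row per cell-frame (the CSV truth channel)."""
        rows = []
        for cell in self.cells:
            for i in range(cell.n_frames):
                rows.append(
                    (
                        cell.id,
                        cell.label,
                        cell.route,
                        cell.entry_frame + i,
                        float(cell.rows[i]),
                        float(cell.cols[i]),
                        float(cell.major_px[i]),
                        float(cell.minor_px[i]),
                        float(cell.orientation_deg[i]),
                        bool(cell.in_band[i]),
                        cell.deform_event,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "cell_id", "label", "route", "frame", "row", "col",
                "major_px", "minor_px", "orientation_deg", "in_band", "deform_event",
            ],
        )

    @classmethod
    def from_frame_table(cls, table: pd.DataFrame) -> "GroundTruth":
        """Rebuild truth objects from the per-cell-frame CSV table."""
        cells = []
        for cid, g in table.groupby("cell_id", sort=True):
            g = g.sort_values("frame")
            cells.append(
                CellTruth(
                    id=int(cid),
                    label=str(g["label"].iloc[0]),
                    route=str(g["route"].iloc[0]),
                    entry_frame=int(g["frame"].iloc[0]),
                    exit_frame=int(g["frame"].iloc[-1]),
                    rows=g["row"].to_numpy(float),
                    cols=g["col"].to_numpy(float),
                    major_px=g["major_px"].to_numpy(float),
                    minor_px=g["minor_px"].to_numpy(float),
                    orientation_deg=g["orientation_deg"].to_numpy(float),
                    in_band=g["in_band"].to_numpy(bool),
                    deform_event=bool(g["deform_event"].iloc[0]),
                )
            )
        return cls(cells)

    def to_cell_summaries(self) -> List[dict]:
        return [
            {
                "id": c.id,
                "label": c.label,
                "route": c.route,
                "entry_frame": c.entry_frame,
                "exit_frame": c.exit_frame,
                "deform_event": c.deform_event,
                "final_row": c.final_centroid[0],
                "final_col": c.final_centroid[1],
            }
            for c in self.cells
        ]


# ---------------------------------------------------------------------------
# Seed streams
# ---------------------------------------------------------------------------
#
# Each random purpose draws from its own child of the scene seed, so any
# single stream (e.g. the routing Bernoulli draws of population i) can be
# replayed in isolation:  population streams use spawn_key (pop_index, code)
# with codes 0=diameter 1=aspect 2=route 3=deform;  scene-level streams use
# (1000,) for the pooled entry order, (1001,) for entry rows and
# (2, frame_index) for per-frame sensor noise.


def population_stream(seed: int, pop_index: int, code: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(pop_index, code)))


def _scene_stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _drift(config: SceneConfig, frame_index: int) -> float:
    if config.frame_count <= 1:
        return 0.0
    return config.drift_amplitude * frame_index / (config.frame_count - 1)


def render_frame(
    poses: Sequence[Tuple[float, float, float, float, float]],
    config: SceneConfig,
    frame_index: int,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one 8-bit frame.

    ``poses`` are ``(row, col, major_px, minor_px, orientation_deg)`` tuples
    (full axis lengths). The background is ``background_level`` plus the
    linear illumination ramp plus i.i.d. Gaussian noise; each cell is an
    anti-aliased filled ellipse at ``cell_level`` whose 1-px soft edge tapers
    inside the ellipse boundary, so the rendered support equals the ground
    truth ellipse. Overlapping cells composite by the darker value.
    """
    h, w = config.frame_height_px, config.frame_width_px
    base = np.full((h, w), config.background_level + _drift(config, frame_index), dtype=np.float64)
    if config.noise_sigma > 0:
        if rng is None:
            rng = _scene_stream(config.seed, 2, frame_index)
        base += rng.normal(0.0, config.noise_sigma, size=(h, w))
    img = base.copy()
    for row, col, major, minor, orient in poses:
        a = max(major, 1.0) / 2.0  # semi-major
        b = max(minor, 1.0) / 2.0
        phi = math.radians(orient)
        pad = int(math.ceil(a)) + 2
        r_lo, r_hi = max(0, int(row) - pad), min(h, int(row) + pad + 1)
        c_lo, c_hi = max(0, int(col) - pad), min(w, int(col) + pad + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        dr = rr - row
        dc = cc - col
        # rotate into the ellipse frame: x along the major axis
        x = dc * math.cos(phi) + dr * math.sin(phi)
        y = -dc * math.sin(phi) + dr * math.cos(phi)
        q = np.sqrt((x / a) ** 2 + (y / b) ** 2)
        sd = (q - 1.0) * b  # approx signed distance to the boundary (neg inside)
        cov = np.clip(-sd, 0.0, 1.0)
        patch = img[r_lo:r_hi, c_lo:c_hi]
        cell_layer = cov * config.cell_level + (1.0 - cov) * base[r_lo:r_hi, c_lo:c_hi]
        np.minimum(patch, cell_layer, out=patch)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------


def _simulate_trajectory(
    config: SceneConfig,
    entry_frame: int,
    entry_row: float,
    radius_px: float,
    aspect_baseline: float,
    speed: float,
    route: str,
    deform_event: bool,
    deform_gain: float,
):
    """Piecewise-linear motion: straight along the channel axis until weir
    contact, then along the weir (separation route) or across it (waste
    route); aspect ratio ramps up/down around band residence for deforming
    cells. Returns pose arrays; poses stop at the frame margin."""
    h, w = config.frame_height_px, config.frame_width_px
    band = config.weir_band()
    theta = math.radians(config.weir_angle)
    dirvec = (math.sin(theta), math.cos(theta))
    contact_col = config.weir_col_at_row(entry_row)

    r, c = float(entry_row), _ENTRY_COL
    phase = "approach"
    gain = 1.0
    step_gain = (deform_gain - 1.0) / DEFORM_RAMP_FRAMES

    rows, cols, majors, minors, orients, in_band = [], [], [], [], [], []
    max_steps = 4 * (h + w)  # hard stop against non-terminating configs
    for _ in range(max_steps):
        if not (1.0 <= r <= h - 2 and 1.0 <= c <= w - 2):
            break
        inside = band.distance((r, c)) <= band.halfwidth
        if deform_event:
            if inside:
                gain = min(deform_gain, gain + step_gain)
            else:
                gain = max(1.0, gain - step_gain)
        aspect = aspect_baseline * gain
        a = radius_px * math.sqrt(aspect)
        b = radius_px / math.sqrt(aspect)
        orient = config.weir_angle if (phase == "slide" or inside) else 0.0
        rows.append(r)
        cols.append(c)
        majors.append(2 * a)
        minors.append(2 * b)
        orients.append(orient)
        in_band.append(inside)
        # advance
        if phase == "approach":
            if route == "separation" and c + speed >= contact_col:
                # land on the weir line, then slide along it
                c = contact_col
                phase = "slide"
            else:
                c += speed
        elif phase == "slide":
            r += speed * dirvec[0]
            c += speed * dirvec[1]
    return (
        np.asarray(rows), np.asarray(cols), np.asarray(majors),
        np.asarray(minors), np.asarray(orients), np.asarray(in_band, dtype=bool),
    )


def _max_transit_frames(config: SceneConfig, row_min: float, row_max: float) -> int:
    """Upper bound on frames any cell spends in the field of view."""
    h, w = config.frame_height_px, config.frame_width_px
    theta = math.radians(config.weir_angle)
    min_speed = min((p.speed for p in config.populations if p.count > 0), default=4.0)
    approach = max(config.weir_col_at_row(row_max), config.weir_col_at_row(row_min)) - _ENTRY_COL
    slide = (h - 2 - row_min) / math.sin(theta)
    straight = w - 2 - _ENTRY_COL
    worst_px = max(approach + slide, straight)
    return int(math.ceil(worst_px / min_speed)) + 2


def generate_scene(config: SceneConfig):
    """Generate the video and its ground truth.

    Returns ``(frames, truth)`` with ``frames`` a ``(T, H, W)`` uint8 array.
    Raises :class:`ConfigurationError` for invalid configs and
    :class:`GenerationError` (naming the population) when cells cannot be
    placed without full occlusion at entry or cannot finish their run within
    ``frame_count`` frames.
    """
    config.validate()
    h, w = config.frame_height_px, config.frame_width_px

    # admissible entry rows: inside the waste ROI row span (so waste-routed
    # cells exit through their ROI), inset by the largest cell radius
    max_radius = max(
        (p.diameter_mean + 3 * p.diameter_sd for p in config.populations if p.count > 0),
        default=10.0,
    ) / (2 * config.pixel_scale)
    inset = math.ceil(max_radius) + 2
    row_min = config.roi_waste.row0 + inset
    row_max = config.roi_waste.row1 - 1 - inset
    total = sum(p.count for p in config.populations)
    if total > 0 and row_min >= row_max:
        raise ConfigurationError("waste ROI row span too narrow for the configured cell sizes")

    # per-population property draws, each from its own seed stream
    cells_meta = []  # (pop_index, pop, diameter, aspect, route, deform)
    for pi, pop in enumerate(config.populations):
        n = pop.count
        if n == 0:
            continue
        diam = population_stream(config.seed, pi, 0).normal(pop.diameter_mean, pop.diameter_sd, n)
        diam = np.clip(diam, 2 * config.pixel_scale, None)
        aspect = population_stream(config.seed, pi, 1).normal(pop.aspect_ratio_mean, pop.aspect_ratio_sd, n)
        aspect = np.clip(aspect, 1.0, None)
        routes = population_stream(config.seed, pi, 2).random(n) < pop.route_separation_prob
        deforms = population_stream(config.seed, pi, 3).random(n) < pop.deform_prob
        for j in range(n):
            cells_meta.append((pi, pop, float(diam[j]), float(aspect[j]),
                               "separation" if routes[j] else "waste", bool(deforms[j])))

    if not cells_meta:
        frames = np.stack([render_frame([], config, t) for t in range(config.frame_count)])
        return frames, GroundTruth([])

    entry_end = config.entry_end_frame
    if entry_end is None:
        entry_end = config.frame_count - _max_transit_frames(config, row_min, row_max) - 2
    if entry_end < config.entry_start_frame:
        raise ConfigurationError("frame_count too small for the entry window and transit time")
    spacing = config.entry_spacing
    if spacing is None:
        spacing = max(3.0, (entry_end - config.entry_start_frame) / max(1, total - 1))

    order = _scene_stream(config.seed, 1000).permutation(len(cells_meta))
    row_rng = _scene_stream(config.seed, 1001)
    roi_set = config.roi_set()

    truths: List[CellTruth] = []
    for slot, idx in enumerate(order):
        pi, pop, diameter, aspect, route, deform = cells_meta[idx]
        entry_frame = config.entry_start_frame + int(round(slot * spacing))
        radius_px = diameter / (2 * config.pixel_scale)
        # draw an entry row that does not fully occlude an already-placed cell
        placed = False
        for _try in range(200):
            entry_row = float(row_rng.uniform(row_min, row_max))
            clear = True
            for other in truths:
                pos = other.centroid_at(entry_frame)
                if pos is None:
                    continue
                o_rad = max(other.major_px[min(entry_frame - other.entry_frame,
                                               other.n_frames - 1)], 2.0) / 2.0
                if math.hypot(pos[0] - entry_row, pos[1] - _ENTRY_COL) < radius_px + o_rad + 2:
                    clear = False
                    break
            if clear:
                placed = True
                break
        if not placed:
            raise GenerationError(
                f"population {pop.label!r} too dense: cannot place cell without full occlusion at entry"
            )
        rows, cols, majors, minors, orients, in_band = _simulate_trajectory(
            config, entry_frame, entry_row, radius_px, aspect, pop.speed, route, deform, pop.deform_gain
        )
        exit_frame = entry_frame + len(rows) - 1
        if exit_frame >= config.frame_count:
            raise GenerationError(
                f"population {pop.label!r}: cell entering at frame {entry_frame} does not "
                f"clear the field of view within frame_count={config.frame_count}"
            )
        cell = CellTruth(
            id=len(truths), label=pop.label, route=route,
            entry_frame=entry_frame, exit_frame=exit_frame,
            rows=rows, cols=cols, major_px=majors, minor_px=minors,
            orientation_deg=orients, in_band=in_band, deform_event=deform,
        )
        realized = roi_set.label_of(cell.final_centroid)
        if realized != route:
            raise GenerationError(
                f"population {pop.label!r}: trajectory ends at {cell.final_centroid} "
                f"(ROI {realized!r}) instead of the drawn {route!r} outlet; "
                "check ROI/weir geometry"
            )
        truths.append(cell)

    frames = np.empty((config.frame_count, h, w), dtype=np.uint8)
    for t in range(config.frame_count):
        poses = []
        for cell in truths:
            if cell.entry_frame <= t <= cell.exit_frame:
                i = t - cell.entry_frame
                poses.append((cell.rows[i], cell.cols[i], cell.major_px[i],
                              cell.minor_px[i], cell.orientation_deg[i]))
        frames[t] = render_frame(poses, config, t)
    return frames, GroundTruth(truths)
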