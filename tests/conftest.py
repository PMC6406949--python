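import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

import weirtrack as wt

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def tumor_population(count, diameter=20.0, sd=1.0, speed=5.0,
                     route_sep=0.95, deform_prob=0.0, deform_gain=1.6):
    return wt.PopulationSpec(
        "tumor", count, diameter, sd, 1.05, 0.03, speed, route_sep, deform_prob, deform_gain
    )


def routing_scene_config(seed, route_sep=0.95, count=100):
    """Many small fast cells at low flux: the configuration used to study
    separation-efficiency recovery."""
    return wt.SceneConfig(
        frame_count=690,
        populations=[tumor_population(count, diameter=10.0, sd=0.5, speed=7.0,
                                      route_sep=route_sep)],
        noise_sigma=5.0,
        seed=seed,
        entry_spacing=6.0,
    )


@pytest.fixture(scope="session")
def clean_scene():
    """20 well-separated ~20 um cells, no sensor noise, entries delayed until
    the background variance has settled to its floor."""
    cfg = wt.SceneConfig(
        frame_count=740,
        populations=[tumor_population(20)],
        noise_sigma=0.0,
        seed=22,
        entry_spacing=20.0,
        entry_start_frame=280,
    )
    frames, truth = wt.generate_scene(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def clean_scene_tracks(clean_scene):
    cfg, frames, truth = clean_scene
    return wt.track_video(frames, cfg.pixel_scale)


@pytest.fixture(scope="session")
def deform_scene():
    """20 cells, half routed each way, 50% transient deformation events,
    moderate sensor noise."""
    cfg = wt.SceneConfig(
        frame_count=660,
        populations=[tumor_population(20, route_sep=0.5, deform_prob=0.5)],
        noise_sigma=5.0,
        seed=31,
        entry_spacing=26.0,
    )
    frames, truth = wt.generate_scene(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def deform_scene_tracks(deform_scene):
    cfg, frames, truth = deform_scene
    return wt.track_video(frames, cfg.pixel_scale)


def match_tracks_to_truth(tracks, truth, radius=3.0):
    """Greedy one-to-one (track, truth-cell) matching by mean distance."""
    from weirtrack.stats import _mean_track_truth_distance

    pairs = []
    for t in tracks:
        for c in truth:
            d = _mean_track_truth_distance(t, c)
            if d is not None and d <= radius:
                pairs.append((d, t.id, c.id))
    pairs.sort()
    used_t, used_c, out = set(), set(), []
    for d, tid, cid in pairs:
        if tid in used_t or cid in used_c:
            continue
        used_t.add(tid)
        used_c.add(cid)
        out.append((tid, cid))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
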