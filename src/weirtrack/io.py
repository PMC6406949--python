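"""Video and table I/O.

Supported video inputs: multi-page TIFF stacks, directories of numbered
PNG/TIFF frames, and uncompressed AVI (via imageio, where a capable backend
is present). All frames are converted to 8-bit grayscale on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .background import as_grayscale


class VideoFormatError(ValueError):
    """The input video could not be read."""


def _to_uint8_stack(frames: Sequence[np.ndarray]) -> np.ndarray:
    gray = [np.clip(np.rint(as_grayscale(f)), 0, 255).astype(np.uint8) for f in frames]
    return np.stack(gray)


def read_video(path) -> np.ndarray:
    """Read a video as a (T, H, W) uint8 array."""
    path = Path(path)
    if not path.exists():
        raise VideoFormatError(f"input video {path} does not exist")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise VideoFormatError(f"no PNG/TIFF frames found in directory {path}")
        frames = []
        for p in files:
            try:
                frames.append(iio.imread(p))
            except Exception as exc:  # pragma: no cover - backend specific
                raise VideoFormatError(f"could not read frame {p}: {exc}") from exc
        return _to_uint8_stack(frames)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        return _to_uint8_stack(list(stack))
    if suffix == ".avi":
        try:
            frames = list(iio.imiter(path))
        except Exception as exc:
            raise VideoFormatError(
                f"could not decode AVI {path} (no capable imageio backend installed); "
                "convert to a multi-page TIFF or a PNG frame directory"
            ) from exc
        if not frames:
            raise VideoFormatError(f"AVI {path} contains no frames")
        return _to_uint8_stack(frames)
    raise VideoFormatError(f"unsupported video format {suffix!r} for {path}")


def write_video(frames: np.ndarray, path) -> Path:
    """Write frames as a multi-page TIFF (``.tif``) or a directory of
    zero-padded PNG frames (any other path)."""
    path = Path(path)
    frames = np.asarray(frames, dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        path.parent.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(path, frames, photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(frames):
            iio.imwrite(path / f"frame_{i:06d}.png", frame)
    return path


def write_masks(masks: Sequence[np.ndarray], path) -> Path:
    """Write foreground masks as a bilevel multi-page TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(masks, dtype=bool))
    return path


def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(config_dict: dict) -> str:
    """Stable hash of a config mapping (timestamps never enter the hash)."""
    canon = yaml.safe_dump(config_dict, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
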