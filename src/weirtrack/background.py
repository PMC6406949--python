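"""Per-pixel adaptive Gaussian-mixture background subtraction.

Each pixel intensity is modelled as a mixture of K Gaussians (weight w_k,
mean mu_k, std sigma_k). Components are ranked by w/sigma - persistent,
low-variance components rank highest and constitute the background.  Per
frame, per pixel: the first ranked component within ``match_sigma`` standard
deviations of the observation is the match; weights decay toward the match
indicator with learning rate alpha; the matched component's mean and
variance move toward the observation with the same rate.  An unmatched
observation replaces the lowest-ranked component.  The pixel is foreground
iff no component matched or the matched component lies outside the smallest
ranked prefix whose cumulative weight exceeds the background ratio T.

Ranking and the background prefix are evaluated on the state *before* the
frame's weight update, so classification reflects the model the frame was
observed against.  All updates are fully vectorised over the frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Tuple

import numpy as np


class FormatError(ValueError):
    """Input frame is not 8-bit grayscale (or convertible)."""


@dataclass
class MixtureParams:
    """Model hyperparameters.

    alpha doubles as the mean/variance learning rate (rho = alpha), the
    simplest stable variant; all values are exposed in the ``background:``
    config block.
    """

    K: int = 5
    alpha: float = 0.01
    match_sigma: float = 2.5
    background_ratio: float = 0.7  # T
    initial_sigma: float = 15.0
    min_sigma: float = 4.0
    initial_weight: float = 0.05
    burn_in_frames: int = 50

    def validate(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.match_sigma <= 0:
            raise ValueError("match_sigma must be positive")
        if not 0 < self.background_ratio < 1:
            raise ValueError("background_ratio must be in (0, 1)")
        if self.min_sigma <= 0 or self.initial_sigma <= 0:
            raise ValueError("sigma parameters must be positive")
        if not 0 < self.initial_weight < 1:
            raise ValueError("initial_weight must be in (0, 1)")
        if self.burn_in_frames < 0:
            raise ValueError("burn_in_frames must be >= 0")


@dataclass
class PixelMixtureState:
    """Per-pixel mixture arrays, shape (H, W, K)."""

    weights: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray

    @property
    def shape(self) -> Tuple[int, int]:
        return self.weights.shape[:2]


def as_grayscale(frame: np.ndarray) -> np.ndarray:
    """Accept 8-bit grayscale; convert RGB(A) by ITU-R 601 luminance."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame.astype(np.float64)
    if frame.ndim == 3 and frame.shape[2] in (3, 4):
        rgb = frame[..., :3].astype(np.float64)
        return rgb @ np.array([0.299, 0.587, 0.114])
    raise FormatError(f"expected a grayscale or RGB frame, got shape {frame.shape}")


def init_model(first_frame: np.ndarray, params: MixtureParams) -> PixelMixtureState:
    """Seed the mixture: component 1 centred on the first frame with full
    weight, remaining components empty (zero weight)."""
    params.validate()
    frame = as_grayscale(first_frame)
    h, w = frame.shape
    weights = np.zeros((h, w, params.K))
    weights[..., 0] = 1.0
    means = np.zeros((h, w, params.K))
    means[..., 0] = frame
    sigmas = np.full((h, w, params.K), float(params.initial_sigma))
    return PixelMixtureState(weights, means, sigmas)


def update_and_classify(
    state: PixelMixtureState, frame: np.ndarray, params: MixtureParams
) -> Tuple[PixelMixtureState, np.ndarray]:
    """Advance the model by one frame; return (state, foreground mask).

    The state is updated in place and also returned. The mask is boolean,
    True where the pixel is foreground.
    """
    x = as_grayscale(frame)
    if x.shape != state.shape:
        raise ValueError(f"frame shape {x.shape} does not match model {state.shape}")
    h, wdt = state.shape
    n = h * wdt
    K = params.K
    alpha = params.alpha
    # flat (n, K) views share memory with the state arrays
    w = state.weights.reshape(n, K)
    mu = state.means.reshape(n, K)
    sig = state.sigmas.reshape(n, K)
    xv = x.reshape(n)

    # 1. rank by w/sigma descending; stable sort -> ties broken by index
    order = np.argsort(-w / sig, axis=1, kind="stable")

    # 2. first ranked component within match_sigma stds of the observation;
    #    zero-weight slots are empty placeholders and cannot match
    match_slot = (w > 0) & (np.abs(xv[:, None] - mu) <= params.match_sigma * sig)
    matched_sorted = np.take_along_axis(match_slot, order, axis=1)
    any_match = matched_sorted.any(axis=1)
    first = np.argmax(matched_sorted, axis=1)  # rank index of the match
    k_match = np.take_along_axis(order, first[:, None], axis=1)[:, 0]  # slot index

    # background prefix from the pre-update weights: smallest prefix with
    # cumulative weight strictly above T
    w_sorted = np.take_along_axis(w, order, axis=1)
    prefix_len = 1 + np.argmax(np.cumsum(w_sorted, axis=1) > params.background_ratio, axis=1)
    foreground = (~any_match | (first >= prefix_len)).reshape(h, wdt)

    # 3. matched-pixel update (weights decay toward the match indicator;
    #    matched mean/variance move toward x with rho = alpha)
    slot_idx = np.arange(K)
    is_match = any_match[:, None] & (slot_idx == k_match[:, None])
    np.copyto(w, (1 - alpha) * w + alpha * is_match, where=any_match[:, None])
    mu_new = (1 - alpha) * mu + alpha * xv[:, None]
    var_new = np.maximum(
        params.min_sigma**2, (1 - alpha) * sig**2 + alpha * (xv[:, None] - mu_new) ** 2
    )
    np.copyto(mu, mu_new, where=is_match)
    np.copyto(sig, np.sqrt(var_new), where=is_match)

    # 4. no match: the lowest-ranked component is replaced by the observation
    is_repl = (~any_match[:, None]) & (slot_idx == order[:, K - 1][:, None])
    np.copyto(w, float(params.initial_weight), where=is_repl)
    np.copyto(mu, np.broadcast_to(xv[:, None], mu.shape), where=is_repl)
    np.copyto(sig, float(params.initial_sigma), where=is_repl)

    w /= w.sum(axis=1, keepdims=True)
    return state, foreground


def background_image(state: PixelMixtureState) -> np.ndarray:
    """Mean of the top-ranked background component per pixel, as uint8."""
    order = np.argsort(-state.weights / state.sigmas, axis=2, kind="stable")
    top = order[..., :1]
    img = np.take_along_axis(state.means, top, axis=2)[..., 0]
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


class BackgroundModel:
    """Streaming wrapper: feed frames, receive (mask, is_burn_in) pairs.

    Masks emitted during the first ``burn_in_frames`` frames are flagged so
    downstream enumeration can skip them while the model settles.
    """

    def __init__(self, params: MixtureParams | None = None):
        self.params = params or MixtureParams()
        self.params.validate()
        self.state: PixelMixtureState | None = None
        self.frame_index = -1

    def process(self, frame: np.ndarray) -> Tuple[np.ndarray, bool]:
        self.frame_index += 1
        if self.state is None:
            self.state = init_model(frame, self.params)
            mask = np.zeros(self.state.shape, dtype=bool)
        else:
            _, mask = update_and_classify(self.state, frame, self.params)
        return mask, self.frame_index < self.params.burn_in_frames

    def process_video(self, frames) -> Iterator[Tuple[np.ndarray, bool]]:
        for frame in frames:
            yield self.process(frame)

    def background(self) -> np.ndarray:
        if self.state is None:
            raise RuntimeError("no frames processed yet")
        return background_image(self.state)
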