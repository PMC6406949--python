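"""Independent reference implementations used as test oracles.

These are deliberately written in the most literal style possible (scalar
loops, exhaustive enumeration) and share no code with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def gmm_reference_masks(video: np.ndarray, params) -> np.ndarray:
    """Straight-line scalar Gaussian-mixture background subtraction.

    Per pixel, per frame: rank components by w/sigma (ties by index), match
    the first component within match_sigma stds, classify against the
    smallest ranked prefix whose cumulative pre-update weight exceeds T,
    then update weights/mean/variance (rho = alpha) or replace the
    lowest-ranked component. Frame 0 initialises the model and is all
    background.
    """
    video = np.asarray(video)
    T, H, W = video.shape
    K = params.K
    alpha = params.alpha
    masks = np.zeros((T, H, W), dtype=bool)
    for i in range(H):
        for j in range(W):
            w = [0.0] * K
            mu = [0.0] * K
            sig = [float(params.initial_sigma)] * K
            w[0] = 1.0
            mu[0] = float(video[0, i, j])
            for t in range(1, T):
                x = float(video[t, i, j])
                order = sorted(range(K), key=lambda k: (-(w[k] / sig[k]), k))
                match_rank = None
                for rank, k in enumerate(order):
                    if w[k] > 0 and abs(x - mu[k]) <= params.match_sigma * sig[k]:
                        match_rank = rank
                        break
                cum = 0.0
                prefix = K
                for rank, k in enumerate(order):
                    cum += w[k]
                    if cum > params.background_ratio:
                        prefix = rank + 1
                        break
                foreground = match_rank is None or match_rank >= prefix
                if match_rank is not None:
                    k_m = order[match_rank]
                    for k in range(K):
                        w[k] = (1 - alpha) * w[k] + (alpha if k == k_m else 0.0)
                    mu_new = (1 - alpha) * mu[k_m] + alpha * x
                    var_new = max(
                        params.min_sigma**2,
                        (1 - alpha) * sig[k_m] ** 2 + alpha * (x - mu_new) ** 2,
                    )
                    mu[k_m] = mu_new
                    sig[k_m] = math.sqrt(var_new)
                else:
                    k_r = order[K - 1]
                    w[k_r] = float(params.initial_weight)
                    mu[k_r] = x
                    sig[k_r] = float(params.initial_sigma)
                s = sum(w)
                for k in range(K):
                    w[k] /= s
                masks[t, i, j] = foreground
    return masks


def moment_axes(coords: np.ndarray):
    """Full major/minor axis lengths of the moment-equivalent ellipse of a
    pixel set, by brute-force second-moment summation."""
    coords = np.asarray(coords, dtype=float)
    r = coords[:, 0]
    c = coords[:, 1]
    rbar, cbar = r.mean(), c.mean()
    mrr = ((r - rbar) ** 2).mean()
    mcc = ((c - cbar) ** 2).mean()
    mrc = ((r - rbar) * (c - cbar)).mean()
    # eigenvalues of the 2x2 covariance matrix
    tr = mrr + mcc
    det = mrr * mcc - mrc**2
    disc = math.sqrt(max(tr**2 / 4 - det, 0.0))
    lam1 = tr / 2 + disc
    lam2 = tr / 2 - disc
    return 4 * math.sqrt(lam1), 4 * math.sqrt(max(lam2, 0.0))


def best_assignment(predictions, blobs, gate_radius: float):
    """Exhaustive minimum-total-distance assignment (for <= ~6 objects).

    Returns a set of (prediction_index, blob_index) pairs of the permutation
    minimising total distance over all pairings whose every pair respects
    the gate.
    """
    n_p, n_b = len(predictions), len(blobs)
    best = None
    best_cost = math.inf
    k = min(n_p, n_b)
    for p_sub in itertools.combinations(range(n_p), k):
        for b_perm in itertools.permutations(range(n_b), k):
            cost = 0.0
            ok = True
            for pi, bi in zip(p_sub, b_perm):
                d = math.hypot(
                    predictions[pi][0] - blobs[bi][0], predictions[pi][1] - blobs[bi][1]
                )
                if d > gate_radius:
                    ok = False
                    break
                cost += d
            if ok and cost < best_cost:
                best_cost = cost
                best = set(zip(p_sub, b_perm))
    return best


def rasterized_ellipse_area(row, col, semi_major, semi_minor, orientation_deg, shape):
    """Pixel-centre-inside count for a ground-truth ellipse."""
    h, w = shape
    phi = math.radians(orientation_deg)
    count = 0
    for r in range(h):
        for c in range(w):
            x = (c - col) * math.cos(phi) + (r - row) * math.sin(phi)
            y = -(c - col) * math.sin(phi) + (r - row) * math.cos(phi)
            if (x / semi_major) ** 2 + (y / semi_minor) ** 2 <= 1.0:
                count += 1
    return count


def binomial_interval(n: int, p: float, level: float = 0.95):
    """Central exact-binomial interval for the success fraction of n draws."""
    from scipy import stats

    lo = stats.binom.ppf((1 - level) / 2, n, p) / n
    hi = stats.binom.ppf(1 - (1 - level) / 2, n, p) / n
    return float(lo), float(hi)
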