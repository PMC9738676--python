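"""Frame selection for observation videos.

Two strategies: a fixed temporal rate, and an adaptive scheme that runs a
per-pixel Gaussian-mixture background model, measures the foreground (moving
pixel) ratio of every frame, and emits a frame whenever the accumulated ratio
crosses a threshold — so busier videos are sampled more densely.

The mixture model follows the classic online scheme: K Gaussians per pixel
ranked by weight/sigma; a frame value matching a component within
``match_threshold`` standard deviations updates it, otherwise the weakest
component is replaced; the top-ranked components covering
``background_weight_threshold`` of the total weight form the background.
Hyperparameters are config-exposed since no canonical values exist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "BackgroundModel",
    "ForegroundAccumulator",
    "update_background",
    "foreground_ratio",
    "adaptive_sample",
    "fixed_rate_sample",
    "sample_video_adaptive",
]

_INIT_VARIANCE = 900.0  # sigma 30 on a 0-255 scale
_MIN_VARIANCE = 4.0


@dataclass
class BackgroundModel:
    """Per-pixel mixture of K Gaussians over intensity."""

    shape: tuple[int, int]
    n_components: int = 3
    learning_rate: float = 0.005
    match_threshold: float = 2.5  # in standard deviations
    background_weight_threshold: float = 0.7
    weights: np.ndarray = field(init=False)
    means: np.ndarray = field(init=False)
    variances: np.ndarray = field(init=False)
    initialized: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        K = self.n_components
        H, W = self.shape
        self.weights = np.full((K, H, W), 1.0 / K)
        self.means = np.zeros((K, H, W))
        self.variances = np.full((K, H, W), _INIT_VARIANCE)


def update_background(
    model: BackgroundModel, frame: np.ndarray
) -> tuple[BackgroundModel, np.ndarray]:
    """One online mixture update; returns the model and the foreground mask.

    The model is updated in place (and also returned, for pipeline-style
    chaining).  The mask is True where the pixel's matched component is not
    part of the background set — or where no component matched at all.
    """
    x = np.asarray(frame, dtype=np.float64)
    if x.shape != model.shape:
        raise ValueError(f"frame shape {x.shape} != model shape {model.shape}")

    K = model.n_components
    lr = model.learning_rate
    w, mu, var = model.weights, model.means, model.variances

    if not model.initialized:
        # seed the first component on the first frame; scene starts as background
        mu[0] = x
        w[:] = 0.0
        w[0] = 1.0
        model.initialized = True
        return model, np.zeros(model.shape, dtype=bool)

    sigma = np.sqrt(var)
    dist = np.abs(x[None, :, :] - mu)
    matches = dist <= model.match_threshold * sigma

    # among matching components pick the fittest (largest weight/sigma)
    fitness = np.where(matches, w / sigma, -np.inf)
    best = np.argmax(fitness, axis=0)
    any_match = matches.any(axis=0)

    comp_idx = np.arange(K)[:, None, None]
    is_best = (comp_idx == best[None, :, :]) & any_match[None, :, :]

    # weight update: matched component reinforced, others decayed
    w *= 1.0 - lr
    w[is_best] += lr

    # matched component's mean/variance pulled toward the sample
    rho = lr
    delta = x[None, :, :] - mu
    mu[is_best] += rho * delta[is_best]
    var[is_best] += rho * (delta[is_best] ** 2 - var[is_best])
    np.clip(var, _MIN_VARIANCE, None, out=var)

    # no match: replace the weakest component with a wide Gaussian at x
    weakest = np.argmin(w, axis=0)
    replace = (comp_idx == weakest[None, :, :]) & (~any_match[None, :, :])
    mu[replace] = np.broadcast_to(x[None, :, :], mu.shape)[replace]
    var[replace] = _INIT_VARIANCE
    w[replace] = 0.05

    w /= w.sum(axis=0, keepdims=True)

    # background set: components ranked by weight/sigma whose cumulative
    # weight first covers the threshold
    order = np.argsort(-(w / np.sqrt(var)), axis=0)
    w_sorted = np.take_along_axis(w, order, axis=0)
    cum = np.cumsum(w_sorted, axis=0)
    bg_sorted = (cum - w_sorted) < model.background_weight_threshold
    bg_mask_per_comp = np.zeros_like(bg_sorted)
    np.put_along_axis(bg_mask_per_comp, order, bg_sorted, axis=0)

    matched_is_bg = np.take_along_axis(
        bg_mask_per_comp, best[None, :, :], axis=0
    )[0]
    foreground = ~(any_match & matched_is_bg)
    return model, foreground


def foreground_ratio(mask: np.ndarray, *, opening: bool = False) -> float:
    """Fraction of foreground pixels in a binary mask.

    ``opening=True`` applies a 3x3 morphological opening first, suppressing
    isolated salt noise before the ratio is taken.
    """
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    if mask.dtype != bool:
        mask = mask.astype(bool)
    if opening:
        mask = ndimage.binary_opening(mask, structure=np.ones((3, 3), dtype=bool))
    return float(mask.sum()) / mask.size


def adaptive_sample(ratios, threshold: float = 0.10) -> list[int]:
    """Accumulate per-frame foreground ratios; emit a frame index whenever the
    running sum reaches ``threshold``, then reset the accumulator to zero.

    The comparison carries a tiny relative epsilon so that exact-in-real-
    arithmetic hits (e.g. ten ratios of 0.01 against 0.10) are not missed to
    float rounding; the selection period for a constant ratio r is therefore
    exactly ceil(threshold / r).
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    eps = 1e-9 * threshold
    selected: list[int] = []
    acc = 0.0
    for idx, r in enumerate(ratios):
        r = float(r)
        if r < 0 or r > 1:
            raise ValueError(f"ratio at frame {idx} outside [0, 1]: {r}")
        acc += r
        if acc >= threshold - eps:
            selected.append(idx)
            acc = 0.0
    return selected


def fixed_rate_sample(n_frames: int, fps: float, rate_hz: float) -> list[int]:
    """Every ``round(fps / rate_hz)``-th frame index, starting at 0."""
    if fps <= 0 or rate_hz <= 0:
        raise ValueError("fps and rate_hz must be > 0")
    if rate_hz > fps:
        raise ValueError(f"sampling rate {rate_hz} exceeds fps {fps}")
    step = max(1, round(fps / rate_hz))
    return list(range(0, int(n_frames), step))


@dataclass
class ForegroundAccumulator:
    """Streaming counterpart of :func:`adaptive_sample`."""

    threshold: float = 0.10
    cumulative_ratio: float = 0.0

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")

    def push(self, ratio: float) -> bool:
        """Add one frame's ratio; True means 'select this frame'."""
        self.cumulative_ratio += ratio
        if self.cumulative_ratio >= self.threshold - 1e-9 * self.threshold:
            self.cumulative_ratio = 0.0
            return True
        return False


def sample_video_adaptive(
    frames,
    *,
    threshold: float = 0.10,
    burn_in: int = 50,
    opening: bool = True,
    model: BackgroundModel | None = None,
    n_components: int = 3,
    learning_rate: float = 0.005,
    match_threshold: float = 2.5,
    background_weight_threshold: float = 0.7,
) -> tuple[list[int], list[float]]:
    """Run the full adaptive pipeline over an iterable of frames.

    The first ``burn_in`` frames only train the background model and are
    ineligible for selection.  Returns (selected indices, per-frame ratios);
    burn-in frames report ratio 0.
    """
    acc = ForegroundAccumulator(threshold=threshold)
    selected: list[int] = []
    ratios: list[float] = []
    for idx, frame in enumerate(frames):
        frame = np.asarray(frame, dtype=np.float64)
        if model is None:
            model = BackgroundModel(
                shape=frame.shape,
                n_components=n_components,
                learning_rate=learning_rate,
                match_threshold=match_threshold,
                background_weight_threshold=background_weight_threshold,
            )
        model, mask = update_background(model, frame)
        if idx < burn_in:
            ratios.append(0.0)
            continue
        r = foreground_ratio(mask, opening=opening)
        ratios.append(r)
        if acc.push(r):
            selected.append(idx)
    return selected, ratios
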