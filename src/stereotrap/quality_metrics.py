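"""Disparity-map quality: pointwise RMSE/EPE and the temporal stability score.

All errors are measured in disparity space (px).  Rangefinder ground-truth
distances in meters are converted to disparity through the rig geometry so
that near- and far-field points contribute on the same scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .stereo_core import DisparityMap, StereoRig

__all__ = [
    "GroundTruthPoint",
    "PointwiseErrors",
    "pointwise_errors",
    "epe",
    "rmse",
    "temporal_quality",
    "fallback_flow",
]


@dataclass(frozen=True)
class GroundTruthPoint:
    """A laser-rangefinder measurement: pixel location plus distance in m."""

    x: int  # column
    y: int  # row
    distance_m: float

    def __post_init__(self) -> None:
        if not self.distance_m > 0:
            raise ValueError("distance_m must be > 0")


@dataclass
class PointwiseErrors:
    """Per-point disparity errors (px); missing points hit invalid pixels."""

    errors_px: np.ndarray
    missing: list[GroundTruthPoint]

    @property
    def epe(self) -> float:
        return epe(self.errors_px)

    @property
    def rmse(self) -> float:
        return rmse(self.errors_px)


def epe(errors: np.ndarray) -> float:
    """Endpoint error for scalar disparities: mean absolute error, px."""
    errors = np.asarray(errors, dtype=np.float64)
    if errors.size == 0:
        raise ValueError("no errors to aggregate")
    return float(np.mean(np.abs(errors)))


def rmse(errors: np.ndarray) -> float:
    """Root-mean-squared error, px."""
    errors = np.asarray(errors, dtype=np.float64)
    if errors.size == 0:
        raise ValueError("no errors to aggregate")
    return float(np.sqrt(np.mean(np.square(errors))))


def pointwise_errors(
    pred: DisparityMap, rig: StereoRig, points: list[GroundTruthPoint]
) -> PointwiseErrors:
    """Signed disparity errors at rangefinder points.

    Per point: ``predicted_disparity(pixel) - bf / distance_m``.  Points
    landing on invalid predicted pixels are reported as missing and excluded
    from the aggregates, with a warning.
    """
    if not points:
        raise ValueError("need at least one ground-truth point")
    H, W = pred.shape
    errs: list[float] = []
    missing: list[GroundTruthPoint] = []
    for pt in points:
        if not (0 <= pt.x < W and 0 <= pt.y < H):
            raise ValueError(f"point ({pt.x}, {pt.y}) outside {W}x{H} image")
        d_pred = pred.values[pt.y, pt.x]
        if not np.isfinite(d_pred):
            missing.append(pt)
            continue
        d_true = rig.bf / pt.distance_m
        errs.append(float(d_pred - d_true))
    if missing:
        warnings.warn(
            f"{len(missing)} ground-truth point(s) fell on invalid pixels "
            "and were excluded",
            stacklevel=2,
        )
    return PointwiseErrors(errors_px=np.asarray(errs), missing=missing)


def temporal_quality(
    frames: list[DisparityMap] | list[np.ndarray],
    flows: list[np.ndarray] | None = None,
) -> float:
    """Flow-compensated mean absolute frame-to-frame disparity change (px).

    For frames ``n = 2..N_T`` each pixel ``(x, y)`` is compared against the
    previous frame at the flow-compensated location ``(x - m_x, y - m_y)``,
    resolved by nearest-neighbor (integer-rounded) lookup.  Terms whose
    warped coordinate leaves the frame or lands on an invalid value are
    skipped, and that frame pair's pixel normalizer shrinks accordingly.

    ``flows`` holds one ``(H, W, 2)`` field per consecutive pair, channel 0 =
    ``m_x`` (column flow from frame ``n`` back to ``n-1``), channel 1 =
    ``m_y``; ``None`` means zero flow everywhere.
    """
    arrs = [f.values if isinstance(f, DisparityMap) else np.asarray(f, dtype=np.float64) for f in frames]
    if len(arrs) < 2:
        raise ValueError("need at least 2 frames")
    H, W = arrs[0].shape
    for a in arrs:
        if a.shape != (H, W):
            raise ValueError("all frames must share one shape")
    if flows is not None and len(flows) != len(arrs) - 1:
        raise ValueError(
            f"need {len(arrs) - 1} flow fields for {len(arrs)} frames, got {len(flows)}"
        )

    yy, xx = np.mgrid[0:H, 0:W]
    total = 0.0
    n_pairs = len(arrs) - 1
    for n in range(1, len(arrs)):
        cur, prev = arrs[n], arrs[n - 1]
        if flows is None:
            sx, sy = xx, yy
        else:
            flow = np.asarray(flows[n - 1], dtype=np.float64)
            if flow.shape != (H, W, 2):
                raise ValueError(f"flow field {n - 1} must have shape ({H}, {W}, 2)")
            sx = np.rint(xx - flow[:, :, 0]).astype(np.int64)
            sy = np.rint(yy - flow[:, :, 1]).astype(np.int64)
        inside = (sx >= 0) & (sx < W) & (sy >= 0) & (sy < H)
        sxc = np.clip(sx, 0, W - 1)
        syc = np.clip(sy, 0, H - 1)
        diff = np.abs(cur - prev[syc, sxc])
        ok = inside & np.isfinite(diff)
        n_ok = int(ok.sum())
        if n_ok == 0:
            raise ValueError(f"no comparable pixels between frames {n - 1} and {n}")
        total += float(diff[ok].sum()) / n_ok
    return total / n_pairs


def fallback_flow(
    prev_frame: np.ndarray,
    next_frame: np.ndarray,
    *,
    block: int = 16,
    search_range: int = 8,
) -> np.ndarray:
    """Integer block-matching optical flow from ``next_frame`` back to ``prev_frame``.

    The frame is tiled into ``block``-sized squares; each block's displacement
    is the integer ``(m_x, m_y)`` within ``±search_range`` minimizing the SSD
    against the previous frame, constant across the block.  Returns an
    ``(H, W, 2)`` field usable directly by :func:`temporal_quality`.
    """
    prev = np.asarray(prev_frame, dtype=np.float64)
    nxt = np.asarray(next_frame, dtype=np.float64)
    if prev.shape != nxt.shape or prev.ndim != 2:
        raise ValueError("frames must be equal-size 2-D arrays")
    H, W = prev.shape
    if block > min(H, W):
        raise ValueError(f"block {block} larger than image {W}x{H}")

    flow = np.zeros((H, W, 2))
    for by in range(0, H, block):
        for bx in range(0, W, block):
            patch = nxt[by : by + block, bx : bx + block]
            ph, pw = patch.shape
            best = (0, 0)
            best_cost = np.inf
            for my in range(-search_range, search_range + 1):
                sy = by - my
                if sy < 0 or sy + ph > H:
                    continue
                for mx in range(-search_range, search_range + 1):
                    sx = bx - mx
                    if sx < 0 or sx + pw > W:
                        continue
                    ref = prev[sy : sy + ph, sx : sx + pw]
                    cost = float(np.sum((patch - ref) ** 2))
                    if cost < best_cost or (
                        cost == best_cost and (abs(mx) + abs(my)) < (abs(best[0]) + abs(best[1]))
                    ):
                        best_cost = cost
                        best = (mx, my)
            flow[by : by + block, bx : bx + block, 0] = best[0]
            flow[by : by + block, bx : bx + block, 1] = best[1]
    return flow
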