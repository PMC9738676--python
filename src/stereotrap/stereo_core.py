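"""Block-matching stereo: SSD cost volumes, winner-take-all disparity, metric depth.

Coordinate convention
---------------------
``(i, j)`` means ``(column, row)``, 0-based.  Numpy arrays are stored
``[row, column]`` as usual, so the cost at pixel ``(i, j)`` and candidate
disparity ``d`` lives at ``volume.values[j, i, d]``.  The disparity shift is
horizontal: the right image is compared at column ``i - d``, i.e. scene
content appears shifted *left* in the right image.

Invalid pixels are encoded as NaN throughout (cost cells, disparity maps,
depth maps); every container also exposes a boolean validity view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StereoRig",
    "RectifiedPair",
    "CostVolume",
    "DisparityMap",
    "DepthMap",
    "build_cost_volume",
    "disparity_from_cost_volume",
    "disparity_to_depth",
    "depth_to_disparity",
    "apply_rectification",
]


@dataclass(frozen=True)
class StereoRig:
    """Calibration constants tying disparity (px) to metric depth (m).

    Depth and disparity are inversely related through the product of the
    camera baseline and the focal length: ``z = baseline_m * focal_px / d``.
    """

    baseline_m: float
    focal_px: float
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        if not self.baseline_m > 0:
            raise ValueError(f"baseline_m must be > 0, got {self.baseline_m}")
        if not self.focal_px > 0:
            raise ValueError(f"focal_px must be > 0, got {self.focal_px}")
        if self.image_width < 1 or self.image_height < 1:
            raise ValueError("image dimensions must be >= 1")

    @property
    def bf(self) -> float:
        """Baseline-focal product (m*px): depth = bf / disparity."""
        return self.baseline_m * self.focal_px


@dataclass(frozen=True)
class RectifiedPair:
    """A pair of rectified grayscale images of equal shape.

    Rectification guarantees that corresponding points share a scanline, so
    the stereo correspondence search is purely horizontal.
    """

    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=np.float64)
        right = np.asarray(self.right, dtype=np.float64)
        if left.ndim != 2 or right.ndim != 2:
            raise ValueError("images must be 2-D grayscale arrays")
        if left.shape != right.shape:
            raise ValueError(
                f"image shapes differ: left {left.shape} vs right {right.shape}"
            )
        if left.size == 0:
            raise ValueError("images must be non-empty")
        if not (np.isfinite(left).all() and np.isfinite(right).all()):
            raise ValueError("image intensities must be finite")
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)

    @property
    def shape(self) -> tuple[int, int]:
        return self.left.shape

    @property
    def width(self) -> int:
        return self.left.shape[1]

    @property
    def height(self) -> int:
        return self.left.shape[0]


@dataclass
class CostVolume:
    """SSD matching costs, shape ``(H, W, D)``; invalid cells are NaN."""

    values: np.ndarray
    max_disparity: int
    patch_half_height: int
    square_window: bool = False

    @property
    def validity(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class DisparityMap:
    """Per-pixel horizontal disparity in px; invalid pixels are NaN."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("disparity map must be 2-D")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DepthMap:
    """Per-pixel depth in meters; invalid pixels are NaN."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("depth map must be 2-D")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def build_cost_volume(
    pair: RectifiedPair,
    max_disparity: int,
    patch_half_height: int,
    *,
    square_window: bool = False,
) -> CostVolume:
    """Sum-of-squared-differences cost volume over candidate disparities.

    For pixel ``(i, j)`` and candidate ``d``::

        V(i, j, d) = sum_{dj=-c..c} (left(i, j+dj) - right(i-d, j+dj))**2

    i.e. a 1-px-wide column patch of height ``2c + 1``.  With
    ``square_window=True`` the sum additionally runs over columns
    ``i-c .. i+c`` (a ``(2c+1)``-square), a pragmatic robustness option that
    departs from the column-patch default.

    Cells whose shifted column ``i - d`` or patch extent leaves the image
    are NaN (flagged invalid), never clamped.
    """
    D = int(max_disparity)
    c = int(patch_half_height)
    if D < 1:
        raise ValueError(f"max_disparity must be >= 1, got {D}")
    if c < 0:
        raise ValueError(f"patch_half_height must be >= 0, got {c}")
    H, W = pair.shape
    if D > W:
        raise ValueError(f"max_disparity {D} exceeds image width {W}")

    left = pair.left
    right = pair.right
    values = np.full((H, W, D), np.nan)

    # per-disparity squared difference, then a vertical (and optionally
    # horizontal) box sum; border cells whose patch leaves the image stay NaN
    for d in range(D):
        sq = np.full((H, W), np.nan)
        if d < W:
            sq[:, d:] = (left[:, d:] - right[:, : W - d]) ** 2
        cost = _box_sum_vertical(sq, c)
        if square_window and c > 0:
            cost = _box_sum_horizontal(cost, c)
        values[:, :, d] = cost

    return CostVolume(
        values=values,
        max_disparity=D,
        patch_half_height=c,
        square_window=square_window,
    )


def _box_sum_vertical(arr: np.ndarray, c: int) -> np.ndarray:
    """Sum of a (2c+1)-tall column window; NaN where the window leaves the frame
    or touches a NaN input cell."""
    if c == 0:
        return arr
    H, W = arr.shape
    out = np.full((H, W), np.nan)
    if H < 2 * c + 1:
        return out
    k = 2 * c + 1
    bad = ~np.isfinite(arr)
    filled = np.where(bad, 0.0, arr)
    cs = np.cumsum(np.vstack([np.zeros((1, W)), filled]), axis=0)
    nb = np.cumsum(np.vstack([np.zeros((1, W), dtype=np.int64), bad]), axis=0)
    win = cs[k:, :] - cs[:-k, :]
    win[(nb[k:, :] - nb[:-k, :]) > 0] = np.nan  # any NaN in the window
    out[c : H - c, :] = win
    return out


def _box_sum_horizontal(arr: np.ndarray, c: int) -> np.ndarray:
    return _box_sum_vertical(arr.T, c).T


def disparity_from_cost_volume(
    volume: CostVolume, *, subpixel: bool = False
) -> DisparityMap:
    """Winner-take-all readout: per pixel the ``d`` minimizing the cost.

    Ties break toward the smallest ``d``.  With ``subpixel=True`` the integer
    winner is refined by fitting a parabola through the costs at
    ``(d-1, d, d+1)`` when all three cells are valid.  Pixels with no valid
    cell at any disparity come out invalid (NaN).
    """
    V = volume.values
    H, W, D = V.shape
    any_valid = np.isfinite(V).any(axis=2)

    filled = np.where(np.isfinite(V), V, np.inf)
    best = np.argmin(filled, axis=2)  # first occurrence == smallest d
    disp = best.astype(np.float64)
    disp[~any_valid] = np.nan

    if subpixel:
        jj, ii = np.nonzero(any_valid & (best >= 1) & (best <= D - 2))
        d0 = best[jj, ii]
        cm = V[jj, ii, d0 - 1]
        cc = V[jj, ii, d0]
        cp = V[jj, ii, d0 + 1]
        ok = np.isfinite(cm) & np.isfinite(cp)
        denom = cm - 2.0 * cc + cp
        ok &= denom > 0
        delta = np.zeros_like(cc)
        delta[ok] = 0.5 * (cm[ok] - cp[ok]) / denom[ok]
        disp[jj, ii] = d0 + np.clip(delta, -0.5, 0.5)

    return DisparityMap(values=disp)


def disparity_to_depth(disparity: DisparityMap, rig: StereoRig) -> DepthMap:
    """``z = b*f / d``; ``d == 0`` or invalid maps to an invalid depth pixel."""
    d = disparity.values
    z = np.full_like(d, np.nan)
    ok = np.isfinite(d) & (d > 0)
    z[ok] = rig.bf / d[ok]
    return DepthMap(values=z)


def depth_to_disparity(depth: DepthMap, rig: StereoRig) -> DisparityMap:
    """``d = b*f / z``; non-positive or invalid depth maps to invalid."""
    z = depth.values
    d = np.full_like(z, np.nan)
    ok = np.isfinite(z) & (z > 0)
    d[ok] = rig.bf / z[ok]
    return DisparityMap(values=d)


def apply_rectification(
    left_raw: np.ndarray,
    right_raw: np.ndarray,
    maps: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray],
) -> RectifiedPair:
    """Resample raw images through precomputed remap grids (bilinear).

    ``maps`` is ``(left_x, left_y, right_x, right_y)``: for each output pixel
    the *source* coordinate (column map, row map) in the raw image.  All four
    grids must share one output shape.  Out-of-bounds source coordinates
    yield NaN output pixels, which are then replaced by 0 so the result
    satisfies the finite-intensity contract of :class:`RectifiedPair`; the
    invalidity is recorded separately by callers that need it.
    """
    lx, ly, rx, ry = (np.asarray(m, dtype=np.float64) for m in maps)
    if not (lx.shape == ly.shape == rx.shape == ry.shape):
        raise ValueError("rectification maps must all share one shape")
    if lx.ndim != 2:
        raise ValueError("rectification maps must be 2-D")

    left = _remap_bilinear(np.asarray(left_raw, dtype=np.float64), lx, ly)
    right = _remap_bilinear(np.asarray(right_raw, dtype=np.float64), rx, ry)
    return RectifiedPair(left=np.nan_to_num(left), right=np.nan_to_num(right))


def _remap_bilinear(img: np.ndarray, map_x: np.ndarray, map_y: np.ndarray) -> np.ndarray:
    H, W = img.shape
    x0 = np.floor(map_x).astype(np.int64)
    y0 = np.floor(map_y).astype(np.int64)
    fx = map_x - x0
    fy = map_y - y0
    inside = (map_x >= 0) & (map_x <= W - 1) & (map_y >= 0) & (map_y <= H - 1)

    x0c = np.clip(x0, 0, W - 1)
    y0c = np.clip(y0, 0, H - 1)
    x1c = np.clip(x0 + 1, 0, W - 1)
    y1c = np.clip(y0 + 1, 0, H - 1)

    v00 = img[y0c, x0c]
    v01 = img[y0c, x1c]
    v10 = img[y1c, x0c]
    v11 = img[y1c, x1c]
    out = (
        v00 * (1 - fx) * (1 - fy)
        + v01 * fx * (1 - fy)
        + v10 * (1 - fx) * fy
        + v11 * fx * fy
    )
    out[~inside] = np.nan
    return out
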