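"""Seeded synthetic inputs: stereo scenes, motion videos, degraded night pairs.

Scenes are fronto-parallel: a textured background plane plus circular
"animal" blobs at nearer depths.  The right image is the left image with
each region shifted *left* by its disparity ``d = b*f/z``, nearer regions
composited over farther ones; dis-occluded pixels receive fresh texture and
are excluded from the shift-recovery scoring mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stereo_core import DisparityMap, RectifiedPair, StereoRig

__all__ = [
    "Blob",
    "SceneSpec",
    "RenderedScene",
    "render_stereo_pair",
    "render_motion_video",
    "degrade_night",
]


@dataclass(frozen=True)
class Blob:
    """A circular foreground region: center (col, row), radius px, depth m."""

    center: tuple[float, float]
    radius_px: float
    depth_m: float


@dataclass(frozen=True)
class SceneSpec:
    width: int = 96
    height: int = 72
    background_depth_m: float = 20.0
    blobs: tuple[Blob, ...] = ()
    rig: StereoRig = field(
        default_factory=lambda: StereoRig(
            baseline_m=0.2, focal_px=500.0, image_width=96, image_height=72
        )
    )
    texture_low: float = 0.0
    texture_high: float = 255.0
    seed: int = 0

    def __post_init__(self) -> None:
        for b in self.blobs:
            if not b.depth_m < self.background_depth_m:
                raise ValueError("blob depths must be nearer than the background")

    def disparity_of(self, depth_m: float) -> float:
        return self.rig.bf / depth_m


@dataclass
class RenderedScene:
    pair: RectifiedPair
    true_disparity: DisparityMap
    blob_masks: list[np.ndarray]  # per-blob boolean masks, left-image frame
    score_mask: np.ndarray  # pixels eligible for shift-recovery scoring


def _blob_mask(spec: SceneSpec, blob: Blob) -> np.ndarray:
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    cx, cy = blob.center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= blob.radius_px**2


def render_stereo_pair(spec: SceneSpec) -> RenderedScene:
    """Render a textured stereo pair with piecewise-constant ground truth.

    Raises if any region's disparity reaches the image width (the shifted
    content would leave the frame entirely).
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width

    disparities = [spec.disparity_of(spec.background_depth_m)] + [
        spec.disparity_of(b.depth_m) for b in spec.blobs
    ]
    for d in disparities:
        if d >= W:
            raise ValueError(f"disparity {d:.1f} px >= image width {W}")

    left = rng.uniform(spec.texture_low, spec.texture_high, size=(H, W))
    true_disp = np.full((H, W), disparities[0])
    blob_masks = []
    for blob, d in zip(spec.blobs, disparities[1:]):
        mask = _blob_mask(spec, blob)
        blob_masks.append(mask)
        true_disp[mask] = d  # later (nearer) blobs may overwrite earlier ones

    # paint the right image far-to-near so near content occludes far content
    right = np.full((H, W), np.nan)
    regions = [(~np.any(blob_masks, axis=0) if blob_masks else np.ones((H, W), bool), disparities[0])]
    order = np.argsort([-b.depth_m for b in spec.blobs])  # far to near
    for k in order:
        regions.append((blob_masks[k], disparities[k + 1]))

    for mask, d in regions:
        di = int(round(d))
        yy, xx = np.nonzero(mask)
        tx = xx - di
        ok = tx >= 0
        right[yy[ok], tx[ok]] = left[yy[ok], xx[ok]]

    disoccluded = ~np.isfinite(right)
    right[disoccluded] = rng.uniform(
        spec.texture_low, spec.texture_high, size=int(disoccluded.sum())
    )

    # pixels whose shifted correspondence exists and is not overwritten by a
    # nearer region are eligible for scoring
    score = np.zeros((H, W), dtype=bool)
    painted_by = np.full((H, W), -1, dtype=np.int64)  # which region owns each right px
    for ridx, (mask, d) in enumerate(regions):
        di = int(round(d))
        yy, xx = np.nonzero(mask)
        tx = xx - di
        ok = tx >= 0
        painted_by[yy[ok], tx[ok]] = ridx
    for ridx, (mask, d) in enumerate(regions):
        di = int(round(d))
        yy, xx = np.nonzero(mask)
        tx = xx - di
        ok = (tx >= 0) & (painted_by[yy, np.clip(tx, 0, W - 1)] == ridx)
        score[yy[ok], xx[ok]] = True

    return RenderedScene(
        pair=RectifiedPair(left=left, right=right),
        true_disparity=DisparityMap(values=true_disp),
        blob_masks=blob_masks,
        score_mask=score,
    )


def render_motion_video(
    spec: SceneSpec,
    n_frames: int,
    blob_velocity: tuple[float, float],
    *,
    blob_radius_px: float = 8.0,
    blob_intensity: float = 255.0,
    start: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Static textured background plus one moving bright blob.

    Returns ``(frames, true_ratios)`` where ``frames`` is
    ``(n_frames, H, W)`` and ``true_ratios[k]`` is the blob's visible area
    divided by the frame area in frame ``k`` (0 once the blob exits).
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.height, spec.width
    background = rng.uniform(spec.texture_low, spec.texture_high, size=(H, W))

    cx, cy = start if start is not None else (W / 4.0, H / 2.0)
    vx, vy = blob_velocity
    frames = np.empty((n_frames, H, W))
    ratios = np.empty(n_frames)
    yy, xx = np.mgrid[0:H, 0:W]
    for k in range(n_frames):
        bx, by = cx + k * vx, cy + k * vy
        mask = (xx - bx) ** 2 + (yy - by) ** 2 <= blob_radius_px**2
        frame = background.copy()
        frame[mask] = blob_intensity
        frames[k] = frame
        ratios[k] = mask.sum() / (H * W)
    return frames, ratios


def degrade_night(
    pair: RectifiedPair, hole_fraction: float, seed: int
) -> tuple[RectifiedPair, np.ndarray]:
    """Blank random contiguous square regions to a constant low intensity.

    Emulates underexposed night regions where matching has no texture to
    work with.  Returns the degraded pair and the boolean hole mask (applied
    identically to both images, in left-image coordinates).
    """
    if not 0.0 <= hole_fraction < 1.0:
        raise ValueError("hole_fraction must be in [0, 1)")
    if hole_fraction == 0.0:
        return pair, np.zeros(pair.shape, dtype=bool)

    rng = np.random.default_rng(seed)
    H, W = pair.shape
    holes = np.zeros((H, W), dtype=bool)
    side = max(2, min(H, W) // 8)
    target = hole_fraction * H * W
    while holes.sum() < target:
        y = rng.integers(0, max(1, H - side))
        x = rng.integers(0, max(1, W - side))
        holes[y : y + side, x : x + side] = True

    left = pair.left.copy()
    right = pair.right.copy()
    left[holes] = 1.0
    right[holes] = 1.0
    return RectifiedPair(left=left, right=right), holes
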