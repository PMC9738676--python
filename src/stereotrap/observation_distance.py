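"""Fuse animal detections with depth maps into camera-animal distances.

A mask detection takes the median of the valid depth values it covers; a
bounding box is expected to mix animal (near) and background (far) pixels, so
its default statistic is the median of the lower half of the valid depths
(a robust 25th percentile).  Distances backed by fewer than ``min_support``
valid depth pixels are reported missing rather than trusted.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stereo_core import DepthMap

__all__ = [
    "Detection",
    "animal_distance_mask",
    "animal_distance_bbox",
    "build_observation_table",
    "load_megadetector_json",
    "OBSERVATION_COLUMNS",
]

MIN_SUPPORT_DEFAULT = 20

OBSERVATION_COLUMNS = [
    "observation_id",
    "video_id",
    "frame_id",
    "timestamp",
    "detection_index",
    "label",
    "confidence",
    "kind",
    "distance_m",
    "n_valid_depth_px",
    "missing",
]


@dataclass
class Detection:
    """One animal detection on one frame: a bbox, optionally with a mask.

    ``bbox`` is absolute-pixel ``(x_min, y_min, x_max, y_max)``, 0-based,
    half-open.  ``kind`` is "mask" when a per-pixel binary mask is present,
    else "bbox".
    """

    frame_id: str
    bbox: tuple[float, float, float, float]
    confidence: float = 1.0
    label: str = "animal"
    mask: np.ndarray | None = None
    video_id: str = ""
    timestamp: float = float("nan")

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate bbox {self.bbox}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence outside [0, 1]: {self.confidence}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask).astype(bool)

    @property
    def kind(self) -> str:
        return "mask" if self.mask is not None else "bbox"


def animal_distance_mask(
    det: Detection, depth: DepthMap, *, min_support: int = MIN_SUPPORT_DEFAULT
) -> tuple[float, int]:
    """Median valid depth under the instance mask; (nan, n) if support < min.

    Invalid depth pixels (night holes, occlusion) are simply excluded, so
    dilating a mask into invalid territory cannot move the distance.
    """
    if det.mask is None:
        raise ValueError("detection carries no mask")
    if det.mask.shape != depth.shape:
        raise ValueError(
            f"mask shape {det.mask.shape} != depth shape {depth.shape}"
        )
    vals = depth.values[det.mask]
    vals = vals[np.isfinite(vals)]
    n = int(vals.size)
    if n < min_support:
        return float("nan"), n
    return float(np.median(vals)), n


def animal_distance_bbox(
    det: Detection,
    depth: DepthMap,
    *,
    statistic: str = "lower-half-median",
    min_support: int = MIN_SUPPORT_DEFAULT,
) -> tuple[float, int]:
    """Robust depth statistic over the valid pixels inside the bbox.

    ``statistic`` is ``"lower-half-median"`` (default: median of the nearest
    half of the depths, i.e. a 25th percentile that stays exact for 50/50
    animal/background splits) or ``"median"``.
    """
    H, W = depth.shape
    x0, y0, x1, y1 = det.bbox
    xi0, yi0 = max(0, int(math.floor(x0))), max(0, int(math.floor(y0)))
    xi1, yi1 = min(W, int(math.ceil(x1))), min(H, int(math.ceil(y1)))
    if xi0 >= xi1 or yi0 >= yi1:
        raise ValueError(f"bbox {det.bbox} has no overlap with {W}x{H} image")
    vals = depth.values[yi0:yi1, xi0:xi1].ravel()
    vals = vals[np.isfinite(vals)]
    n = int(vals.size)
    if n < min_support:
        return float("nan"), n
    if statistic == "median":
        return float(np.median(vals)), n
    if statistic == "lower-half-median":
        vals = np.sort(vals)
        lower = vals[: (n + 1) // 2]
        return float(np.median(lower)), n
    raise ValueError(f"unknown statistic {statistic!r}")


def build_observation_table(
    detections: list[Detection],
    depth_maps: dict[str, DepthMap],
    *,
    min_confidence: float = 0.2,
    statistic: str = "lower-half-median",
    min_support: int = MIN_SUPPORT_DEFAULT,
) -> pd.DataFrame:
    """Join detections to their depth frames and fuse distances.

    One row per detection at or above ``min_confidence``.  Rows whose
    distance could not be resolved (insufficient valid depth) are retained
    with ``missing=True`` so downstream exports can drop them explicitly.
    """
    unmatched = sorted(
        {d.frame_id for d in detections if d.frame_id not in depth_maps}
    )
    if unmatched:
        raise KeyError(f"detections reference frames without depth maps: {unmatched}")

    rows = []
    obs_id = 0
    for k, det in enumerate(detections):
        if det.confidence < min_confidence:
            continue
        depth = depth_maps[det.frame_id]
        if det.mask is not None:
            dist, n_px = animal_distance_mask(det, depth, min_support=min_support)
        else:
            dist, n_px = animal_distance_bbox(
                det, depth, statistic=statistic, min_support=min_support
            )
        rows.append(
            {
                "observation_id": obs_id,
                "video_id": det.video_id,
                "frame_id": det.frame_id,
                "timestamp": det.timestamp,
                "detection_index": k,
                "label": det.label,
                "confidence": det.confidence,
                "kind": det.kind,
                "distance_m": dist,
                "n_valid_depth_px": n_px,
                "missing": not np.isfinite(dist),
            }
        )
        obs_id += 1
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def load_megadetector_json(
    path: str | Path, image_sizes: dict[str, tuple[int, int]]
) -> list[Detection]:
    """Read detections from MegaDetector-style output JSON.

    Boxes come normalized as ``[x, y, width, height]`` relative to the image
    and are converted to absolute 0-based half-open pixel corners using
    ``image_sizes[frame_id] = (width_px, height_px)``.  The frame id is the
    image file stem.
    """
    payload = json.loads(Path(path).read_text())
    detections: list[Detection] = []
    for image in payload.get("images", []):
        frame_id = Path(image["file"]).stem
        if frame_id not in image_sizes:
            raise KeyError(f"no image size registered for frame {frame_id!r}")
        W, H = image_sizes[frame_id]
        for det in image.get("detections", []):
            x, y, w, h = det["bbox"]
            detections.append(
                Detection(
                    frame_id=frame_id,
                    bbox=(x * W, y * H, (x + w) * W, (y + h) * H),
                    confidence=float(det.get("conf", 1.0)),
                    label=str(det.get("category", "animal")),
                )
            )
    return detections
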