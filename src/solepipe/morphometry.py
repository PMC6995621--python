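"""Metric body measurements from segmented fish silhouettes.

Each fish mask is reduced to its minimum-area rotated rectangle; the long
rectangle side scaled by the calibration gives the body length ("height" in
the top-view reporting convention) and the short side the body width.  The
rotated rectangle — rather than the axis-aligned bounding box — makes the
measurement invariant to the arbitrary orientation of the fish on the tank
bottom (axis-aligned boxes overestimate length by up to sqrt(2)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .calibrate import CalibrationResult
from .detect import Detection

#: Added to each rotated-rectangle side before scaling, compensating the
#: shrinkage of extents measured between pixel *centers* of a rasterized
#: silhouette: a pixel belongs to the mask when its center lies inside the
#: outline, so each boundary falls short by up to half a pixel; the expected
#: total shortfall per dimension is about half a pixel.
BOUNDARY_OFFSET_PX = 0.5

MIN_MASK_PX = 20


class MeasurementSkipped(RuntimeError):
    """The fish was detected but cannot be measured (partial or merged mask)."""


class DegenerateMaskError(ValueError):
    """Mask too small or too thin to carry a rotated rectangle."""


@dataclass(frozen=True)
class FishMeasurement:
    object_id: int
    length_cm: float
    width_cm: float
    bbox: tuple[int, int, int, int]
    orientation_deg: float  # major-axis angle in [0, 180)
    partial: bool = False


def min_area_rect(points: np.ndarray) -> tuple[float, float, float]:
    """Minimum-area enclosing rectangle of a 2-D point set.

    Rotating-calipers over the convex hull: the optimal rectangle has a side
    collinear with a hull edge.  Returns (long side, short side, angle of the
    long side in degrees, in [0, 180)).  Points are (row, col) or (x, y) —
    the side lengths are frame-independent.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegenerateMaskError(f"need >= 3 points in 2-D, got shape {pts.shape}")
    try:
        hull = ConvexHull(pts)
    except QhullError as e:
        raise DegenerateMaskError(f"degenerate point set: {e}") from e
    hp = pts[hull.vertices]
    edges = np.diff(np.vstack([hp, hp[:1]]), axis=0)
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), math.pi / 2))
    best = (math.inf, 0.0, 0.0, 0.0)
    for th in angles:
        c, s = math.cos(th), math.sin(th)
        rot = hp @ np.array([[c, -s], [s, c]])
        ext = rot.max(axis=0) - rot.min(axis=0)
        area = ext[0] * ext[1]
        if area < best[0]:
            best = (area, float(ext[0]), float(ext[1]), th)
    _, e0, e1, th = best
    # angle of the long side in the original frame
    if e0 >= e1:
        long_side, short_side, ang = e0, e1, -th
    else:
        long_side, short_side, ang = e1, e0, math.pi / 2 - th
    return long_side, short_side, math.degrees(ang % math.pi)


def measure_fish(
    fish: Detection,
    calibration: CalibrationResult,
    object_id: int = 0,
    min_mask_px: int = MIN_MASK_PX,
    boundary_offset_px: float = BOUNDARY_OFFSET_PX,
) -> FishMeasurement:
    """Convert one framed fish into metric length and width.

    Raises :class:`MeasurementSkipped` for partial (border-truncated) or
    merged masks — a truncated silhouette cannot yield a valid length — and
    :class:`DegenerateMaskError` for masks below ``min_mask_px`` pixels.
    """
    if fish.cls != "fish":
        raise ValueError(f"expected a fish detection, got class {fish.cls!r}")
    if fish.partial:
        raise MeasurementSkipped("fish mask touches the image border (partial)")
    if fish.merged:
        raise MeasurementSkipped("fish mask flagged as merged objects")
    if fish.area_px < min_mask_px:
        raise DegenerateMaskError(
            f"mask has {fish.area_px} px, below the minimum {min_mask_px}"
        )
    r0, c0, _, _ = fish.bbox
    pts = np.argwhere(fish.mask).astype(np.float64)
    pts[:, 0] += r0
    pts[:, 1] += c0
    long_px, short_px, ang = min_area_rect(pts)
    long_px += boundary_offset_px
    short_px += boundary_offset_px
    scale = calibration.scale_cm_per_px
    return FishMeasurement(
        object_id=object_id,
        length_cm=long_px * scale,
        width_cm=short_px * scale,
        bbox=fish.bbox,
        orientation_deg=ang,
        partial=False,
    )
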