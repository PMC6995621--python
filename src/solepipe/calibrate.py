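"""Metric self-calibration from the in-scene reference circle.

The reference object is a white 3-D printed hemisphere of known diameter
(4.2680 cm by default) which projects to a circle in a top-view photograph.
Counting its pixels fixes the cm-per-pixel scale of the whole image; a single
isotropic scale is assumed (top-down camera, flat tank bottom — the
planarity assumption).  No lens-distortion or water-refraction correction is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .detect import Detection
from .synthscene import REFERENCE_DIAMETER_CM


class CalibrationError(RuntimeError):
    """No usable reference object: the pipeline cannot produce metric sizes."""


@dataclass(frozen=True)
class CalibrationResult:
    scale_cm_per_px: float
    reference_diameter_px: float  # equivalent-area diameter of the mask
    circularity: float
    reference_diameter_cm: float = REFERENCE_DIAMETER_CM
    bbox_diameter_px: float = float("nan")  # diagnostic alternative estimate


def calibrate_from_reference(
    reference: Detection,
    reference_diameter_cm: float = REFERENCE_DIAMETER_CM,
    circularity_min: float = 0.8,
) -> CalibrationResult:
    """Derive the image scale from a detected reference circle.

    The pixel diameter is the equivalent-area diameter 2*sqrt(A/pi) of the
    mask, which is robust to 1-px boundary noise (the bbox-based diameter is
    recorded for diagnostics).  Raises :class:`CalibrationError` when the
    mask is empty or insufficiently circular — an elongated blob mistaken
    for the reference must abort calibration rather than silently skew every
    downstream measurement.
    """
    if reference.cls != "reference":
        raise ValueError(f"expected a reference detection, got class {reference.cls!r}")
    if reference_diameter_cm <= 0:
        raise ValueError("reference_diameter_cm must be positive")
    area = reference.area_px
    if area == 0:
        raise CalibrationError("reference mask is empty")
    if reference.circularity < circularity_min:
        raise CalibrationError(
            f"reference mask circularity {reference.circularity:.3f} below "
            f"{circularity_min}: not a usable circle. Check that the reference "
            "object is fully visible and unoccluded."
        )
    diameter_px = 2.0 * math.sqrt(area / math.pi)
    r0, c0, r1, c1 = reference.bbox
    bbox_diameter_px = (r1 - r0 + c1 - c0) / 2.0
    return CalibrationResult(
        scale_cm_per_px=reference_diameter_cm / diameter_px,
        reference_diameter_px=diameter_px,
        circularity=reference.circularity,
        reference_diameter_cm=reference_diameter_cm,
        bbox_diameter_px=bbox_diameter_px,
    )
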