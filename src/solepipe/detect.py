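"""Scene normalization, object segmentation and detection evaluation.

Stage one of the measurement pipeline resizes the photograph so its smaller
side is exactly 1024 px (aspect preserved).  Stage two finds every fish and
the single circular reference object.  The default backend is classical:
estimate the background level by the image median, threshold the absolute
contrast (Otsu), extract connected components, and classify each component by
shape — near-circular blobs are reference candidates, elongated blobs are
fish.  A learned detector can be plugged in behind the same contract
(``image -> list[Detection]``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from skimage import measure as skmeasure
from skimage import transform as sktransform
from skimage.filters import threshold_otsu

from .synthscene import GroundTruth

logger = logging.getLogger(__name__)

RESIZE_TARGET_PX = 1024


@dataclass(frozen=True)
class Detection:
    """One segmented object: class, tight bbox, mask and shape scores.

    ``circularity`` is 4*pi*A/P^2 (1 for a disc); ``elongation`` is the
    major/minor axis ratio (>= 1).  ``partial`` marks masks touching the
    image border; ``merged`` marks fish blobs exceeding single-fish shape
    bounds (typically two touching fish segmented as one component).
    """

    cls: str  # "fish" | "reference"
    bbox: tuple[int, int, int, int]  # half-open (row0, col0, row1, col1)
    mask: np.ndarray  # boolean, cropped to bbox
    confidence: float
    circularity: float
    elongation: float
    partial: bool = False
    merged: bool = False

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


@dataclass(frozen=True)
class DetectorConfig:
    resize_target_px: int = RESIZE_TARGET_PX
    min_object_area_px: int = 80
    min_contrast: float = 0.05  # floor under the Otsu threshold
    circularity_min: float = 0.82  # at/above -> reference candidate
    elongation_min: float = 1.4  # at/above -> fish
    fish_max_elongation: float = 8.0  # above -> flagged merged
    fish_max_area_px: float | None = None  # above -> flagged merged
    backend: str = "classical"  # "classical" | "plugin"
    plugin: Callable[[np.ndarray], list["Detection"]] | None = None

    def __post_init__(self) -> None:
        if self.resize_target_px <= 0 or self.min_object_area_px < 1:
            raise ValueError("invalid detector config sizes")
        if not (0 < self.circularity_min <= 1.2):
            raise ValueError("circularity_min out of range")
        if self.elongation_min < 1.0:
            raise ValueError("elongation_min must be >= 1")


def resize_to_policy(
    image: np.ndarray, target_px: int = RESIZE_TARGET_PX
) -> tuple[np.ndarray, float]:
    """Rescale so the smaller image side is exactly ``target_px`` pixels.

    Aspect ratio is preserved to within 1 px of rounding; both output sides
    end up >= ``target_px``.  Returns the resized image and the scalar zoom
    factor so pixel counts can be mapped back to the original resolution.
    Color images (H, W, C) are resized per channel.
    """
    img = np.asarray(image)
    if img.ndim not in (2, 3) or img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {img.shape}")
    rows, cols = img.shape[:2]
    short = min(rows, cols)
    factor = target_px / short
    if short == target_px:
        return img, 1.0
    out_shape = (
        target_px if rows == short else int(round(rows * factor)),
        target_px if cols == short else int(round(cols * factor)),
    )
    resized = sktransform.resize(
        img.astype(np.float64),
        out_shape + img.shape[2:],
        order=1,
        anti_aliasing=factor < 1.0,
        preserve_range=True,
    )
    return resized, factor


def _shape_scores(region) -> tuple[float, float]:
    area = region.area
    perim = region.perimeter
    circularity = 4.0 * math.pi * area / perim**2 if perim > 0 else 0.0
    minor = region.axis_minor_length
    major = region.axis_major_length
    elongation = major / minor if minor > 0 else math.inf
    return float(circularity), float(elongation)


def segment_scene(image: np.ndarray, config: DetectorConfig | None = None) -> list[Detection]:
    """Find and classify every object in a (policy-resized) grey image.

    Deterministic for a fixed image and config.  Components smaller than
    ``min_object_area_px`` or matching neither shape rule are dropped (with a
    logged warning for the latter).  At most one reference is returned; among
    circular candidates the highest circularity (then largest area) wins and
    the remainder are re-considered as fish.
    """
    config = config or DetectorConfig()
    if config.backend == "plugin":
        if config.plugin is None:
            raise ValueError("backend='plugin' requires a plugin callable")
        return config.plugin(image)

    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:
        img = img.mean(axis=2)
    background = float(np.median(img))
    deviation = np.abs(img - background)
    try:
        thr = float(threshold_otsu(deviation))
    except ValueError:  # constant image
        return []
    thr = max(thr, config.min_contrast)
    fg = deviation > thr
    if not fg.any():
        return []

    labels = skmeasure.label(fg, connectivity=2)
    shape = img.shape
    candidates: list[Detection] = []
    for region in skmeasure.regionprops(labels):
        if region.area < config.min_object_area_px:
            continue
        r0, c0, r1, c1 = region.bbox
        mask = region.image.copy()
        circ, elong = _shape_scores(region)
        partial = r0 == 0 or c0 == 0 or r1 == shape[0] or c1 == shape[1]
        contrast = float(np.mean(deviation[r0:r1, c0:c1][mask]))
        confidence = float(min(1.0, contrast / (2.0 * thr)))
        candidates.append(
            Detection(
                cls="",  # assigned below
                bbox=(r0, c0, r1, c1),
                mask=mask,
                confidence=confidence,
                circularity=circ,
                elongation=elong,
                partial=partial,
            )
        )

    circular = [d for d in candidates if d.circularity >= config.circularity_min
                and d.elongation < config.elongation_min]
    reference: Detection | None = None
    if circular:
        best = max(circular, key=lambda d: (d.circularity, d.area_px))
        reference = replace(best, cls="reference")

    out: list[Detection] = []
    if reference is not None:
        out.append(reference)
    for d in candidates:
        if reference is not None and d.bbox == reference.bbox:
            continue
        if d.elongation >= config.elongation_min:
            merged = d.elongation > config.fish_max_elongation or (
                config.fish_max_area_px is not None and d.area_px > config.fish_max_area_px
            )
            out.append(replace(d, cls="fish", merged=merged))
        elif d.circularity >= config.circularity_min:
            # a second circular blob: only one reference allowed
            logger.warning(
                "dropping extra circular object at bbox %s (circularity %.3f)",
                d.bbox, d.circularity,
            )
        else:
            logger.warning(
                "dropping ambiguous object at bbox %s (circularity %.3f, elongation %.2f)",
                d.bbox, d.circularity, d.elongation,
            )
    return out


# ---------------------------------------------------------------------------
# Evaluation against ground truth


@dataclass(frozen=True)
class ClassMatchStats:
    n_true: int
    n_detected: int
    n_matched: int

    @property
    def recall(self) -> float:
        return self.n_matched / self.n_true if self.n_true else float("nan")

    @property
    def precision(self) -> float:
        return self.n_matched / self.n_detected if self.n_detected else float("nan")

    @property
    def accuracy(self) -> float:
        """Matched over true — the detection-accuracy convention used here."""
        return self.recall


@dataclass(frozen=True)
class MatchSummary:
    per_class: dict[str, ClassMatchStats]
    iou_min: float

    def __getitem__(self, cls: str) -> ClassMatchStats:
        return self.per_class[cls]


def mask_iou(a_bbox, a_mask, b_bbox, b_mask) -> float:
    """Intersection-over-union of two bbox-cropped masks."""
    r0 = max(a_bbox[0], b_bbox[0])
    c0 = max(a_bbox[1], b_bbox[1])
    r1 = min(a_bbox[2], b_bbox[2])
    c1 = min(a_bbox[3], b_bbox[3])
    area_a = int(a_mask.sum())
    area_b = int(b_mask.sum())
    inter = 0
    if r1 > r0 and c1 > c0:
        sub_a = a_mask[r0 - a_bbox[0] : r1 - a_bbox[0], c0 - a_bbox[1] : c1 - a_bbox[1]]
        sub_b = b_mask[r0 - b_bbox[0] : r1 - b_bbox[0], c0 - b_bbox[1] : c1 - b_bbox[1]]
        inter = int(np.sum(sub_a & sub_b))
    union = area_a + area_b - inter
    return inter / union if union else 0.0


def match_detections(
    detections: Sequence[Detection], truth: GroundTruth, iou_min: float = 0.5
) -> MatchSummary:
    """Greedy one-to-one IoU matching of detections against ground truth.

    Within each class, detections are taken in order of decreasing
    confidence and matched to the unmatched truth object of highest IoU
    (>= ``iou_min``).  Reports per-class recall, precision and accuracy
    (= matched / true, the per-object-recall convention).
    """
    if not (0.0 < iou_min <= 1.0):
        raise ValueError(f"iou_min must be in (0, 1], got {iou_min}")
    per_class: dict[str, ClassMatchStats] = {}
    for cls in ("fish", "reference"):
        true_objs = [o for o in truth.objects if o.cls == cls]
        dets = sorted(
            (d for d in detections if d.cls == cls),
            key=lambda d: -d.confidence,
        )
        taken = [False] * len(true_objs)
        matched = 0
        for d in dets:
            best_j, best_iou = -1, iou_min
            for j, t in enumerate(true_objs):
                if taken[j]:
                    continue
                iou = mask_iou(d.bbox, d.mask, t.bbox, t.mask)
                if iou >= best_iou:
                    best_j, best_iou = j, iou
            if best_j >= 0:
                taken[best_j] = True
                matched += 1
        per_class[cls] = ClassMatchStats(
            n_true=len(true_objs), n_detected=len(dets), n_matched=matched
        )
    return MatchSummary(per_class=per_class, iou_min=iou_min)
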