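"""End-to-end tank processing: image in, annotated image + report out.

Orchestrates the four measurement stages — resize to policy, segment,
self-calibrate from the reference circle, measure and weigh each fish — and
assembles the per-tank report: one row per fish (id, length cm, width cm,
weight g), tank totals, and optionally the stocking density when the tank
floor area is configured.  Fish are numbered top-to-bottom then
left-to-right by bounding-box corner so ids are deterministic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomass import BiomassModel
from .calibrate import CalibrationError, CalibrationResult, calibrate_from_reference
from .detect import Detection, DetectorConfig, resize_to_policy, segment_scene
from .morphometry import DegenerateMaskError, MeasurementSkipped, measure_fish
from .synthscene import REFERENCE_DIAMETER_CM

#: Daily feed ration as a fraction of tank biomass.
FEED_RATION_FRACTION = 0.005

REPORT_COLUMNS = ["fish_id", "length_cm", "width_cm", "weight_g", "partial"]


@dataclass(frozen=True)
class PipelineConfig:
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    reference_diameter_cm: float = REFERENCE_DIAMETER_CM
    reference_circularity_min: float = 0.8
    tank_floor_area_m2: float | None = None
    source_image_id: str = ""

    def __post_init__(self) -> None:
        if self.reference_diameter_cm <= 0:
            raise ValueError("reference_diameter_cm must be positive")
        if self.tank_floor_area_m2 is not None and self.tank_floor_area_m2 <= 0:
            raise ValueError("tank_floor_area_m2 must be positive")


@dataclass(frozen=True)
class ReportRow:
    fish_id: int
    length_cm: float  # NaN for partial fish
    width_cm: float
    weight_g: float
    partial: bool


@dataclass(frozen=True)
class TankReport:
    rows: tuple[ReportRow, ...]
    scale_cm_per_px: float
    source_image_id: str = ""
    tank_floor_area_m2: float | None = None

    @property
    def fish_count(self) -> int:
        return len(self.rows)

    @property
    def measured_count(self) -> int:
        return sum(1 for r in self.rows if not r.partial)

    @property
    def total_biomass_kg(self) -> float:
        return sum(r.weight_g for r in self.rows if not r.partial) / 1000.0

    @property
    def density_kg_per_m2(self) -> float | None:
        if self.tank_floor_area_m2 is None:
            return None
        return self.total_biomass_kg / self.tank_floor_area_m2

    @property
    def ration_kg(self) -> float:
        """Daily feed ration at 0.5% of tank biomass."""
        return FEED_RATION_FRACTION * self.total_biomass_kg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fish_id": [r.fish_id for r in self.rows],
                "length_cm": [r.length_cm for r in self.rows],
                "width_cm": [r.width_cm for r in self.rows],
                "weight_g": [r.weight_g for r in self.rows],
                "partial": [r.partial for r in self.rows],
            }
        )

    def totals(self) -> dict:
        return {
            "fish_count": self.fish_count,
            "measured_count": self.measured_count,
            "total_biomass_kg": self.total_biomass_kg,
            "density_kg_per_m2": self.density_kg_per_m2,
            "ration_kg": self.ration_kg,
            "scale_cm_per_px": self.scale_cm_per_px,
            "tank_floor_area_m2": self.tank_floor_area_m2,
            "source_image_id": self.source_image_id,
        }


def run_pipeline(
    image: np.ndarray,
    config: PipelineConfig,
    model: BiomassModel,
) -> tuple[np.ndarray, TankReport, CalibrationResult]:
    """Process one top-view tank image into an annotated image and a report.

    Raises :class:`CalibrationError` when no reference circle is found (no
    metric scale is recoverable).  Zero fish is a valid empty report.
    Partial (border-truncated) fish are reported as rows with NaN
    measurements and ``partial=True``; merged blobs are excluded entirely.
    """
    resized, _factor = resize_to_policy(
        image, target_px=config.detector.resize_target_px
    )
    detections = segment_scene(resized, config.detector)
    reference = next((d for d in detections if d.cls == "reference"), None)
    if reference is None:
        raise CalibrationError(
            "no reference object detected: cannot calibrate the image scale. "
            "Ensure the reference circle is visible and unoccluded."
        )
    calibration = calibrate_from_reference(
        reference,
        reference_diameter_cm=config.reference_diameter_cm,
        circularity_min=config.reference_circularity_min,
    )

    fish = sorted(
        (d for d in detections if d.cls == "fish" and not d.merged),
        key=lambda d: (d.bbox[0], d.bbox[1]),
    )
    rows: list[ReportRow] = []
    kept: list[tuple[int, Detection]] = []
    next_id = 1
    for det in fish:
        if det.partial:
            rows.append(
                ReportRow(next_id, float("nan"), float("nan"), float("nan"), True)
            )
            kept.append((next_id, det))
            next_id += 1
            continue
        try:
            m = measure_fish(det, calibration, object_id=next_id)
        except (MeasurementSkipped, DegenerateMaskError):
            continue
        weight = float(model.predict(m.length_cm, m.width_cm))
        rows.append(ReportRow(next_id, m.length_cm, m.width_cm, weight, False))
        kept.append((next_id, det))
        next_id += 1

    report = TankReport(
        rows=tuple(rows),
        scale_cm_per_px=calibration.scale_cm_per_px,
        source_image_id=config.source_image_id,
        tank_floor_area_m2=config.tank_floor_area_m2,
    )
    annotated = annotate_image(resized, kept, reference)
    return annotated, report, calibration


def annotate_image(
    image: np.ndarray,
    fish: list[tuple[int, Detection]],
    reference: Detection | None = None,
) -> np.ndarray:
    """Draw fish bounding boxes with their id numbers (and the reference
    box) over the image; returns an RGB uint8 array.  The underlying pixels
    are preserved — only overlay graphics are added."""
    from PIL import Image, ImageDraw

    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        rgb = np.stack([img] * 3, axis=2)
    else:
        rgb = img
    arr = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    pil = Image.fromarray(arr, mode="RGB")
    draw = ImageDraw.Draw(pil)
    for fid, det in fish:
        r0, c0, r1, c1 = det.bbox
        draw.rectangle([c0, r0, c1 - 1, r1 - 1], outline=(255, 40, 40), width=2)
        draw.text((c0 + 3, max(r0 - 14, 0)), str(fid), fill=(255, 40, 40))
    if reference is not None:
        r0, c0, r1, c1 = reference.bbox
        draw.rectangle([c0, r0, c1 - 1, r1 - 1], outline=(40, 120, 255), width=2)
        draw.text((c0 + 3, max(r0 - 14, 0)), "ref", fill=(40, 120, 255))
    return np.asarray(pil)


# ---------------------------------------------------------------------------
# Report I/O


def _fmt(x: float) -> str:
    if isinstance(x, float) and math.isnan(x):
        return ""
    return repr(float(x))


def write_report(report: TankReport, path) -> None:
    """Write the per-fish table as CSV plus a side-car ``*.totals.json``.

    Floats are written with full ``repr`` precision so a read round-trip
    reproduces the report exactly, and identical runs produce byte-identical
    files.
    """
    path = str(path)
    lines = [",".join(REPORT_COLUMNS)]
    for r in report.rows:
        lines.append(
            f"{r.fish_id},{_fmt(r.length_cm)},{_fmt(r.width_cm)},"
            f"{_fmt(r.weight_g)},{str(r.partial).lower()}"
        )
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
    totals = report.totals()
    with open(_totals_path(path), "w") as fh:
        json.dump(totals, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _totals_path(path: str) -> str:
    base = path[:-4] if path.endswith(".csv") else path
    return base + ".totals.json"


def read_report(path) -> TankReport:
    """Read a report written by :func:`write_report` (CSV + totals JSON)."""
    path = str(path)
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header != REPORT_COLUMNS:
            raise ValueError(f"unexpected report header {header}")
        rows = []
        for line in fh:
            line = line.strip()
            if not line:
                continue
            fid, l, w, g, partial = line.split(",")
            rows.append(
                ReportRow(
                    fish_id=int(fid),
                    length_cm=float(l) if l else float("nan"),
                    width_cm=float(w) if w else float("nan"),
                    weight_g=float(g) if g else float("nan"),
                    partial=partial == "true",
                )
            )
    with open(_totals_path(path)) as fh:
        totals = json.load(fh)
    return TankReport(
        rows=tuple(rows),
        scale_cm_per_px=totals["scale_cm_per_px"],
        source_image_id=totals.get("source_image_id", ""),
        tank_floor_area_m2=totals.get("tank_floor_area_m2"),
    )
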