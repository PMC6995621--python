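"""Synthetic benchmark harnesses for the measurement pipeline.

Each benchmark regenerates its scenes from seeds, runs the relevant stages
and reduces the outcome to the headline figure: per-object detection recall,
median relative measurement error, held-out regressor fidelity, and per-tank
total-biomass error.  They are used both by the test suite and by the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .biomass import BiomassModel, fit_biomass_mlp
from .calibrate import calibrate_from_reference
from .detect import DetectorConfig, mask_iou, match_detections, segment_scene
from .morphometry import measure_fish
from .pipeline import PipelineConfig, run_pipeline
from .synthscene import generate_biomass_dataset, render_scene, sample_scene


@dataclass(frozen=True)
class DetectionBenchmark:
    fish_recall_percent: float
    reference_recall_percent: float
    n_scenes: int
    n_fish_true: int


def detection_benchmark(
    seeds: Iterable[int],
    n_fish: int = 5,
    config: DetectorConfig | None = None,
    iou_min: float = 0.5,
) -> DetectionBenchmark:
    """Per-object detection recall over rendered scenes.

    Each seed renders one non-overlapping ``n_fish``-fish scene with a
    reference circle; detections are matched greedily against ground truth
    at the given IoU threshold.
    """
    config = config or DetectorConfig()
    seeds = list(seeds)
    fish_true = fish_matched = ref_true = ref_matched = 0
    for seed in seeds:
        spec = sample_scene(n_fish=n_fish, seed=seed)
        img, truth = render_scene(spec)
        summary = match_detections(segment_scene(img, config), truth, iou_min=iou_min)
        fish_true += summary["fish"].n_true
        fish_matched += summary["fish"].n_matched
        ref_true += summary["reference"].n_true
        ref_matched += summary["reference"].n_matched
    return DetectionBenchmark(
        fish_recall_percent=100.0 * fish_matched / fish_true,
        reference_recall_percent=100.0 * ref_matched / ref_true,
        n_scenes=len(seeds),
        n_fish_true=fish_true,
    )


@dataclass(frozen=True)
class MeasurementBenchmark:
    median_length_error_percent: float
    median_width_error_percent: float
    n_fish: int


def measurement_benchmark(
    seeds: Iterable[int],
    n_fish: int = 5,
    config: DetectorConfig | None = None,
) -> MeasurementBenchmark:
    """Median relative error of length and width over rendered fish.

    Runs the full measurement path — segment, calibrate from the detected
    reference, measure each detected fish — and compares against the
    renderer's exact ground truth (detections matched to truth by best mask
    IoU).  Default scenes put 20-40 cm fish at 0.1 cm/px, i.e. 200-400 px
    body length.
    """
    config = config or DetectorConfig()
    len_errors: list[float] = []
    wid_errors: list[float] = []
    for seed in seeds:
        spec = sample_scene(n_fish=n_fish, seed=seed)
        img, truth = render_scene(spec)
        dets = segment_scene(img, config)
        ref = next((d for d in dets if d.cls == "reference"), None)
        if ref is None:
            continue
        cal = calibrate_from_reference(ref)
        for det in dets:
            if det.cls != "fish" or det.partial or det.merged:
                continue
            best = max(
                truth.fish,
                key=lambda o: mask_iou(det.bbox, det.mask, o.bbox, o.mask),
            )
            m = measure_fish(det, cal)
            len_errors.append(
                abs(m.length_cm - best.true_length_cm) / best.true_length_cm
            )
            wid_errors.append(
                abs(m.width_cm - best.true_width_cm) / best.true_width_cm
            )
    return MeasurementBenchmark(
        median_length_error_percent=100.0 * float(np.median(len_errors)),
        median_width_error_percent=100.0 * float(np.median(wid_errors)),
        n_fish=len(len_errors),
    )


def regressor_benchmark(seed: int = 7, n: int = 400) -> tuple[float, BiomassModel]:
    """Held-out R^2 of the 9-layer regressor on a noise-free table."""
    records = generate_biomass_dataset(n=n, noise_cv=0.0, seed=seed)
    model, report = fit_biomass_mlp(records, seed=seed)
    return report.r2_test, model


@dataclass(frozen=True)
class TankBenchmark:
    max_relative_error: float
    median_relative_error: float
    n_tanks: int


def tank_biomass_benchmark(
    seeds: Iterable[int],
    model: BiomassModel,
    n_fish: int = 5,
) -> TankBenchmark:
    """End-to-end per-tank total-biomass error over rendered tanks."""
    rel_errors: list[float] = []
    for seed in seeds:
        spec = sample_scene(n_fish=n_fish, seed=seed)
        img, truth = render_scene(spec)
        _, report, _ = run_pipeline(img, PipelineConfig(), model)
        true_total = sum(o.true_weight_g for o in truth.fish) / 1000.0
        rel_errors.append(abs(report.total_biomass_kg - true_total) / true_total)
    arr = np.asarray(rel_errors)
    return TankBenchmark(
        max_relative_error=float(arr.max()),
        median_relative_error=float(np.median(arr)),
        n_tanks=len(rel_errors),
    )
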