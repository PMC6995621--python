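"""Render a synthetic tank and run the full measurement pipeline.

Builds a 5-fish scene with a known cm-per-pixel scale, then runs
resize -> segment -> self-calibrate -> measure -> weigh, and compares the
reported tank biomass against the renderer's exact ground truth.
"""

from solepipe import (
    PipelineConfig,
    exact_baseline,
    render_scene,
    run_pipeline,
    sample_scene,
)
from solepipe.synthscene import DEFAULT_ALPHA

spec = sample_scene(n_fish=5, seed=42)
image, truth = render_scene(spec)

# weigh with the exact generating power law so the example isolates
# detection + calibration + measurement error
model = exact_baseline(DEFAULT_ALPHA, 2.0, 1.0)
config = PipelineConfig(tank_floor_area_m2=2.25, source_image_id="example-42")
annotated, report, calibration = run_pipeline(image, config, model)

print(report.to_frame().round(2).to_string(index=False))
print(f"calibration: {calibration.scale_cm_per_px:.5f} cm/px "
      f"(true {spec.scale_true} cm/px)")
true_total = sum(o.true_weight_g for o in truth.fish) / 1000.0
print(f"total biomass: {report.total_biomass_kg:.3f} kg "
      f"(true {true_total:.3f} kg, "
      f"error {100 * abs(report.total_biomass_kg - true_total) / true_total:.2f}%)")
print(f"stocking density: {report.density_kg_per_m2:.3f} kg/m2; "
      f"daily feed ration at 0.5%: {report.ration_kg * 1000:.0f} g")
# Each row is one fish: its id (numbered top-to-bottom in the image), body
# length and width in cm, and estimated weight in g.
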