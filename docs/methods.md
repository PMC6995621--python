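# Methods

## Problem and scope

The package estimates individual and total biomass of benthic flatfish in a
culture tank from one top-view photograph. Flatfish lie flat on the tank
bottom, so a top view exposes each animal's full silhouette; a reference
object of known size in the same plane converts pixel measurements to
centimetres; and an allometric relation converts body dimensions to weight.
The package also provides the cohort-level statistics used to compare
growth between husbandry regimes (e.g. standard-handled vs low-interaction
groups).

Out of scope by design: training a deep detector on real photographs (a
plugin hook is provided instead), video tracking or re-identification of
individuals, lens-distortion or water-refraction correction, and
client/server transport (the pipeline is a library call plus a thin CLI).

## Synthetic scenes

Real tank photographs of this kind are not publicly available, so the test
bed is a parametric renderer with exact ground truth.

* **Fish silhouette.** A tapered ellipse: with normalized major-axis
  coordinate u ∈ [−1, 1] and minor-axis coordinate v, a point is inside
  when |v| ≤ √(1−u²)·f(u), f(u) = 1 − 0.6·taper·max(u, 0) (head at u = −1).
  `taper` ∈ [0, 1] blends from a pure ellipse toward a sole-like outline
  with a narrowed tail. The construction leaves the full length (u = ±1)
  and the maximum width (u = 0) unchanged, so `length_cm`/`width_cm` are
  exact silhouette extents and serve directly as measurement oracles.
  Shape, not texture, is what drives the measurement pipeline, so no
  attempt is made at photorealism.
* **Rasterization.** A pixel belongs to an object iff its center lies
  inside the analytic outline (hard edges, no anti-aliasing). Ground-truth
  masks are recorded before additive Gaussian pixel noise (default
  sd 0.02 on a [0, 1] grey scale) is applied, so they are exact.
* **Default scene.** 1024 × 1280 px at a true scale of 0.1 cm/px — a
  ~1.0 × 1.3 m field of view, consistent with a camera ~1.5 m above a grey
  fiberglass tank. Background grey 0.50, fish grey 0.18–0.32 (dark on
  light), reference 0.95 (white). Fish lengths uniform on 20–40 cm
  (200–400 px), width/length aspect uniform on 0.32–0.45. Non-overlap is
  enforced by rejection sampling with a 4 px separation so connected
  components cannot merge; overlapping scenes can be rendered explicitly
  with `allow_overlap=True` to exercise the merged-blob failure mode.
* **Reference object.** A filled circle of diameter 4.2680 cm / scale
  (42.7 px at the default scale), the projected outline of the white
  printed hemisphere used for calibration.
* **Tank floor area.** The stocking-density denominator is explicit
  configuration (`tank_floor_area_m2`), defaulting to none. The worked
  default used in examples, 2.25 m², is reverse-engineered so that five
  ~0.75 kg adults stock at ~1.67 kg/m²; tank volume alone (1390 L) does
  not determine floor area.
* **Allometric tables.** Weight = α·L^β·Wd^γ·exp(ε) with β = 2, γ = 1 and
  α calibrated so a 35 × 14 cm adult weighs 750 g — plausible flatfish
  scaling in which weight tracks silhouette area × width-linked thickness.
  ε ~ N(0, log(1+cv)); the default cv is 0 (near-deterministic allometry,
  matching the very high estimated-vs-real weight correlations this kind
  of regressor reports). Parameter-recovery tests are agnostic to these
  defaults.
* **Growth cohorts.** Two groups sharing one initial-weight distribution
  (lognormal, mean 0.75 kg, sd 0.35 kg — dispersion chosen to match an
  SEM of ~0.09 kg at n = 15); final weight t1 = t0·(1 + effect + ε),
  ε ~ N(0, 0.04). Default mean relative effects: 2.2% (control) and 11%
  (low-interaction), the before/after ratios of typical group means. The
  relative-noise default 0.04 was fixed by a Monte-Carlo power check
  (1000 seeds) showing the paired t-test at n = 15 rejects the null in
  ~100% of draws at the 11% effect; the test suite re-checks ≥ 95% power
  over 200 seeds. n per group must be divisible by 3 (three tank
  replicates).

What the generator does **not** emulate: water-surface glare and
refraction, shadows, fish texture and fin detail, partial burial in
sediment, and camera distortion. Passing benchmarks therefore demonstrate
the geometric and statistical correctness of the pipeline on clean
silhouettes, not field robustness on real photographs — the detector
backend is explicitly pluggable for that reason.

## Detection

Classical backend: background level = image median (the tank floor
dominates the frame); foreground = |image − median| above the Otsu
threshold (floored at 0.05 contrast so a blank image yields nothing);
8-connected components of at least 80 px. Classification is by shape
alone: circularity ≥ 0.82 and elongation < 1.4 → reference candidate;
elongation ≥ 1.4 → fish; anything else is dropped with a logged warning.
Exactly one reference is kept (highest circularity, then largest area).
Masks touching the image border are flagged `partial` — they are detected
and counted but never measured, since a truncated silhouette has no valid
length. Fish blobs with elongation > 8 (or area above an optional bound)
are flagged `merged` and excluded from measurement as an honest failure
mode for overlapping animals.

Evaluation is per-object greedy IoU matching (detections in decreasing
confidence order, matched at IoU ≥ 0.5); "accuracy" is reported as
matched/true, i.e. per-object recall.

## Calibration and morphometry

Scale = reference diameter (cm) / equivalent-area diameter 2√(A/π) of the
reference mask (px). The equivalent-area estimator is robust to ±1 px
boundary noise; the bbox-based diameter is logged for diagnostics. A
circularity gate (default 0.8) turns a bad reference into a hard
`CalibrationError` rather than a silently wrong scale. One isotropic scale
is assumed for the whole image (planar tank bottom, top-down camera).

Fish dimensions come from the minimum-area rotated rectangle of the mask
(convex hull + rotating calipers): long side × scale = length, short side
× scale = width. **Boundary convention:** extents measured across pixel
centers underestimate the true silhouette extent by up to one pixel
(expected ≈ 0.5 px), so 0.5 px is added to each rectangle side before
scaling. The constant was fixed by a calibration experiment on scenes
generated from seeds disjoint from every benchmark seed family. Measured
on 200 rendered fish at ≥ 200 px body length, median relative errors are
≈ 0.13% (length) and ≈ 0.24% (width).

Measurements are computed on the policy-resized image and are metrically
correct because calibration is computed on the same image; the resize
factor is carried for traceability only. "Height" in the reporting
convention is the top-view body length (major axis); whether a real
protocol includes the caudal fin in "height" is unknowable here — the
synthetic ground truth defines length as the full silhouette major axis.

## Weight regression

* **Baseline.** OLS of log W on [1, log L, log Wd]; exact on noise-free
  power-law data (machine-precision recovery is a test). Rank-deficient
  designs raise `DegenerateFitError`.
* **Network.** Nine layers counted including input and output:
  2 → 64 → 64 → 32 → 32 → 16 → 16 → 8 → 1, ReLU hidden activations,
  linear output. A convolutional architecture is not meaningful for two
  scalar inputs, so the network is fully connected. Training: Adam
  (lr 0.001, β₁ 0.9, β₂ 0.999), batch size 4, MSE on standardized
  log-weight (allometric errors are multiplicative), inputs standardized,
  80/20 train–test split, up to 2000 epochs with early stopping
  (patience 100) on the held-out loss, best-held-out weights kept.
  He-normal initialization. Training is pure NumPy and bit-reproducible
  from its seed; a deep-learning framework can be substituted behind the
  same model contract.
* **Conventions.** R² = 1 − SS_res/SS_tot, with R² ≡ 0 when SS_tot = 0 and
  residuals are nonzero (constant-target degenerate case). Predictions
  more than 25% outside the training input range raise an
  `ExtrapolationWarning`. Models serialize to versioned JSON with
  full-precision floats, so save → load → predict is bit-identical.

On the noise-free 400-record table the held-out R² is ≈ 0.99999 and
network predictions agree with the closed-form baseline within 1%
everywhere on the training range; empirical monotonicity of the network in
each input is checked on a grid with a 2% relative-dip tolerance
(the baseline is monotone analytically).

## Pipeline and report

Stages run in order; no reference → `CalibrationError` abort; zero fish →
valid empty report. Fish ids are assigned by bounding-box top-left corner
(row, then column), so numbering is deterministic without tracking.
Partial fish appear as rows with empty measurements and `partial=true`;
totals sum non-partial rows only. The report is CSV
(`fish_id,length_cm,width_cm,weight_g,partial`) with a side-car
`*.totals.json` (counts, biomass kg, density kg/m² when the floor area is
configured, scale, and the daily feed ration at 0.5% of biomass). Floats
are written with repr precision: write → read round-trips exactly, and
identical runs produce byte-identical files.

## Growth statistics

Paired t: t = mean(d)/(sd(d)/√n), df = n − 1, d = after − before.
Two-sample comparison of increments: Welch by default (the variant is an
explicit flag; pooled agrees with Welch exactly for balanced
equal-variance groups). Two-sided p-values via
P(|T| ≥ t) = I_{df/(df+t²)}(df/2, ½) with I the regularized incomplete
beta function; the suite checks agreement with an independent reference
CDF to 1e-8 and empirical type-I error within [0.03, 0.07] at α = 0.05
under the null. Summaries are mean ± SEM (sd/√n; undefined at n = 1) and
the gainer percentage (strictly positive increments, rounded to two
decimals). Zero-variance differences raise `DegenerateVarianceError`
rather than returning an infinite statistic. No multiple-testing
correction is applied. Increments are reported in both kg and percent of
initial weight.

## Numerical and design choices

* Coordinates are 0-based (row, col) with half-open bboxes throughout.
* Resize policy: output short side exactly 1024 px (bilinear,
  anti-aliased when downscaling); upscaling is applied when the input is
  smaller, per the at-least-1024 rule.
* All generators and the trainer are pure functions of (parameters, seed)
  using `numpy.random.default_rng`.
* Benchmark problem sizes — 50 scenes for detection, 40 scenes / 200 fish
  for measurement, 20 tanks end-to-end, 400 training records — were chosen
  as the package's standard benchmark suite; each completes in seconds to
  tens of seconds on one CPU.

## Known limitations

* Synthetic-only validation: no real photographs are bundled; the
  classical detector's recall on clean renders (100%) is an upper bound on
  field performance.
* Hard-edged rasterization makes segmentation easier than anti-aliased or
  blurred imagery would be; the +0.5 px boundary constant is tied to this
  convention and should be re-calibrated for a different imaging model.
* Overlapping fish are only flagged (merged), not split; density reporting
  requires the operator to supply the tank floor area; no refraction
  correction is applied for a submerged scene.
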