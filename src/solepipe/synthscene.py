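"""Synthetic top-view tank scenes with exact ground truth.

The generators in this module stand in for real tank photographs and fish
records: grey-tank scenes containing sole-shaped elongated silhouettes and a
single white calibration circle of known physical diameter, allometric
morphometry tables (length, width, weight triples), and before/after growth
cohorts.  Every generator is a pure function of its parameters and a seed, so
rendered scenes double as exact oracles for the detection, calibration and
measurement stages.

Conventions: image coordinates are 0-based ``(row, col)``; bounding boxes are
half-open ``(row0, col0, row1, col1)``; grey levels live in ``[0, 1]``;
physical scale is expressed as cm per pixel.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: True diameter of the 3-D printed white hemisphere used as the in-scene
#: reference object.  Seen from above it projects to a circle of this diameter.
REFERENCE_DIAMETER_CM = 4.2680

#: Default allometric coefficients for W = alpha * L^beta * W^gamma (grams,
#: centimetres).  alpha is calibrated so a 35 cm x 14 cm adult sole weighs
#: ~750 g, matching typical adult body weights of ~0.75 kg.
DEFAULT_BETA = 2.0
DEFAULT_GAMMA = 1.0
DEFAULT_ALPHA = 750.0 / (35.0**DEFAULT_BETA * 14.0**DEFAULT_GAMMA)

#: Minimum grey-level contrast a fish must have against the background.
MIN_CONTRAST = 0.05

#: Fraction by which the silhouette half-width shrinks at the tail tip when
#: taper = 1.  Controls how sole-like (asymmetric, tapered) the shape is.
_TAPER_STRENGTH = 0.6


class SceneError(ValueError):
    """Raised when a scene specification cannot be rendered."""


def allometric_weight(
    length_cm: float,
    width_cm: float,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    gamma: float = DEFAULT_GAMMA,
) -> float:
    """Power-law weight (g) from body length and width (cm)."""
    return float(alpha * length_cm**beta * width_cm**gamma)


@dataclass(frozen=True)
class FishSpec:
    """Parametric description of one fish silhouette in a scene.

    ``length_cm`` / ``width_cm`` are the top-view major and minor body axes.
    ``orientation_deg`` is the angle of the major axis in [0, 180), measured
    from the column (x) axis toward the row (y) axis.  ``taper`` in [0, 1]
    blends from a pure ellipse (0) toward a sole-like shape with a tapered
    tail (1); the maximum width and the full length of the silhouette are
    unaffected by taper.  ``weight_g`` defaults to the allometric weight.
    """

    length_cm: float
    width_cm: float
    centroid_px: tuple[float, float]
    orientation_deg: float = 0.0
    intensity: float = 0.25
    taper: float = 0.45
    weight_g: float | None = None

    def __post_init__(self) -> None:
        if not (self.length_cm > self.width_cm > 0):
            raise SceneError(
                f"need length_cm > width_cm > 0, got {self.length_cm}, {self.width_cm}"
            )
        if not (0.0 <= self.taper <= 1.0):
            raise SceneError(f"taper must be in [0, 1], got {self.taper}")
        if not (0.0 <= self.intensity <= 1.0):
            raise SceneError(f"intensity must be in [0, 1], got {self.intensity}")

    @property
    def true_weight_g(self) -> float:
        if self.weight_g is not None:
            return self.weight_g
        return allometric_weight(self.length_cm, self.width_cm)


@dataclass(frozen=True)
class SceneSpec:
    """Full parametric description of a renderable tank scene."""

    image_shape_px: tuple[int, int] = (1024, 1280)
    background_intensity: float = 0.50
    background_noise_sd: float = 0.02
    scale_true: float = 0.1
    reference_diameter_cm: float = REFERENCE_DIAMETER_CM
    reference_center_px: tuple[float, float] | None = None
    reference_intensity: float = 0.95
    fish: tuple[FishSpec, ...] = ()
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_true <= 0:
            raise SceneError(f"scale_true must be > 0, got {self.scale_true}")
        if self.reference_diameter_cm <= 0:
            raise SceneError("reference_diameter_cm must be > 0")
        for f in self.fish:
            if abs(f.intensity - self.background_intensity) < MIN_CONTRAST:
                raise SceneError(
                    f"fish intensity {f.intensity} too close to background "
                    f"{self.background_intensity} (min contrast {MIN_CONTRAST})"
                )
        object.__setattr__(self, "fish", tuple(self.fish))

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["fish"] = [dataclasses.asdict(f) for f in self.fish]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SceneSpec":
        d = json.loads(text)
        d["fish"] = tuple(
            FishSpec(**{**f, "centroid_px": tuple(f["centroid_px"])}) for f in d["fish"]
        )
        d["image_shape_px"] = tuple(d["image_shape_px"])
        if d.get("reference_center_px") is not None:
            d["reference_center_px"] = tuple(d["reference_center_px"])
        return cls(**d)


@dataclass(frozen=True)
class ObjectTruth:
    """Exact annotation of one rendered object."""

    cls: str  # "fish" | "reference"
    bbox: tuple[int, int, int, int]  # half-open (row0, col0, row1, col1)
    mask: np.ndarray  # boolean, cropped to bbox
    true_length_cm: float
    true_width_cm: float
    true_weight_g: float | None = None  # fish only

    def full_mask(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out


@dataclass(frozen=True)
class GroundTruth:
    """Scene-level annotations: every object plus the true metric scale."""

    objects: tuple[ObjectTruth, ...]
    scale_true: float
    image_shape_px: tuple[int, int]

    @property
    def fish(self) -> tuple[ObjectTruth, ...]:
        return tuple(o for o in self.objects if o.cls == "fish")

    @property
    def reference(self) -> ObjectTruth | None:
        for o in self.objects:
            if o.cls == "reference":
                return o
        return None


def _fish_mask(spec: FishSpec, shape: tuple[int, int], scale: float):
    """Rasterize one fish silhouette; returns (bbox, cropped mask).

    The silhouette is a tapered ellipse: a point with normalized major-axis
    coordinate u in [-1, 1] and minor-axis coordinate v is inside when
    |v| <= sqrt(1 - u^2) * f(u), with f(u) = 1 - taper * s * max(u, 0)
    (head at u = -1, tail at u = +1).  The maximum half-width (at u = 0) and
    the total length (u = +-1) are independent of taper, so length_cm and
    width_cm are exact silhouette extents.
    """
    a = spec.length_cm / (2.0 * scale)  # major half axis, px
    b = spec.width_cm / (2.0 * scale)
    cr, cc = spec.centroid_px
    th = math.radians(spec.orientation_deg)
    ct, st = math.cos(th), math.sin(th)

    pad = a + 2.0
    r0 = max(int(math.floor(cr - pad)), 0)
    c0 = max(int(math.floor(cc - pad)), 0)
    r1 = min(int(math.ceil(cr + pad)) + 1, shape[0])
    c1 = min(int(math.ceil(cc + pad)) + 1, shape[1])
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    dy = rr - cr
    dx = cc_grid - cc
    # major axis direction: (cos th) along cols, (sin th) along rows
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    f = 1.0 - _TAPER_STRENGTH * spec.taper * np.clip(u, 0.0, None)
    with np.errstate(invalid="ignore"):
        inside = (np.abs(u) <= 1.0) & (np.abs(v) <= np.sqrt(np.clip(1 - u**2, 0, None)) * f)
    return _tighten(inside, r0, c0)


def _circle_mask(center: tuple[float, float], radius_px: float, shape):
    cr, cc = center
    r0 = max(int(math.floor(cr - radius_px)) - 1, 0)
    c0 = max(int(math.floor(cc - radius_px)) - 1, 0)
    r1 = min(int(math.ceil(cr + radius_px)) + 2, shape[0])
    c1 = min(int(math.ceil(cc + radius_px)) + 2, shape[1])
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    inside = (rr - cr) ** 2 + (cc_grid - cc) ** 2 <= radius_px**2
    return _tighten(inside, r0, c0)


def _tighten(patch: np.ndarray, r0: int, c0: int):
    """Crop a boolean patch to its tight bbox in image coordinates."""
    rows = np.any(patch, axis=1)
    cols = np.any(patch, axis=0)
    if not rows.any():
        raise SceneError("object rasterized to an empty mask")
    ra, rb = np.where(rows)[0][[0, -1]]
    ca, cb = np.where(cols)[0][[0, -1]]
    bbox = (r0 + int(ra), c0 + int(ca), r0 + int(rb) + 1, c0 + int(cb) + 1)
    return bbox, patch[ra : rb + 1, ca : cb + 1]


def _touches_border(bbox, shape) -> bool:
    r0, c0, r1, c1 = bbox
    return r0 == 0 or c0 == 0 or r1 == shape[0] or c1 == shape[1]


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to a float grey image in [0, 1] plus exact ground truth.

    Objects are rasterized as hard-edged silhouettes (a pixel belongs to an
    object iff its center lies inside the analytic outline); additive Gaussian
    noise is applied after the masks are recorded, so the ground-truth masks
    are exact.  Raises :class:`SceneError` for out-of-frame objects and, when
    ``allow_overlap`` is false, for any pairwise mask overlap (or contact
    within 8-connectivity, which would merge components downstream).
    """
    shape = spec.image_shape_px
    if shape[0] <= 0 or shape[1] <= 0:
        raise SceneError(f"empty image shape {shape}")
    img = np.full(shape, spec.background_intensity, dtype=np.float64)

    objects: list[ObjectTruth] = []
    occupancy = np.zeros(shape, dtype=bool)

    ref_center = spec.reference_center_px
    if ref_center is None:
        ref_center = (shape[0] * 0.5, shape[1] * 0.5)
    ref_radius = spec.reference_diameter_cm / spec.scale_true / 2.0
    bbox, mask = _circle_mask(ref_center, ref_radius, shape)
    if _touches_border(bbox, shape) and _mask_clipped(ref_center, ref_radius, shape):
        raise SceneError("reference circle extends outside the image")
    _paint(img, occupancy, bbox, mask, spec.reference_intensity, spec.allow_overlap, "reference")
    objects.append(
        ObjectTruth(
            cls="reference",
            bbox=bbox,
            mask=mask,
            true_length_cm=spec.reference_diameter_cm,
            true_width_cm=spec.reference_diameter_cm,
        )
    )

    for i, f in enumerate(spec.fish):
        a_px = f.length_cm / (2.0 * spec.scale_true)
        cr, cc = f.centroid_px
        if not (0 <= cr < shape[0] and 0 <= cc < shape[1]):
            raise SceneError(f"fish {i} centroid {f.centroid_px} outside the image")
        bbox, mask = _fish_mask(f, shape, spec.scale_true)
        if _touches_border(bbox, shape) and (
            cr - a_px < -0.5 or cc - a_px < -0.5
            or cr + a_px > shape[0] - 0.5 or cc + a_px > shape[1] - 0.5
        ):
            raise SceneError(f"fish {i} extends outside the image")
        _paint(img, occupancy, bbox, mask, f.intensity, spec.allow_overlap, f"fish {i}")
        objects.append(
            ObjectTruth(
                cls="fish",
                bbox=bbox,
                mask=mask,
                true_length_cm=f.length_cm,
                true_width_cm=f.width_cm,
                true_weight_g=f.true_weight_g,
            )
        )

    rng = np.random.default_rng(spec.seed)
    if spec.background_noise_sd > 0:
        img = img + rng.normal(0.0, spec.background_noise_sd, size=shape)
    img = np.clip(img, 0.0, 1.0)
    truth = GroundTruth(objects=tuple(objects), scale_true=spec.scale_true, image_shape_px=shape)
    return img, truth


def _mask_clipped(center, radius, shape) -> bool:
    cr, cc = center
    return (
        cr - radius < -0.5 or cc - radius < -0.5
        or cr + radius > shape[0] - 0.5 or cc + radius > shape[1] - 0.5
    )


def _paint(img, occupancy, bbox, mask, intensity, allow_overlap, label):
    r0, c0, r1, c1 = bbox
    region = occupancy[r0:r1, c0:c1]
    if not allow_overlap and np.any(region & mask):
        raise SceneError(f"{label} overlaps a previously placed object")
    img[r0:r1, c0:c1][mask] = intensity
    region |= mask


# ---------------------------------------------------------------------------
# Random scene sampling


def sample_scene(
    n_fish: int = 5,
    seed: int = 0,
    image_shape_px: tuple[int, int] = (1024, 1280),
    scale_true: float = 0.1,
    length_range_cm: tuple[float, float] = (20.0, 40.0),
    aspect_range: tuple[float, float] = (0.32, 0.45),
    background_intensity: float = 0.50,
    background_noise_sd: float = 0.02,
    fish_intensity_range: tuple[float, float] = (0.18, 0.32),
    taper_range: tuple[float, float] = (0.3, 0.6),
    min_separation_px: int = 4,
    max_tries: int = 2000,
) -> SceneSpec:
    """Draw a random non-overlapping scene spec, reproducible from ``seed``.

    Fish lengths are uniform on ``length_range_cm`` and widths follow a
    uniform aspect ratio; positions and orientations are rejection-sampled so
    that object masks (dilated by ``min_separation_px``) stay disjoint and
    fully inside the frame.  The reference circle is placed first.
    """
    rng = np.random.default_rng(seed)
    shape = image_shape_px
    occupancy = np.zeros(shape, dtype=bool)

    ref_radius = REFERENCE_DIAMETER_CM / scale_true / 2.0
    margin = ref_radius + min_separation_px + 2
    ref_center = (
        float(rng.uniform(margin, shape[0] - margin)),
        float(rng.uniform(margin, shape[1] - margin)),
    )
    bbox, mask = _circle_mask(ref_center, ref_radius, shape)
    _occupy(occupancy, bbox, mask, min_separation_px)

    fish: list[FishSpec] = []
    for _ in range(n_fish):
        placed = False
        for _try in range(max_tries):
            length = float(rng.uniform(*length_range_cm))
            width = length * float(rng.uniform(*aspect_range))
            a_px = length / (2.0 * scale_true)
            m = a_px + min_separation_px + 2
            if 2 * m >= min(shape):
                raise SceneError("fish too large for the image at this scale")
            cand = FishSpec(
                length_cm=length,
                width_cm=width,
                centroid_px=(
                    float(rng.uniform(m, shape[0] - m)),
                    float(rng.uniform(m, shape[1] - m)),
                ),
                orientation_deg=float(rng.uniform(0.0, 180.0)),
                intensity=float(rng.uniform(*fish_intensity_range)),
                taper=float(rng.uniform(*taper_range)),
            )
            bbox, mask = _fish_mask(cand, shape, scale_true)
            grown = _grow(mask, min_separation_px)
            r0, c0, r1, c1 = bbox
            g0, g1 = min_separation_px, min_separation_px
            rr0, cc0 = max(r0 - g0, 0), max(c0 - g0, 0)
            rr1, cc1 = min(r1 + g1, shape[0]), min(c1 + g1, shape[1])
            sub = grown[
                g0 - (r0 - rr0) : g0 + (rr1 - r0), g1 - (c0 - cc0) : g1 + (cc1 - c0)
            ]
            if not np.any(occupancy[rr0:rr1, cc0:cc1] & sub):
                _occupy(occupancy, bbox, mask, min_separation_px)
                fish.append(cand)
                placed = True
                break
        if not placed:
            raise SceneError(
                f"could not place {n_fish} non-overlapping fish in {max_tries} tries"
            )

    return SceneSpec(
        image_shape_px=shape,
        background_intensity=background_intensity,
        background_noise_sd=background_noise_sd,
        scale_true=scale_true,
        reference_center_px=ref_center,
        fish=tuple(fish),
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def _grow(mask: np.ndarray, pad: int) -> np.ndarray:
    """Binary dilation of a cropped mask by a square structuring element,
    returned on a canvas padded by ``pad`` on every side."""
    from scipy.ndimage import binary_dilation

    canvas = np.pad(mask, pad)
    if pad > 0:
        canvas = binary_dilation(canvas, iterations=pad)
    return canvas


def _occupy(occupancy, bbox, mask, pad):
    shape = occupancy.shape
    grown = _grow(mask, pad)
    r0, c0, r1, c1 = bbox
    rr0, cc0 = max(r0 - pad, 0), max(c0 - pad, 0)
    rr1, cc1 = min(r1 + pad, shape[0]), min(c1 + pad, shape[1])
    sub = grown[pad - (r0 - rr0) : pad + (rr1 - r0), pad - (c0 - cc0) : pad + (cc1 - c0)]
    occupancy[rr0:rr1, cc0:cc1] |= sub


# ---------------------------------------------------------------------------
# Allometric morphometry tables


@dataclass(frozen=True)
class BiomassRecord:
    length_cm: float
    width_cm: float
    weight_g: float

    def __post_init__(self) -> None:
        if min(self.length_cm, self.width_cm, self.weight_g) <= 0:
            raise ValueError("BiomassRecord fields must be strictly positive")


def generate_biomass_dataset(
    n: int = 400,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    gamma: float = DEFAULT_GAMMA,
    noise_cv: float = 0.0,
    seed: int = 0,
    length_range_cm: tuple[float, float] = (20.0, 40.0),
    aspect_range: tuple[float, float] = (0.32, 0.45),
) -> list[BiomassRecord]:
    """Sample (length, width, weight) morphometry records.

    Lengths are uniform on ``length_range_cm``; width = length x uniform
    aspect ratio; weight follows the power law W = alpha L^beta W^gamma with
    multiplicative lognormal noise, ``log W`` jittered by
    ``Normal(0, log(1 + noise_cv))``.  With ``noise_cv = 0`` the records lie
    exactly on the power-law surface.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if noise_cv < 0:
        raise ValueError(f"noise_cv must be >= 0, got {noise_cv}")
    rng = np.random.default_rng(seed)
    lengths = rng.uniform(*length_range_cm, size=n)
    widths = lengths * rng.uniform(*aspect_range, size=n)
    eps = rng.normal(0.0, math.log1p(noise_cv), size=n) if noise_cv > 0 else np.zeros(n)
    weights = alpha * lengths**beta * widths**gamma * np.exp(eps)
    return [
        BiomassRecord(float(l), float(w), float(g))
        for l, w, g in zip(lengths, widths, weights)
    ]


def biomass_records_to_frame(records: list[BiomassRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "length_cm": [r.length_cm for r in records],
            "width_cm": [r.width_cm for r in records],
            "weight_g": [r.weight_g for r in records],
        }
    )


def biomass_records_from_frame(df: pd.DataFrame) -> list[BiomassRecord]:
    return [
        BiomassRecord(float(r.length_cm), float(r.width_cm), float(r.weight_g))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Growth cohorts


@dataclass(frozen=True)
class CohortRecord:
    fish_id: str
    group: str  # "CTRL" | "EXP"
    replicate: int
    sex: str  # "M" | "F" | "unknown"
    weight_t0_kg: float
    weight_t1_kg: float

    def __post_init__(self) -> None:
        if self.weight_t0_kg <= 0 or self.weight_t1_kg <= 0:
            raise ValueError("cohort weights must be positive")


def generate_growth_cohort(
    n_per_group: int = 15,
    mean_t0_kg: float = 0.75,
    sd_t0_kg: float = 0.35,
    growth_effect_ctrl: float = 0.022,
    growth_effect_exp: float = 0.11,
    noise_sd: float = 0.04,
    seed: int = 0,
) -> list[CohortRecord]:
    """Sample a two-group before/after weight cohort.

    Both groups share the same initial-weight distribution (lognormal with
    the requested mean and sd); final weight is
    ``t1 = t0 * (1 + effect + Normal(0, noise_sd))``, with a group-specific
    mean relative effect.  Fish are split into three equal tank replicates
    per group, mirroring a 3-replicates-of-5 design at the default n = 15.
    """
    if n_per_group % 3 != 0:
        raise ValueError("n_per_group must be divisible by 3 (three tank replicates)")
    if mean_t0_kg <= 0:
        raise ValueError("mean_t0_kg must be positive")
    if sd_t0_kg < 0 or noise_sd < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    per_rep = n_per_group // 3
    for group, effect in (("CTRL", growth_effect_ctrl), ("EXP", growth_effect_exp)):
        # lognormal parametrized by desired arithmetic mean/sd
        if sd_t0_kg > 0:
            s2 = math.log1p((sd_t0_kg / mean_t0_kg) ** 2)
            mu = math.log(mean_t0_kg) - s2 / 2.0
            t0 = rng.lognormal(mu, math.sqrt(s2), size=n_per_group)
        else:
            t0 = np.full(n_per_group, mean_t0_kg)
        mult = np.full(n_per_group, 1.0 + effect) + (
            rng.normal(0.0, noise_sd, size=n_per_group) if noise_sd > 0 else 0.0
        )
        mult = np.clip(mult, 0.05, None)  # weights stay positive
        sexes = rng.choice(["M", "F"], size=n_per_group)
        for i in range(n_per_group):
            records.append(
                CohortRecord(
                    fish_id=f"{group}-{i + 1:02d}",
                    group=group,
                    replicate=i // per_rep + 1,
                    sex=str(sexes[i]),
                    weight_t0_kg=float(t0[i]),
                    weight_t1_kg=float(t0[i] * mult[i]),
                )
            )
    return records


def cohort_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])[
        ["fish_id", "group", "replicate", "sex", "weight_t0_kg", "weight_t1_kg"]
    ]


def cohort_from_frame(df: pd.DataFrame) -> list[CohortRecord]:
    return [
        CohortRecord(
            str(r.fish_id), str(r.group), int(r.replicate), str(r.sex),
            float(r.weight_t0_kg), float(r.weight_t1_kg),
        )
        for r in df.itertuples()
    ]


def save_image_png(img: np.ndarray, path) -> None:
    """Write a float grey image in [0, 1] as 8-bit greyscale PNG."""
    from PIL import Image

    arr = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_image(path) -> np.ndarray:
    """Read an image file as float grey in [0, 1] (RGB is averaged)."""
    from PIL import Image

    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
    return arr / 255.0
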