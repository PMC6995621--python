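import math

import numpy as np
import pytest

from solepipe.biomass import fit_allometric_baseline
from solepipe.synthscene import (
    DEFAULT_ALPHA,
    FishSpec,
    SceneSpec,
    SceneError,
    generate_biomass_dataset,
    generate_growth_cohort,
    render_scene,
    sample_scene,
)


class TestRenderScene:
    def test_reference_only_scene_has_one_circle_of_expected_diameter(self):
        spec = SceneSpec(
            image_shape_px=(512, 512),
            scale_true=0.05,
            reference_center_px=(256.0, 256.0),
            fish=(),
            seed=1,
        )
        img, truth = render_scene(spec)
        assert img.shape == (512, 512)
        assert len(truth.objects) == 1
        ref = truth.objects[0]
        assert ref.cls == "reference"
        # 4.2680 cm / 0.05 cm/px = 85.36 px across
        r0, c0, r1, c1 = ref.bbox
        assert r1 - r0 == pytest.approx(85.36, abs=1.5)
        assert c1 - c0 == pytest.approx(85.36, abs=1.5)
        eq_diam = 2 * math.sqrt(ref.mask.sum() / math.pi)
        assert eq_diam == pytest.approx(85.36, rel=0.01)

    def test_five_fish_scene_has_six_disjoint_objects(self, scene42):
        _, img, truth = scene42
        assert len(truth.objects) == 6
        total = np.zeros(truth.image_shape_px, dtype=int)
        for o in truth.objects:
            total += o.full_mask(truth.image_shape_px)
        assert total.max() == 1  # pairwise disjoint

    def test_rendering_is_deterministic(self):
        spec = sample_scene(n_fish=3, seed=9)
        img1, _ = render_scene(spec)
        img2, _ = render_scene(spec)
        np.testing.assert_array_equal(img1, img2)

    def test_bbox_is_tight_around_mask(self, scene42):
        _, _, truth = scene42
        for o in truth.objects:
            # first/last rows and cols of the cropped mask must be occupied
            assert o.mask[0, :].any() and o.mask[-1, :].any()
            assert o.mask[:, 0].any() and o.mask[:, -1].any()

    def test_mask_extent_matches_true_dimensions_within_discretization(self, scene42):
        spec, _, truth = scene42
        for o in truth.fish:
            # the mask diagonal extent bounds the true length
            npx = max(o.bbox[2] - o.bbox[0], o.bbox[3] - o.bbox[1])
            diag = math.hypot(o.bbox[2] - o.bbox[0], o.bbox[3] - o.bbox[1])
            assert npx * spec.scale_true <= o.true_length_cm + 2 * spec.scale_true
            assert diag * spec.scale_true >= o.true_length_cm - 2 * spec.scale_true

    def test_out_of_frame_fish_rejected(self):
        fish = FishSpec(30.0, 12.0, centroid_px=(20.0, 200.0))
        spec_kwargs = dict(image_shape_px=(400, 400), scale_true=0.1,
                           reference_center_px=(300.0, 300.0), seed=0)
        with pytest.raises(SceneError, match="outside"):
            render_scene(SceneSpec(fish=(fish,), **spec_kwargs))

    def test_overlapping_fish_rejected_unless_allowed(self):
        f1 = FishSpec(30.0, 12.0, centroid_px=(300.0, 300.0))
        f2 = FishSpec(28.0, 11.0, centroid_px=(310.0, 310.0))
        kwargs = dict(image_shape_px=(700, 700), scale_true=0.1,
                      reference_center_px=(80.0, 80.0), seed=0)
        with pytest.raises(SceneError, match="overlap"):
            render_scene(SceneSpec(fish=(f1, f2), **kwargs))
        img, truth = render_scene(SceneSpec(fish=(f1, f2), allow_overlap=True, **kwargs))
        assert len(truth.objects) == 3

    def test_fish_spec_invariants_enforced(self):
        with pytest.raises(SceneError):
            FishSpec(length_cm=10.0, width_cm=12.0, centroid_px=(0, 0))
        with pytest.raises(SceneError):
            FishSpec(length_cm=10.0, width_cm=4.0, centroid_px=(0, 0), taper=1.5)

    def test_scene_spec_json_round_trip(self):
        spec = sample_scene(n_fish=2, seed=5)
        again = SceneSpec.from_json(spec.to_json())
        assert again == spec


class TestBiomassDataset:
    def test_noise_free_weights_follow_power_law_exactly(self):
        recs = generate_biomass_dataset(n=50, alpha=0.01, beta=2, gamma=1,
                                        noise_cv=0.0, seed=3)
        for r in recs:
            assert r.weight_g == pytest.approx(0.01 * r.length_cm**2 * r.width_cm, rel=1e-12)

    def test_hand_computed_power_law_values(self):
        # 0.01 * 10^2 * 4 = 4 g ; 0.01 * 20^2 * 8 = 32 g
        assert 0.01 * 10**2 * 4 == pytest.approx(4.0)
        recs = generate_biomass_dataset(n=2, alpha=0.01, beta=2, gamma=1, noise_cv=0,
                                        seed=0, length_range_cm=(20.0, 20.0),
                                        aspect_range=(0.4, 0.4))
        assert all(r.weight_g == pytest.approx(32.0, rel=1e-12) for r in recs)

    def test_log_log_fit_recovers_parameters_to_machine_precision(self):
        recs = generate_biomass_dataset(n=400, alpha=0.01, beta=2.0, gamma=1.0,
                                        noise_cv=0.0, seed=11)
        log_alpha, beta, gamma = fit_allometric_baseline(recs)
        assert log_alpha == pytest.approx(math.log(0.01), abs=1e-10)
        assert beta == pytest.approx(2.0, abs=1e-10)
        assert gamma == pytest.approx(1.0, abs=1e-10)

    def test_determinism_and_rejections(self):
        a = generate_biomass_dataset(n=10, seed=4)
        b = generate_biomass_dataset(n=10, seed=4)
        assert a == b
        with pytest.raises(ValueError):
            generate_biomass_dataset(n=1)
        with pytest.raises(ValueError):
            generate_biomass_dataset(n=10, alpha=-1.0)
        with pytest.raises(ValueError):
            generate_biomass_dataset(n=10, noise_cv=-0.1)

    def test_default_alpha_calibration_750g_adult(self):
        # a 35 cm x 14 cm adult sole weighs 750 g under the default power law
        assert DEFAULT_ALPHA * 35.0**2 * 14.0 == pytest.approx(750.0)


class TestGrowthCohort:
    def test_shape_and_replicate_structure(self):
        recs = generate_growth_cohort(n_per_group=15, seed=0)
        assert len(recs) == 30
        for group in ("CTRL", "EXP"):
            sub = [r for r in recs if r.group == group]
            assert len(sub) == 15
            for rep in (1, 2, 3):
                assert sum(1 for r in sub if r.replicate == rep) == 5

    def test_zero_effect_zero_noise_is_identity(self):
        recs = generate_growth_cohort(n_per_group=6, growth_effect_ctrl=0.0,
                                      growth_effect_exp=0.0, noise_sd=0.0, seed=2)
        assert all(r.weight_t1_kg == pytest.approx(r.weight_t0_kg, rel=1e-12) for r in recs)

    def test_determinism_and_rejections(self):
        assert generate_growth_cohort(seed=8) == generate_growth_cohort(seed=8)
        with pytest.raises(ValueError):
            generate_growth_cohort(n_per_group=7)
        with pytest.raises(ValueError):
            generate_growth_cohort(mean_t0_kg=-0.5)
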