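import math
import warnings

import numpy as np
import pytest

from solepipe.biomass import (
    BiomassModel,
    DegenerateFitError,
    ExtrapolationWarning,
    MLPConfig,
    baseline_model,
    evaluate_r2,
    exact_baseline,
    fit_allometric_baseline,
    fit_biomass_mlp,
    predict_weight,
)
from solepipe.synthscene import BiomassRecord, generate_biomass_dataset


@pytest.fixture(scope="module")
def small_fit():
    """A quick MLP fit (60 records, few epochs) for contract tests."""
    recs = generate_biomass_dataset(n=60, noise_cv=0.0, seed=5)
    cfg = MLPConfig(epochs=150, patience=0)
    return recs, cfg, fit_biomass_mlp(recs, cfg, seed=5)


class TestAllometricBaseline:
    def test_exact_recovery_on_noise_free_data(self):
        recs = generate_biomass_dataset(n=400, alpha=0.01, beta=2, gamma=1,
                                        noise_cv=0.0, seed=7)
        la, be, ga = fit_allometric_baseline(recs)
        assert la == pytest.approx(math.log(0.01), abs=1e-10)
        assert be == pytest.approx(2.0, abs=1e-10)
        assert ga == pytest.approx(1.0, abs=1e-10)

    def test_identical_dimensions_rejected(self):
        recs = [BiomassRecord(20.0, 8.0, 30.0)] * 10
        with pytest.raises(DegenerateFitError):
            fit_allometric_baseline(recs)

    def test_beta_recovered_within_three_se_under_noise(self):
        # OLS sampling theory: se(beta) from the noisy log-log fit
        recs = generate_biomass_dataset(n=400, alpha=0.01, beta=2, gamma=1,
                                        noise_cv=0.05, seed=21)
        _, be, _ = fit_allometric_baseline(recs)
        X = np.column_stack([
            np.ones(len(recs)),
            np.log([r.length_cm for r in recs]),
            np.log([r.width_cm for r in recs]),
        ])
        y = np.log([r.weight_g for r in recs])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        s2 = resid @ resid / (len(recs) - 3)
        se_beta = math.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(be - 2.0) < 3 * se_beta

    def test_baseline_prediction_is_power_law(self):
        model = exact_baseline(alpha=0.01, beta=2.0, gamma=1.0)
        assert predict_weight(model, 20.0, 8.0) == pytest.approx(32.0, rel=1e-12)

    def test_baseline_monotone_in_length_and_width(self):
        model = exact_baseline(alpha=0.01, beta=2.0, gamma=1.0)
        grid = np.linspace(10, 40, 20)
        w_len = model.predict(grid, np.full_like(grid, 10.0))
        w_wid = model.predict(np.full_like(grid, 30.0), np.clip(grid, 4, 16))
        assert np.all(np.diff(w_len) > 0)
        assert np.all(np.diff(model.predict(np.full_like(grid, 30.0),
                                            np.linspace(4, 16, 20))) > 0)

    def test_negative_inputs_rejected(self):
        model = exact_baseline(0.01, 2, 1)
        with pytest.raises(ValueError):
            predict_weight(model, -1.0, 5.0)


class TestEvaluateR2:
    def test_identity_and_constant_and_hand_case(self):
        obs = [1.0, 2.0, 3.0]
        assert evaluate_r2(obs, obs) == pytest.approx(1.0)
        assert evaluate_r2([2.0, 2.0, 2.0], obs) == pytest.approx(0.0)
        assert evaluate_r2([1.0, 2.0, 4.0], obs) == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_r2([1.0, 2.0], [1.0, 2.0, 3.0])


class TestMLP:
    def test_architecture_is_nine_layers(self, small_fit):
        _, _, (model, _) = small_fit
        assert len(model.architecture) == 9
        assert model.architecture[0] == 2 and model.architecture[-1] == 1
        assert len(model.weights) == 8  # 8 weight matrices connect 9 layers

    def test_training_is_deterministic(self):
        recs = generate_biomass_dataset(n=40, noise_cv=0.0, seed=6)
        cfg = MLPConfig(epochs=60, patience=0)
        m1, _ = fit_biomass_mlp(recs, cfg, seed=3)
        m2, _ = fit_biomass_mlp(recs, cfg, seed=3)
        for w1, w2 in zip(m1.weights, m2.weights):
            np.testing.assert_array_equal(w1, w2)
        assert m1.predict(25.0, 10.0) == m2.predict(25.0, 10.0)

    def test_serialization_round_trip_bitwise(self, small_fit):
        _, _, (model, _) = small_fit
        again = BiomassModel.from_json(model.to_json())
        L = np.linspace(21, 39, 11)
        W = np.linspace(8, 15, 11)
        np.testing.assert_array_equal(model.predict(L, W), again.predict(L, W))

    def test_constant_weight_dataset_gives_r2_zero_convention(self):
        recs = generate_biomass_dataset(n=30, noise_cv=0.0, seed=9)
        const = [BiomassRecord(r.length_cm, r.width_cm, 100.0) for r in recs]
        cfg = MLPConfig(epochs=60, patience=0)
        model, report = fit_biomass_mlp(const, cfg, seed=1)
        preds = model.predict(
            np.array([r.length_cm for r in const]),
            np.array([r.width_cm for r in const]),
        )
        assert np.allclose(preds, 100.0, rtol=0.05)
        assert report.r2_test == 0.0  # SS_tot = 0 with nonzero residuals

    def test_nonpositive_weights_rejected(self):
        recs = generate_biomass_dataset(n=30, seed=2)
        bad = recs[:-1] + [BiomassRecord(20.0, 8.0, 1e-12)]
        cfg = MLPConfig(epochs=10)
        # BiomassRecord forbids <= 0, so corrupt after construction
        object.__setattr__(bad[-1], "weight_g", -5.0)
        with pytest.raises(ValueError):
            fit_biomass_mlp(bad, cfg, seed=0)

    def test_extrapolation_warning_outside_training_range(self, small_fit):
        _, _, (model, _) = small_fit
        with pytest.warns(ExtrapolationWarning):
            model.predict(80.0, 30.0)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            model.predict(30.0, 11.0)  # interior point: no warning


class TestMLPFidelity:
    """Deeper checks on the full-size noise-free fit (shared fixture)."""

    def test_heldout_r2_on_noise_free_data(self, mlp400):
        _, report = mlp400
        assert report.r2_test >= 0.9997
        assert report.r2_train <= 1.0

    def test_training_points_predicted_within_one_percent(self, records400, mlp400):
        model, _ = mlp400
        L = np.array([r.length_cm for r in records400])
        W = np.array([r.width_cm for r in records400])
        true = np.array([r.weight_g for r in records400])
        rel = np.abs(model.predict(L, W) - true) / true
        assert rel.max() <= 0.01

    def test_mlp_agrees_with_baseline_within_one_percent(self, records400, mlp400, baseline400):
        model, _ = mlp400
        L = np.array([r.length_cm for r in records400])
        W = np.array([r.width_cm for r in records400])
        pb = baseline400.predict(L, W)
        rel = np.abs(model.predict(L, W) - pb) / pb
        assert rel.max() <= 0.01

    def test_mlp_empirically_monotone_on_grid(self, mlp400):
        # tolerance: no relative dip worse than 2% along either axis
        model, _ = mlp400
        Lg = np.linspace(21, 39, 25)
        Wg = np.linspace(8, 16, 13)
        for w in Wg:
            p = model.predict(Lg, np.full_like(Lg, w))
            assert (np.diff(p) / p[:-1]).min() > -0.02
        for l in Lg[::4]:
            p = model.predict(np.full_like(Wg, l), Wg)
            assert (np.diff(p) / p[:-1]).min() > -0.02
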