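import pytest

from solepipe.biomass import baseline_model, fit_biomass_mlp
from solepipe.synthscene import generate_biomass_dataset, render_scene, sample_scene


@pytest.fixture(scope="session")
def scene42():
    """One rendered 5-fish scene with ground truth (seed 42)."""
    spec = sample_scene(n_fish=5, seed=42)
    img, truth = render_scene(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def records400():
    """Noise-free 400-record allometric table (seed 7)."""
    return generate_biomass_dataset(n=400, noise_cv=0.0, seed=7)


@pytest.fixture(scope="session")
def baseline400(records400):
    return baseline_model(records400)


@pytest.fixture(scope="session")
def mlp400(records400):
    """The 9-layer regressor trained on the noise-free table (seed 7)."""
    return fit_biomass_mlp(records400, seed=7)
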