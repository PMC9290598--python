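import numpy as np
import pytest

from canopymass import ChmConfig, PlotRecord, SceneParams, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_plot():
    """1 m x 1 m plot on flat ground at z = 100 m."""
    corners = [(0, 0, 100.0), (1, 0, 100.0), (1, 1, 100.0), (0, 1, 100.0)]
    return PlotRecord(plot_id="p1", corners=corners, biomass=500.0,
                      species="stipa", pft="graminoid", survey_id="s1")


@pytest.fixture
def default_chm():
    return ChmConfig()


@pytest.fixture(scope="session")
def small_scene():
    """Noise-free constant-sward scene used by several modules."""
    params = SceneParams(
        seed=42, n_plots=6, pft_mix=("graminoid",), point_density=5000,
        vertical_noise_sd=0.0, biomass_cv=0.0, roughness=0.0,
        plot_size=0.5,
    )
    return generate_scene(params)
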