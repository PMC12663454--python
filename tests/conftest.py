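import numpy as np
import pytest

from peroxikit.imaging import QuantConfig
from peroxikit.simulate import ImageSimParams, default_count_params


@pytest.fixture
def count_params():
    return default_count_params()


@pytest.fixture
def clean_image_params():
    """Noise-free yeast-like stack: 4 cells, 5 spots each."""
    return ImageSimParams(
        n_cells=4,
        spots_per_cell=5,
        poisson_noise=False,
        gaussian_noise_sd=0.0,
        seed=11,
    )


@pytest.fixture
def quant_config():
    return QuantConfig(sigma_um=(0.25, 0.11, 0.11), min_separation_um=0.4)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
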