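import numpy as np
import pytest

from dx2quant.image_sim import FieldSpec


@pytest.fixture
def small_spec() -> FieldSpec:
    """A compact field that still places several well-separated cells."""
    return FieldSpec(
        width=256,
        height=256,
        n_cells=4,
        nucleus_radius=(8.0, 12.0),
        mean_red_foci_per_cell=6.0,
        mean_green_foci_per_cell=3.0,
        spot_sigma=1.5,
        noise_sd=3.0,
        seed=42,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
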