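import numpy as np
import pytest

from cytostretch.synthetic_data import FiberFieldSpec, NucleiFieldSpec


@pytest.fixture
def small_fiber_spec():
    """Small, quiet fiber field for fast unit tests."""
    return FiberFieldSpec(
        image_shape_px=(256, 256),
        n_fibers=40,
        noise_sd=0.0,
        background_level=0.0,
        fiber_amplitude=1000.0,
    )


@pytest.fixture
def small_nuclei_spec():
    return NucleiFieldSpec(image_shape_px=(256, 256), n_nuclei=10)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
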