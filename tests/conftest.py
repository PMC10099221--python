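import numpy as np
import pytest

from grainseg import synthetic


@pytest.fixture(scope="session")
def easy_scene():
    """One small rendered scene with a handful of partially adherent kernels."""
    spec = synthetic.sample_scene(
        7, image_size=(128, 128), n_instances=(3, 5), adhesion_level=0.2,
        axis_range=(10.0, 16.0),
    )
    image, anns = synthetic.render_scene(spec)
    return spec, image, anns


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
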