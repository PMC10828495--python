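import numpy as np
import pytest

from ucmp.synth import ImageSpec, gen_psfg_image


@pytest.fixture(scope="session")
def small_psfg():
    """A 256x256 synthetic PSFG image at 20% fibrosis with its truth."""
    return gen_psfg_image(ImageSpec(width=256, height=256,
                                    target_fibrosis_fraction=0.2, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
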