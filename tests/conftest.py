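import numpy as np
import pytest

from medsrnet.config import GeneratorSpec, PhantomSpec
from medsrnet.phantom import generate_phantom


@pytest.fixture(scope="session")
def phantom64():
    return generate_phantom(PhantomSpec(size=64, seed=7))


@pytest.fixture(scope="session")
def phantom128():
    return generate_phantom(PhantomSpec(size=128, seed=3))


@pytest.fixture(scope="session")
def tiny_gen_spec():
    # smallest invariant-preserving widths; cheap enough for CPU tests
    return GeneratorSpec(widths=(4, 8, 16, 32), stem_units=2, stem_width=4,
                         stage_module_counts=(1, 1, 1), blocks_per_module=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
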