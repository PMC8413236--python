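import numpy as np
import pytest

from ppfequant.synthetic.phantom import (PhantomSpec, generate_phantom,
                                         spec_for_coverage)


@pytest.fixture(scope="session")
def clean_phantom():
    """Lesion-free phantom with its ground truth and label grid."""
    spec = PhantomSpec(seed=7)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def phantom25():
    """Phantom with ~25% upper-zone pleural-shell coverage."""
    spec = spec_for_coverage(25.0, seed=11)
    volume, truth = generate_phantom(spec)
    return spec, volume, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
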