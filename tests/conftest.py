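import numpy as np
import pytest

from microloc.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """100-sample, 8-class, 48px dataset shared across pipeline tests."""
    return generate_dataset(
        SyntheticSpec(n_samples=100, n_classes=8, image_size=48, seed=3)
    )


@pytest.fixture(scope="session")
def longtail_labels():
    """Label matrix of a 1000-sample 28-class long-tail dataset."""
    ds = generate_dataset(
        SyntheticSpec(n_samples=1000, n_classes=28, tail_exponent=1.5, seed=7)
    )
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
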