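import numpy as np
import pytest

from patchverify import synthgen


@pytest.fixture(scope="session")
def small_dataset():
    """Compact seeded dataset for classifier-in-the-loop tests.

    14 subjects split 7/7, free per-subject image counts; same accessory
    pool and annotation rule as the default composition.
    """
    spec = synthgen.SyntheticSpec(
        n_subjects=14,
        train_subjects=7,
        train_total_images=None,
        test_total_images=None,
        seed=7,
    )
    return synthgen.generate_dataset(spec)


@pytest.fixture(scope="session")
def full_dataset():
    """Default-composition dataset: 75 subjects, 322 train / 359 test images."""
    return synthgen.generate_dataset(synthgen.SyntheticSpec(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
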