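import numpy as np
import pytest

from kitefusion.phantoms import PhantomSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_spec():
    """32-px phantom spec for fast training/IO tests."""
    return PhantomSpec(image_size=32, lesion_radius=(3.0, 8.0), seed=5)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec, 6, 6, seed=5)


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-resolution cohort kept small for mid-weight tests."""
    return generate_cohort(PhantomSpec(seed=3), 6, 6, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_blob_mask(rng, shape, p=0.15):
    return (rng.random(shape) < p).astype(np.uint8)
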