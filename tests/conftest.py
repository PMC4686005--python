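import numpy as np
import pytest

from voxar.phantom import PhantomSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_spec():
    """A 32-cube phantom specification used by fast pipeline tests."""
    return PhantomSpec(shape=(32, 32, 32))


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """3 conditions x 3 subjects on a 32-cube grid."""
    return generate_cohort(small_spec, {c: 3 for c in small_spec.conditions}, seed=77)
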