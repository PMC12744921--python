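import numpy as np
import pytest

from slabseg import PhantomSpec, generate_cohort, generate_phantom


@pytest.fixture(scope="session")
def tiny_spec():
    return PhantomSpec(grid_shape=(10, 64, 64))


@pytest.fixture(scope="session")
def tiny_case(tiny_spec):
    return generate_phantom(tiny_spec, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(3, tiny_spec, seed=5)
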