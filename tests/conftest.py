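import numpy as np
import pytest

from hippseg.synthetic import SyntheticSpec, generate_dataset, generate_subject


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def subject_sample(default_spec):
    """200 synthetic subjects for distributional checks (seeded)."""
    return generate_dataset(default_spec, 200, seed=1234)


@pytest.fixture(scope="session")
def small_dataset(default_spec):
    """10 synthetic subjects used by sampling/training tests."""
    return generate_dataset(default_spec, 10, seed=42)


@pytest.fixture()
def one_subject(default_spec):
    return generate_subject(default_spec, np.random.default_rng(7))
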