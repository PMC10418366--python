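import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mature_sequence():
    from chi1sno import load_packaged_sequence

    return load_packaged_sequence()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_study():
    """3-residue study set (one responsive) shared across tests."""
    from chi1sno import make_study_set

    return make_study_set(
        n_residues=3, responsive_ids=[271], first_residue=270, base_seed=7
    )
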