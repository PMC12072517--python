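import numpy as np
import pytest

from oxprofile.synthetic import StudyDesign, generate_endpoint_table


@pytest.fixture(scope="session")
def small_design():
    return StudyDesign(n_subjects=15, n_replicates=3, seed=20240901)


@pytest.fixture(scope="session")
def endpoint_table(small_design):
    return generate_endpoint_table(small_design)


@pytest.fixture()
def rng():
    return np.random.default_rng(777)
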