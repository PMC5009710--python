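import numpy as np
import pytest

from hormonet.synthetic_data import load_arabidopsis_fixture


@pytest.fixture(scope="session")
def arabidopsis():
    """The packaged curated fixture bundle (db, annotations, regulation, ppi, evidence)."""
    return load_arabidopsis_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
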