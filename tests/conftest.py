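import numpy as np
import pytest

from fibropath import synthdata


@pytest.fixture(scope="session")
def small_bundle():
    """One coherent synthetic disease scenario at reduced size."""
    return synthdata.generate_bundle(
        n_genes=800,
        n_pathways=20,
        n_planted_pathways=2,
        n_case=8,
        n_control=8,
        n_drugs=40,
        n_failed=6,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
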