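import numpy as np
import pytest

from convergeflow import io as cio
from convergeflow.simulate import DEFAULT_TREE_NEWICK, default_logit_pis


@pytest.fixture
def tree():
    return cio.read_newick(DEFAULT_TREE_NEWICK)


@pytest.fixture
def logit_pis():
    return default_logit_pis()


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)
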