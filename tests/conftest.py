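import numpy as np
import pytest

from varkit.fixtures import make_genome
from varkit.model import Dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def toy_dataset():
    """A small dataset with a 5 kb random reference on one chromosome."""
    return Dataset(reference=make_genome({"chr1": 5_000}, seed=7))
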