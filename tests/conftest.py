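import numpy as np
import pytest

from mpem_interactome import interactome as inter
from mpem_interactome.io import EdgeRecord


@pytest.fixture
def small_interactome():
    """Two seeds, three known partners, two novel partners, one shared."""
    seeds = ["SEED1", "SEED2"]
    known = [
        EdgeRecord.make("SEED1", "KA"),
        EdgeRecord.make("SEED1", "KB"),
        EdgeRecord.make("SEED2", "KC"),
        EdgeRecord.make("SEED1", "SEED2"),
    ]
    predicted = [
        EdgeRecord.make("SEED1", "NA1", provenance="novel", score=0.9),
        EdgeRecord.make("SEED2", "NA1", provenance="novel", score=0.8),
        EdgeRecord.make("SEED2", "NB1", provenance="novel", score=0.7),
    ]
    return inter.assemble(seeds, known, predicted)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
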