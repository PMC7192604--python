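import numpy as np
import pytest

from regdiver import synth
from regdiver.trn import TranscriptionUnit, load_regulatory_network


@pytest.fixture(scope="session")
def small_network():
    """Tiny hand-checkable network: 2 TFs, 4 TGs, 3 TUs."""
    edges = [("tfA", "g1"), ("tfA", "g2"), ("tfA", "g3"), ("tfB", "g4")]
    tus = [
        TranscriptionUnit("tu1", ("g1", "g2")),
        TranscriptionUnit("tu2", ("g3",)),
        TranscriptionUnit("tu3", ("g4",)),
    ]
    return load_regulatory_network(edges, tus)


@pytest.fixture(scope="session")
def cohort_setup():
    """A fixed synthetic network + genome shared by cohort-level tests."""
    net = synth.generate_network(30, 300, alpha=2.5, seed=11)
    genome = synth.generate_genome(net, seed=12)
    return net, genome


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
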