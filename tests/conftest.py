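import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    database=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def seq_factory():
    """Factory for random valid small-RNA sequences."""
    from pirnacnn.seqio import SmallRNASequence

    def make(rng, length, seq_id="s"):
        residues = "".join(rng.choice(list("ACGT"), size=length))
        return SmallRNASequence(seq_id, residues)

    return make
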