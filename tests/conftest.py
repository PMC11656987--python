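import numpy as np
import pytest

from ltrlearn.seqio import LabeledSequence, PWMotif


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_sequences(rng):
    def make(n, length, prefix="s"):
        bases = np.array(list("ACGT"))
        return [
            LabeledSequence(id=f"{prefix}{i}", sequence="".join(rng.choice(bases, size=length)))
            for i in range(n)
        ]

    return make


@pytest.fixture
def sharp_motif():
    """Width-8 near-consensus PWM (ACGTACGT)."""
    m = np.full((4, 8), 0.02)
    for j, b in enumerate("ACGTACGT"):
        m["ACGT".index(b), j] = 0.94
    return PWMotif("sharp", m, kind="probabilities")
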