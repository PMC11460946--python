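import numpy as np
import pytest

from irminer.fixtures import make_pipeline_fixture

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_starts(sequence, pos1="VLIST", pos6="ILV"):
    """Independent window-by-window motif oracle (1-based starts)."""
    starts = []
    for p in range(len(sequence) - 5):
        w = sequence[p : p + 6]
        if w[0] in pos1 and w[2] == "Y" and w[5] in pos6:
            starts.append(p + 1)
    return starts


def random_protein(rng, length, alphabet=AA20):
    return "".join(rng.choice(list(alphabet), size=length))


@pytest.fixture(scope="session")
def pipeline_fixture():
    """The ten-protein end-to-end fixture (one designed failure per stage)."""
    return make_pipeline_fixture(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
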