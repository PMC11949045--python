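import numpy as np
import pandas as pd
import pytest

from apobec_emt import (
    CHANNELS_96,
    SignatureMatrix,
    example_signatures,
    make_reference,
)


@pytest.fixture(scope="session")
def reference_100kb():
    """One 100 kb random contig at 45% GC, shared across tests."""
    return make_reference(100_000, 0.45, 1, seed=7)


@pytest.fixture(scope="session")
def signature_set():
    """The synthetic stand-in reference signature set (5 signatures)."""
    return example_signatures()


@pytest.fixture(scope="session")
def orthogonal_pair():
    """Two toy signatures with disjoint channel support."""
    a = np.zeros(96)
    b = np.zeros(96)
    a[:8] = 1 / 8
    b[40:50] = 1 / 10
    frame = pd.DataFrame({"sigA": a, "sigB": b}, index=list(CHANNELS_96))
    return SignatureMatrix(frame)
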