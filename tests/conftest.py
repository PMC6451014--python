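import numpy as np
import pytest

from seqspace.models import build_dayhoff_model


@pytest.fixture(scope="session")
def dayhoff():
    return build_dayhoff_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
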