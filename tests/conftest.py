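import os

import numpy as np
import pytest

os.environ.setdefault("MPLBACKEND", "Agg")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
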