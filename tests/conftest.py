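import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from wtie import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def phantom_pair():
    """Default seeded 128x128 phantom with additive Gaussian noise sigma=0.1."""
    spec = PhantomSpec(seed=7)
    clean, noisy = make_phantom(spec)
    return spec, clean, noisy
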