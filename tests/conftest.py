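import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # test-local oracle helpers


@pytest.fixture
def rng():
    return np.random.default_rng(20230615)


def random_weather_sequence(rng, n_days=120):
    """Random but physically valid daily weather (t, h, w, p, month)."""
    temps = rng.uniform(-10.0, 35.0, n_days)
    rhs = rng.uniform(5.0, 100.0, n_days)
    winds = rng.uniform(0.0, 60.0, n_days)
    wet = rng.random(n_days) < 0.3
    precs = np.where(wet, rng.gamma(0.8, 6.0, n_days), 0.0)
    months = rng.integers(1, 13, n_days)
    return list(zip(temps, rhs, winds, precs, months))
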