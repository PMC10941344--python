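import numpy as np
import pytest

from hralab import RRISeries


@pytest.fixture
def rng():
    return np.random.default_rng(20240229)


@pytest.fixture
def random_series():
    """Factory: seeded random RR series resembling a resting tachogram."""

    def make(seed: int, n: int = 120, mean: float = 900.0, sd: float = 40.0) -> RRISeries:
        r = np.random.default_rng(seed)
        values = np.clip(r.normal(mean, sd, n), 300.0, 2000.0)
        return RRISeries(values=values)

    return make
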