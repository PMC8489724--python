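import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


class FixedRng:
    """Deterministic stand-in for a Generator: fixed uniform/normal values."""

    def __init__(self, uniform_value=0.5, normal_value=0.0):
        self.uniform_value = uniform_value
        self.normal_value = normal_value

    def uniform(self, lo, hi, size=None):
        val = self.uniform_value
        if not (lo <= val <= hi):
            val = 0.5 * (lo + hi)
        return np.full(size, val) if size is not None else val

    def normal(self, loc, scale, size=None):
        return np.full(size, self.normal_value) if size is not None else self.normal_value

    def random(self, size=None):
        return np.full(size, self.uniform_value) if size is not None else self.uniform_value

    def integers(self, lo, hi=None, size=None):
        return np.zeros(size, dtype=int) if size is not None else 0


@pytest.fixture
def fixed_rng():
    return FixedRng
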