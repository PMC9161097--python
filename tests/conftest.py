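import numpy as np
import pytest

from tdgrn.data import ExpressionTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_data(rng):
    """8 time points x 3 genes of smooth positive random data."""
    t = np.arange(8, dtype=float)
    base = 1.5 + 0.5 * np.sin(t[:, None] * np.array([0.5, 0.8, 1.1]))
    values = base + 0.05 * rng.normal(size=base.shape)
    return ExpressionTimeSeries(("A", "B", "C"), t, values)


@pytest.fixture
def lag2_pair():
    """Two genes where gene2 copies gene1 delayed by 2 samples."""
    t = np.arange(12, dtype=float)
    x = 1.0 + 0.6 * np.sin(0.9 * t) + 0.02 * t
    y = np.empty_like(x)
    y[2:] = x[:-2]
    y[:2] = x[0]
    values = np.column_stack([x, y])
    return ExpressionTimeSeries(("g1", "g2"), t, values)
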