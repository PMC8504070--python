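import numpy as np
import pytest

from contrastfdr import MeasurementPair


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_pair():
    """3 features x (2, 2) replicates with known row means."""
    return MeasurementPair(
        x=np.array([[3.0, 5.0], [2.0, 2.0], [1.0, 1.0]]),
        y=np.array([[2.0, 2.0], [2.0, 2.0], [4.0, 2.0]]),
        feature_ids=["a", "b", "c"],
    )


def brute_force_cutoff(c, q, offset, scale):
    """Independent O(d^2) scan over every candidate threshold.

    Used as the oracle for the BC (offset=scale=1) and GZ (offset=scale=1/h)
    cutoff rules; deliberately avoids sorting/searchsorted tricks.
    """
    c = np.asarray(c, dtype=float)
    candidates = sorted({abs(v) for v in c if v != 0.0})
    for t in candidates:
        neg = sum(1 for v in c if v <= -t)
        pos = sum(1 for v in c if v >= t)
        if (offset + scale * neg) / max(pos, 1) <= q:
            return t
    return np.inf
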