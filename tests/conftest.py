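import itertools

import numpy as np
import pytest

from drosoquant import dam


def rle_sleep_oracle(counts, min_bout=5):
    """Independent run-length-encoding oracle for sleep bouts.

    Walks the counts with itertools.groupby and returns (start, duration)
    for every maximal zero run of length >= min_bout.
    """
    bouts = []
    pos = 0
    for is_zero, run in itertools.groupby(counts, key=lambda c: c == 0):
        n = len(list(run))
        if is_zero and n >= min_bout:
            bouts.append((pos, n))
        pos += n
    return bouts


def random_trace(rng, n_days=2, p_zero=None):
    """A random activity trace with tunable inactivity probability."""
    if p_zero is None:
        p_zero = rng.uniform(0.2, 0.95)
    n = n_days * 1440
    counts = np.where(
        rng.random(n) < p_zero, 0, rng.integers(1, 6, size=n)
    )
    return dam.ActivityTrace(fly_id="rnd", counts=counts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
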