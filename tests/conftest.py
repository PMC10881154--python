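import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


def brute_force_ks_d(a, b):
    """Independent ECDF-scan oracle for the two-sample KS statistic.

    Evaluates both right-continuous empirical CDFs at every observed value
    and returns the maximum absolute difference.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.searchsorted(a, x, side="right") / a.size
        fb = np.searchsorted(b, x, side="right") / b.size
        best = max(best, abs(fa - fb))
    return best
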