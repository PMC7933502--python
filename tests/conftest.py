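import numpy as np
import pytest

from fmsc.core import METRIC_NAMES, MorphometryTable, Parcellation, ParcelTimeSeries


@pytest.fixture
def parc34():
    return Parcellation.yeo17_two_hemisphere()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_table(rng):
    """A 34-region x 8-metric morphometry table with generic values."""
    values = rng.normal(loc=10.0, scale=2.0, size=(34, 8))
    return MorphometryTable("toy", values, METRIC_NAMES)


@pytest.fixture
def toy_timeseries(rng):
    return ParcelTimeSeries("toy", rng.standard_normal((5, 50)))


# ---------------------------------------------------------------------------
# Independent brute-force oracles, shared across test modules.  These are
# deliberately written as scalar loops from the textbook definitions and
# never call into the package.
# ---------------------------------------------------------------------------

def pearson_loop(x, y):
    """Pearson correlation from the covariance definition, scalar loops."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / (sxx * syy) ** 0.5


def holm_sidak_loop(pvalues):
    """Step-down Sidak adjustment as an explicit loop."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(indexed):
        adj = 1.0 - (1.0 - pvalues[idx]) ** (m - rank)
        running = max(running, adj)
        adjusted[idx] = min(running, 1.0)
    return adjusted


def upper_triangle_pairs(m):
    """Row-major strict upper-triangle pair enumeration."""
    return [(i, j) for i in range(m) for j in range(i + 1, m)]
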