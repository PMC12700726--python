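import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


# ---------------------------------------------------------------- oracles


def aci_oracle(power):
    """Nested-loop reference for the pair-normalised ACI."""
    total = 0.0
    n_f, n_t = power.shape
    for f in range(n_f):
        for i in range(1, n_t):
            a, b = power[f, i], power[f, i - 1]
            if a + b > 0:
                total += abs(a - b) / (a + b)
    return total


def merge_oracle(times, gap_s=5.0):
    """Event count by scanning sorted gaps."""
    if not times:
        return 0
    ts = sorted(times)
    n = 1
    for prev, cur in zip(ts, ts[1:]):
        if cur - prev >= gap_s:
            n += 1
    return n


def kmeans1d_oracle(values, k=3):
    """Exhaustive optimal 1-D k-means over contiguous partitions of the
    sorted values; returns the partition as a label per input value
    (0 = highest-mean cluster)."""
    import itertools

    order = np.argsort(-np.asarray(values, dtype=float))
    v = np.asarray(values, dtype=float)[order]
    n = len(v)
    best, best_cuts = np.inf, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        ss = 0.0
        for a, b in zip(bounds, bounds[1:]):
            seg = v[a:b]
            ss += float(np.sum((seg - seg.mean()) ** 2))
        if ss < best - 1e-12:
            best, best_cuts = ss, cuts
    labels_sorted = np.empty(n, dtype=int)
    bounds = [0, *best_cuts, n]
    for ci, (a, b) in enumerate(zip(bounds, bounds[1:])):
        labels_sorted[a:b] = ci
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels
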