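"""Shared fixtures and independent oracles."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from equisync import VerticalSignal

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_signal(values, rate=100.0, t0=0.0, placement="horse_back",
                demean=True):
    """VerticalSignal helper: demeans so the baseline contract holds."""
    values = np.asarray(values, dtype=float)
    if demean:
        values = values - values.mean()
    return VerticalSignal(t0=t0, rate=rate, values=values,
                          baseline_removed=demean, source_placement=placement)


def brute_lagged_pearson(x, y, max_lag_samples):
    """Pure-Python double-loop overlap-only lagged Pearson correlation.

    Independent oracle for cross_correlation: explicit scalar loops, no
    vectorized shortcuts.
    """
    x, y = list(map(float, x)), list(map(float, y))
    n_x, n_y = len(x), len(y)
    out = []
    for d in range(-max_lag_samples, max_lag_samples + 1):
        xs, ys = [], []
        for i in range(n_x):
            j = i + d
            if 0 <= j < n_y:
                xs.append(x[i])
                ys.append(y[j])
        n = len(xs)
        mx = sum(xs) / n
        my = sum(ys) / n
        sxy = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
        sxx = sum((a - mx) ** 2 for a in xs)
        syy = sum((b - my) ** 2 for b in ys)
        denom = (sxx * syy) ** 0.5
        out.append(sxy / denom if denom > 0 else 0.0)
    return np.array(out)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
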