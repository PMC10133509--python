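import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_stable_model(rng):
    """Random stable 2-pole/1-zero model (real poles) for property tests."""
    from fluidbalance.sysid import TransferFunctionModel

    p1 = rng.uniform(-0.95, 0.95)
    p2 = rng.uniform(-0.95, 0.95)
    return TransferFunctionModel(
        b=(rng.uniform(-1, 1), rng.uniform(-1, 1)),
        a=(-(p1 + p2), p1 * p2),
    )


def reference_difference_equation(b, a, u):
    """Independent brute-force oracle: the literal recursion

        y[k] = sum_i b[i] u[k-i] - sum_j a[j] y[k-j]

    evaluated in pure Python with zero initial conditions.
    """
    y = []
    for k in range(len(u)):
        acc = 0.0
        for i, bi in enumerate(b):
            if k - i >= 0:
                acc += bi * u[k - i]
        for j, aj in enumerate(a, start=1):
            if k - j >= 0:
                acc -= aj * y[k - j]
        y.append(acc)
    return np.asarray(y)


def brute_force_broken_stick(t, y, margin_frac=0.10, spacing=1.0):
    """Exhaustive hinge regression over every candidate on a 1-min grid."""
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    span = t[-1] - t[0]
    lo, hi = t[0] + margin_frac * span, t[-1] - margin_frac * span
    cands = np.arange(np.ceil(lo / spacing) * spacing, hi + 1e-9, spacing)
    cands = cands[(cands > lo - 1e-9) & (cands < hi + 1e-9)]
    best = None
    for c in cands:
        X = np.column_stack((np.ones_like(t), t, np.maximum(t - c, 0.0)))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        rss = float(r @ r)
        if best is None or rss < best[0] - 1e-12:
            best = (rss, float(c), beta)
    return best  # (rss, breakpoint, beta)
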