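"""Broken-stick (one-breakpoint piecewise-linear) modelling of CFI.

Future fluid intake is unknown at prediction time, so the cumulative
intake observed in the estimation window is summarized by two line
segments joined continuously at an unknown breakpoint — a cheap detector
of the moment the intake rate changes (typically: decreases).  The
post-breakpoint slope, clamped at zero, extrapolates the intake 24 h
ahead under the assumption of constant future therapy.

The fit solves, for each candidate breakpoint c on a grid, the linear
least-squares problem in the hinge parameterization

    y(t) = beta0 + beta1 t + beta2 (t - c)_+

and keeps the global residual-sum-of-squares minimizer (earliest
breakpoint on ties).  Continuity at the join is exact by construction.
Normal equations are assembled from suffix sums so the whole candidate
sweep is O(n + candidates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = ["BrokenStickFit", "fit_broken_stick", "extrapolate_cfi"]

DEFAULT_CANDIDATE_SPACING_MIN = 15.0
DEFAULT_EDGE_MARGIN_FRAC = 0.10


@dataclass(frozen=True)
class BrokenStickFit:
    """Continuous two-segment linear model of a window's CFI.

    ``intercept`` is the first segment's value at the window start (L),
    slopes are in L/min, ``breakpoint`` in minutes from window start.
    ``slope2`` may be negative as fitted; extrapolation clamps it.
    """

    intercept: float
    slope1: float
    slope2: float
    breakpoint: float
    rss: float

    def value_at(self, t) -> np.ndarray:
        """Evaluate the fitted piecewise line at minutes ``t``."""
        t = np.asarray(t, dtype=float)
        hinge = np.maximum(t - self.breakpoint, 0.0)
        return self.intercept + self.slope1 * t + (self.slope2 - self.slope1) * hinge

    def to_dict(self) -> dict:
        return {
            "intercept_l": self.intercept,
            "slope1_l_per_min": self.slope1,
            "slope2_l_per_min": self.slope2,
            "breakpoint_min": self.breakpoint,
            "rss": self.rss,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


def _single_line_fit(t: np.ndarray, y: np.ndarray) -> BrokenStickFit:
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (intercept + slope * t)
    mid = float(t[0] + (t[-1] - t[0]) / 2.0)
    return BrokenStickFit(
        intercept=float(intercept + slope * t[0]) if t[0] else float(intercept),
        slope1=float(slope),
        slope2=float(slope),
        breakpoint=mid,
        rss=float(resid @ resid),
    )


def fit_broken_stick(
    t,
    y,
    candidate_spacing_min: float = DEFAULT_CANDIDATE_SPACING_MIN,
    edge_margin_frac: float = DEFAULT_EDGE_MARGIN_FRAC,
) -> BrokenStickFit:
    """Fit the one-breakpoint model over a grid of candidate breakpoints.

    Candidates lie on multiples of ``candidate_spacing_min`` strictly
    inside the window after discarding ``edge_margin_frac`` of its span at
    each end (degenerate near-empty segments are useless clinically and
    ill-conditioned numerically).  Falls back to a single-line fit when
    fewer than two candidates exist.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) != len(y):
        raise ValueError("t and y lengths differ")
    if len(t) < 10:
        raise ValueError("need at least 10 samples for a broken-stick fit")

    span = t[-1] - t[0]
    lo = t[0] + edge_margin_frac * span
    hi = t[-1] - edge_margin_frac * span
    first = np.ceil(lo / candidate_spacing_min) * candidate_spacing_min
    candidates = np.arange(first, hi + 1e-9, candidate_spacing_min)
    candidates = candidates[(candidates > lo - 1e-9) & (candidates < hi + 1e-9)]
    if len(candidates) < 2:
        return _single_line_fit(t, y)

    # suffix sums over samples with t >= c give the hinge moments in O(1)
    n = len(t)
    s1 = np.concatenate((np.cumsum(np.ones(n)[::-1])[::-1], [0.0]))
    st = np.concatenate((np.cumsum(t[::-1])[::-1], [0.0]))
    st2 = np.concatenate((np.cumsum((t * t)[::-1])[::-1], [0.0]))
    sy = np.concatenate((np.cumsum(y[::-1])[::-1], [0.0]))
    sty = np.concatenate((np.cumsum((t * y)[::-1])[::-1], [0.0]))

    T1, Tt, Tt2 = float(n), t.sum(), (t * t).sum()
    Ty, Tty, Tyy = y.sum(), (t * y).sum(), float(y @ y)

    # index of first sample strictly past each candidate (hinge support)
    start = np.searchsorted(t, candidates, side="right")
    c = candidates
    Sh = st[start] - c * s1[start]
    Sh2 = st2[start] - 2 * c * st[start] + c * c * s1[start]
    Sth = st2[start] - c * st[start]
    Shy = sty[start] - c * sy[start]

    k = len(c)
    G = np.empty((k, 3, 3))
    G[:, 0, 0] = T1
    G[:, 0, 1] = G[:, 1, 0] = Tt
    G[:, 0, 2] = G[:, 2, 0] = Sh
    G[:, 1, 1] = Tt2
    G[:, 1, 2] = G[:, 2, 1] = Sth
    G[:, 2, 2] = Sh2
    rhs = np.empty((k, 3))
    rhs[:, 0] = Ty
    rhs[:, 1] = Tty
    rhs[:, 2] = Shy

    beta = np.linalg.solve(G, rhs[..., None])[..., 0]
    rss = Tyy - np.einsum("ij,ij->i", beta, rhs)
    # earliest breakpoint among near-ties (tolerance absorbs the rounding
    # noise of the suffix-sum RSS formula)
    tol = 1e-9 * max(abs(Tyy), 1.0)
    best = int(np.argmax(rss <= rss.min() + tol))

    bp = float(c[best])
    # re-solve the winner on the explicit design matrix: the suffix-sum
    # normal equations rank candidates fast but lose digits
    hinge = np.maximum(t - bp, 0.0)
    X = np.column_stack((np.ones_like(t), t, hinge))
    (b0, b1, b2), *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - (b0 + b1 * t + b2 * hinge)
    return BrokenStickFit(
        intercept=float(b0 + b1 * t[0]),
        slope1=float(b1),
        slope2=float(b1 + b2),
        breakpoint=bp,
        rss=float(resid @ resid),
    )


def extrapolate_cfi(
    fit: BrokenStickFit,
    window_end_value: float,
    horizon_minutes: int = 1440,
) -> np.ndarray:
    """Continue CFI past the window at the post-breakpoint rate.

    Anchored at the last *observed* CFI value so the simulated input has
    no jump at the junction; the rate is max(slope2, 0) because cumulative
    intake cannot decrease.  Returns ``horizon_minutes`` samples at 60 s
    spacing, starting one minute after the window end.
    """
    if horizon_minutes < 0:
        raise ValueError("negative extrapolation horizon")
    rate = max(fit.slope2, 0.0)
    return window_end_value + rate * np.arange(1, horizon_minutes + 1, dtype=float)
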