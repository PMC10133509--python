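"""Patient-individual discrete-time transfer-function identification.

The patient is modelled as a linear time-invariant "black box" mapping
cumulative fluid intake u[k] (CFI, liters) to cumulative fluid balance
y[k] (CFB, liters) at one sample per minute:

    P(z) = (b0 + b1 z^-1) / (1 + a1 z^-1 + a2 z^-2)

i.e. two poles, one zero, and a direct feedthrough term b0 (CFB reacts
instantaneously to intake because it is computed from it).  Identification
minimizes the *simulation* (output-error) objective

    J(theta) = sum_k (y[k] - yhat_theta[k])^2,   yhat_theta = P_theta u,

refined from a linear ARX initializer by a damped Gauss-Newton
(Levenberg-Marquardt) search with an analytic sensitivity-filter Jacobian.
Stability is deliberately not enforced — oscillatory or unstable fluid
responses are physiologically possible — but pole moduli are reported and
a divergence guard aborts overflowing simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "TransferFunctionModel",
    "EstimationReport",
    "SimulationDivergedError",
    "simulate_tf",
    "arx_initialize",
    "estimate_tf",
]

DEFAULT_TS_SECONDS = 60.0
DEFAULT_OVERFLOW_GUARD_L = 1e6


class SimulationDivergedError(RuntimeError):
    """The simulated output overflowed the divergence guard."""


@dataclass(frozen=True)
class TransferFunctionModel:
    """Coefficients of P(z) with a monic denominator.

    ``b`` holds the numerator (b0 ... bm, feedthrough first) and ``a`` the
    denominator tail (a1 ... an); the leading denominator coefficient is
    fixed to 1.  Defaults describe the 2-pole / 1-zero / feedthrough
    structure used throughout.
    """

    b: tuple[float, ...] = (0.0, 0.0)
    a: tuple[float, ...] = (0.0, 0.0)
    ts: float = DEFAULT_TS_SECONDS

    def __post_init__(self) -> None:
        if len(self.b) > len(self.a) + 1:
            raise ValueError("numerator order exceeds denominator order (non-causal)")
        coeffs = (*self.b, *self.a)
        if not all(np.isfinite(c) for c in coeffs):
            raise ValueError("non-finite transfer-function coefficient")

    # named accessors for the default structure
    @property
    def b0(self) -> float:
        return self.b[0]

    @property
    def b1(self) -> float:
        return self.b[1] if len(self.b) > 1 else 0.0

    @property
    def a1(self) -> float:
        return self.a[0] if len(self.a) > 0 else 0.0

    @property
    def a2(self) -> float:
        return self.a[1] if len(self.a) > 1 else 0.0

    @property
    def order_n(self) -> int:
        return len(self.a)

    @property
    def order_m(self) -> int:
        return len(self.b) - 1

    def poles(self) -> np.ndarray:
        return np.roots([1.0, *self.a])

    def pole_magnitudes(self) -> np.ndarray:
        return np.sort(np.abs(self.poles()))[::-1]

    def is_stable(self) -> bool:
        return bool(np.all(self.pole_magnitudes() < 1.0))

    def to_dict(self) -> dict:
        return {
            "b0": self.b0,
            "b1": self.b1,
            "a1": self.a1,
            "a2": self.a2,
            "ts_seconds": self.ts,
            "order_n": self.order_n,
            "order_m": self.order_m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TransferFunctionModel":
        return cls(b=(d["b0"], d["b1"]), a=(d["a1"], d["a2"]), ts=d.get("ts_seconds", 60.0))


@dataclass
class EstimationReport:
    model: TransferFunctionModel
    objective_value: float
    iterations: int
    converged: bool
    pole_magnitudes: tuple[float, ...]
    degenerate_input: bool = False


def _as_array(x) -> np.ndarray:
    arr = np.asarray(getattr(x, "values", x), dtype=float)
    if arr.ndim != 1:
        raise ValueError("input series must be one-dimensional")
    return arr


def simulate_tf(
    model: TransferFunctionModel,
    u,
    overflow_guard: float = DEFAULT_OVERFLOW_GUARD_L,
) -> np.ndarray:
    """Free-run simulation of the difference equation with zero initial state.

        y[k] = b0 u[k] + b1 u[k-1] - a1 y[k-1] - a2 y[k-2]

    with y[-1] = y[-2] = 0 and u[-1] = 0 (the CFB offset is zero at the
    window start).  Raises :class:`SimulationDivergedError` if |y| exceeds
    ``overflow_guard`` liters or becomes non-finite.
    """
    uu = _as_array(u)
    if not np.all(np.isfinite(uu)):
        raise ValueError("non-finite input sample")
    with np.errstate(over="ignore", invalid="ignore"):
        y = lfilter(np.asarray(model.b), np.asarray([1.0, *model.a]), uu)
    if not np.all(np.isfinite(y)) or (len(y) and np.max(np.abs(y)) > overflow_guard):
        raise SimulationDivergedError(
            f"simulated CFB exceeded {overflow_guard:g} L (unstable model)"
        )
    return y


def _simulate_or_none(b: np.ndarray, a: np.ndarray, u: np.ndarray, guard: float):
    with np.errstate(over="ignore", invalid="ignore"):
        y = lfilter(b, np.concatenate(([1.0], a)), u)
    if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > guard:
        return None
    return y


def arx_initialize(u, y, orders: tuple[int, int] = (2, 1)) -> tuple[TransferFunctionModel, bool]:
    """Equation-error (ARX) least squares, the linear initializer.

    Solves  y[k] = sum_i b_i u[k-i] - sum_j a_j y[k-j] + e[k]  by ordinary
    least squares (minimum-norm solution on rank deficiency).  Returns the
    model and a degenerate-input flag (True when the regressor is all
    zero).
    """
    n, m = orders
    uu, yy = _as_array(u), _as_array(y)
    if len(uu) != len(yy):
        raise ValueError("input and output lengths differ")
    n_params = (m + 1) + n
    lag = max(n, m)
    if len(uu) < lag + 10 * n_params:
        raise ValueError("series too short for the requested model orders")

    k = np.arange(lag, len(uu))
    cols = [uu[k - i] for i in range(m + 1)] + [-yy[k - j] for j in range(1, n + 1)]
    X = np.column_stack(cols)
    if not X.any():
        return TransferFunctionModel(b=(0.0,) * (m + 1), a=(0.0,) * n), True
    theta, *_ = np.linalg.lstsq(X, yy[k], rcond=None)
    return (
        TransferFunctionModel(b=tuple(theta[: m + 1]), a=tuple(theta[m + 1 :])),
        False,
    )


def _reflect_unstable_poles(a: np.ndarray) -> np.ndarray:
    """Map poles outside the unit circle to their stable reflections."""
    poles = np.roots(np.concatenate(([1.0], a)))
    mags = np.abs(poles)
    if np.all(mags < 1.0):
        return a
    poles = np.where(mags >= 1.0, poles / np.maximum(mags, 1e-12) ** 2, poles)
    return np.real(np.poly(poles))[1:]


def estimate_tf(
    u,
    y,
    orders: tuple[int, int] = (2, 1),
    max_iter: int = 100,
    rel_tol: float = 1e-10,
    overflow_guard: float = DEFAULT_OVERFLOW_GUARD_L,
) -> EstimationReport:
    """Output-error transfer-function fit on one estimation window.

    Starts from :func:`arx_initialize` (poles reflected inside the unit
    circle if the initializer simulates unstably) and refines by
    Levenberg-Marquardt on the simulation-error sum of squares.  The
    Jacobian is analytic: with A(z) the current denominator,

        d yhat / d b_i = z^-i u / A,    d yhat / d a_j = -z^-j yhat / A.

    Convergence: relative objective decrease below ``rel_tol`` or
    ``max_iter`` iterations.  The objective never increases across accepted
    iterates; if no finite-objective model is found the ARX initializer is
    returned with ``converged=False``.
    """
    n, m = orders
    uu, yy = _as_array(u), _as_array(y)
    arx_model, degenerate = arx_initialize(uu, yy, orders)
    if degenerate:
        return EstimationReport(
            model=arx_model,
            objective_value=float(np.sum(yy**2)),
            iterations=0,
            converged=True,
            pole_magnitudes=tuple(arx_model.pole_magnitudes()),
            degenerate_input=True,
        )

    def unpack(theta):
        return theta[: m + 1], theta[m + 1 :]

    theta = np.array([*arx_model.b, *arx_model.a])
    b, a = unpack(theta)
    yhat = _simulate_or_none(b, a, uu, overflow_guard)
    if yhat is None:
        a_stable = _reflect_unstable_poles(a)
        theta = np.concatenate([b, a_stable])
        b, a = unpack(theta)
        yhat = _simulate_or_none(b, a, uu, overflow_guard)
    if yhat is None:
        return EstimationReport(
            model=arx_model,
            objective_value=float("inf"),
            iterations=0,
            converged=False,
            pole_magnitudes=tuple(arx_model.pole_magnitudes()),
        )

    resid = yy - yhat
    obj = float(resid @ resid)
    lam = 1e-3
    iterations = 0
    converged = False

    for iterations in range(1, max_iter + 1):
        a_full = np.concatenate(([1.0], a))
        # sensitivity filters: shift the base responses for higher lags
        fu = lfilter([1.0], a_full, uu)
        fy = lfilter([1.0], a_full, yhat)
        J = np.empty((len(uu), m + 1 + n))
        for i in range(m + 1):
            J[:, i] = np.concatenate((np.zeros(i), fu[: len(uu) - i]))
        for j in range(1, n + 1):
            J[:, m + j] = -np.concatenate((np.zeros(j), fy[: len(uu) - j]))
        if not np.all(np.isfinite(J)):
            break

        JtJ = J.T @ J
        Jtr = J.T @ resid
        diag = np.diag(JtJ).copy()
        diag[diag == 0.0] = 1.0

        accepted = False
        for _ in range(50):
            try:
                step = np.linalg.solve(JtJ + lam * np.diag(diag), Jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            theta_new = theta + step
            b_new, a_new = unpack(theta_new)
            yhat_new = _simulate_or_none(b_new, a_new, uu, overflow_guard)
            if yhat_new is not None:
                resid_new = yy - yhat_new
                obj_new = float(resid_new @ resid_new)
                if obj_new <= obj:
                    accepted = True
                    break
            lam *= 10.0
        if not accepted:
            break

        rel_decrease = (obj - obj_new) / max(obj, 1e-300)
        theta, b, a = theta_new, b_new, a_new
        yhat, resid, obj = yhat_new, resid_new, obj_new
        lam = max(lam / 3.0, 1e-12)
        if rel_decrease < rel_tol:
            converged = True
            break

    model = TransferFunctionModel(b=tuple(b), a=tuple(a))
    return EstimationReport(
        model=model,
        objective_value=obj,
        iterations=iterations,
        converged=converged,
        pole_magnitudes=tuple(model.pole_magnitudes()),
    )
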