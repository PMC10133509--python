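"""Sliding-window CFB prediction over an ICU stay.

A window consists of an estimation period (24, 48, 72, 96 or 120 h) used
to fit the patient's transfer function and broken-stick intake model,
followed by a fixed 24 h prediction period; the window slides in 2 h
steps while fully contained in the stay.  Within each window the CFB (and
CFI) offset is reset to zero at the window start, matching the zero
initial conditions of the transfer-function simulation.

Per-window pipeline:

1. re-zero CFI and CFB at the window start;
2. fit the transfer function on the estimation segment (output error);
3. fit the broken stick to the estimation-segment CFI and extrapolate the
   intake 24 h at the (clamped) post-breakpoint rate;
4. simulate the transfer function over the full concatenated input
   (observed estimation CFI + extrapolated CFI) from zero initial
   conditions, so the model state at the prediction start reflects the
   estimation period;
5. keep the final 24 h of the simulated output as the predicted CFB and
   score it against the actual CFB at horizons 8, 12, 16, 20, 24 h.

Prediction segments use inclusive endpoints: 1441 samples at 60 s, with
horizon h at sample index 60*h.  Unstable fits whose simulation
overflows are flagged ``diverged`` and excluded from error statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .broken_stick import BrokenStickFit, extrapolate_cfi, fit_broken_stick
from .evaluation import HORIZONS_H, endpoint_error, rmse_last_30min
from .records import CumulativeSeries, PatientRecord
from .sysid import (
    EstimationReport,
    SimulationDivergedError,
    TransferFunctionModel,
    estimate_tf,
    simulate_tf,
)

__all__ = [
    "ESTIMATION_HOURS",
    "PREDICTION_HOURS",
    "STEP_HOURS",
    "WindowSpec",
    "PredictionResult",
    "generate_windows",
    "rezero_window",
    "predict_window",
    "run_patient",
    "run_cohort",
    "results_to_frame",
]

ESTIMATION_HOURS = (24, 48, 72, 96, 120)
PREDICTION_HOURS = 24
STEP_HOURS = 2


@dataclass(frozen=True)
class WindowSpec:
    """One sliding-window position for one patient."""

    patient_id: str
    start_min: int
    estimation_hours: int
    prediction_hours: int = PREDICTION_HOURS
    step_hours: int = STEP_HOURS

    @property
    def estimation_samples(self) -> int:
        """Samples in the estimation segment, inclusive of both ends."""
        return self.estimation_hours * 60 + 1

    @property
    def prediction_samples(self) -> int:
        return self.prediction_hours * 60 + 1

    @property
    def end_min(self) -> int:
        return self.start_min + (self.estimation_hours + self.prediction_hours) * 60


@dataclass
class PredictionResult:
    """Predicted vs actual CFB for one window, in the re-zeroed frame."""

    window: WindowSpec
    model: TransferFunctionModel | None
    cfi_fit: BrokenStickFit | None
    predicted_cfb: np.ndarray | None
    actual_cfb: np.ndarray | None
    rmse_by_horizon: dict[int, float] = field(default_factory=dict)
    endpoint_error_by_horizon: dict[int, float] = field(default_factory=dict)
    diverged: bool = False
    converged: bool = True


def _stay_minutes(record: PatientRecord) -> int:
    """Last minute index of the stay's sample grid."""
    if record.cfb is not None:
        return len(record.cfb.values) - 1
    return record.n_samples - 1


def generate_windows(
    record: PatientRecord,
    estimation_hours: int,
    step_hours: int = STEP_HOURS,
    prediction_hours: int = PREDICTION_HOURS,
) -> list[WindowSpec]:
    """All fully observed window positions, starting at admission.

    Starts at 0, step_hours, 2*step_hours, ... minutes while
    start + estimation + prediction fits inside the stay.  Empty list if
    even the first window does not fit.
    """
    total_min = (estimation_hours + prediction_hours) * 60
    last_min = _stay_minutes(record)
    step_min = step_hours * 60
    windows = []
    start = 0
    while start + total_min <= last_min:
        windows.append(
            WindowSpec(
                patient_id=record.patient_id,
                start_min=start,
                estimation_hours=estimation_hours,
                prediction_hours=prediction_hours,
                step_hours=step_hours,
            )
        )
        start += step_min
    return windows


def rezero_window(
    series: CumulativeSeries, window: WindowSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Split a series into (estimation, prediction) segments re-zeroed at
    the window start.

    Both segments subtract the value at the window's first sample, so the
    estimation segment starts at 0 and the prediction segment shares the
    same frame.  The segments overlap in one sample (the prediction start).
    """
    s = window.start_min
    e = s + window.estimation_hours * 60
    p = e + window.prediction_hours * 60
    vals = series.values
    if s < 0 or p > len(vals) - 1:
        raise ValueError("window extends past the end of the series")
    offset = vals[s]
    return vals[s : e + 1] - offset, vals[e : p + 1] - offset


def predict_window(
    record: PatientRecord,
    window: WindowSpec,
    keep_series: bool = True,
    sysid_options: dict | None = None,
    broken_stick_options: dict | None = None,
) -> PredictionResult:
    """Run the full estimation → extrapolation → simulation pipeline on
    one window and score the prediction."""
    if record.cfi is None or record.cfb is None:
        raise ValueError("record has no derived series")
    cfi_est, _ = rezero_window(record.cfi, window)
    cfb_est, cfb_pred_actual = rezero_window(record.cfb, window)

    report: EstimationReport = estimate_tf(cfi_est, cfb_est, **(sysid_options or {}))
    t_est = np.arange(len(cfi_est), dtype=float)
    fit = fit_broken_stick(t_est, cfi_est, **(broken_stick_options or {}))
    cfi_future = extrapolate_cfi(fit, cfi_est[-1], window.prediction_hours * 60)
    u_full = np.concatenate((cfi_est, cfi_future))

    result = PredictionResult(
        window=window,
        model=report.model,
        cfi_fit=fit,
        predicted_cfb=None,
        actual_cfb=cfb_pred_actual if keep_series else None,
        converged=report.converged,
    )
    try:
        y_full = simulate_tf(report.model, u_full)
    except SimulationDivergedError:
        result.diverged = True
        result.rmse_by_horizon = {h: float("nan") for h in HORIZONS_H}
        result.endpoint_error_by_horizon = {h: float("nan") for h in HORIZONS_H}
        return result

    predicted = y_full[window.estimation_hours * 60 :]
    result.rmse_by_horizon = {
        h: rmse_last_30min(predicted, cfb_pred_actual, h) for h in HORIZONS_H
    }
    result.endpoint_error_by_horizon = {
        h: endpoint_error(predicted, cfb_pred_actual, h) for h in HORIZONS_H
    }
    if keep_series:
        result.predicted_cfb = predicted
    else:
        result.actual_cfb = None
    return result


def run_patient(
    record: PatientRecord,
    estimation_hours: tuple[int, ...] = ESTIMATION_HOURS,
    keep_series: bool = False,
    **kwargs,
) -> list[PredictionResult]:
    """All windows for one patient, ascending start within each
    estimation time."""
    results = []
    for est_h in estimation_hours:
        for window in generate_windows(record, est_h):
            results.append(predict_window(record, window, keep_series=keep_series, **kwargs))
    return results


def run_cohort(
    records,
    estimation_hours: tuple[int, ...] = ESTIMATION_HOURS,
    keep_series: bool = False,
    **kwargs,
) -> tuple[list[PredictionResult], pd.DataFrame]:
    """Deterministic cohort sweep (sorted patients, ascending windows).

    Returns all window results plus a per-estimation-time count table with
    columns n_patients, n_predictions, n_diverged.  Per-window failures
    never abort the cohort.
    """
    all_results: list[PredictionResult] = []
    counts: dict[int, dict[str, int]] = {
        est: {"n_patients": 0, "n_predictions": 0, "n_diverged": 0} for est in estimation_hours
    }
    for record in sorted(records, key=lambda r: r.patient_id):
        for est_h in estimation_hours:
            windows = generate_windows(record, est_h)
            if windows:
                counts[est_h]["n_patients"] += 1
            for window in windows:
                res = predict_window(record, window, keep_series=keep_series, **kwargs)
                counts[est_h]["n_predictions"] += 1
                if res.diverged:
                    counts[est_h]["n_diverged"] += 1
                all_results.append(res)
    count_df = (
        pd.DataFrame.from_dict(counts, orient="index")
        .rename_axis("estimation_h")
        .reset_index()
    )
    return all_results, count_df


def results_to_frame(results) -> pd.DataFrame:
    """Flatten window results: one row per window, errors in liters."""
    rows = []
    for r in results:
        row = {
            "patient_id": r.window.patient_id,
            "window_start_min": r.window.start_min,
            "estimation_h": r.window.estimation_hours,
            "diverged": r.diverged,
        }
        for h in HORIZONS_H:
            row[f"rmse_{h}h"] = r.rmse_by_horizon.get(h, float("nan"))
        for h in HORIZONS_H:
            row[f"err_{h}h"] = r.endpoint_error_by_horizon.get(h, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def save_window_sidecar(result: PredictionResult, directory) -> Path:
    """Store the window's model and intake fit as JSON next to the results
    table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = (
        f"{result.window.patient_id}_e{result.window.estimation_hours}"
        f"_s{result.window.start_min}.json"
    )
    payload = {
        "window": {
            "patient_id": result.window.patient_id,
            "start_min": result.window.start_min,
            "estimation_h": result.window.estimation_hours,
            "prediction_h": result.window.prediction_hours,
        },
        "model": result.model.to_dict() if result.model else None,
        "converged": result.converged,
        "cfi_fit": result.cfi_fit.to_dict() if result.cfi_fit else None,
        "diverged": result.diverged,
    }
    path = directory / name
    path.write_text(json.dumps(payload, indent=2))
    return path
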