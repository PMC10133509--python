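"""Fluid event logs and minute-sampled cumulative series.

Raw ICU fluid documentation arrives as timestamped intake and loss events
(infusions, boluses, urine entries, drains, ...).  This module parses such
event logs, applies the cohort inclusion filters (length of stay between 4
and 7 days, no negative volumes, no long documentation gaps) and turns each
patient's events into uniformly sampled cumulative curves at one sample per
minute:

* CFI — cumulative fluid intake,
* CFL — cumulative fluid losses,
* CFB — cumulative fluid balance, CFB = CFI - CFL.

Interpolation rules follow clinical documentation practice: cumulative
curves are step-held at documented entries, except urine, whose cumulative
curve is linearly interpolated between consecutive documented entries (the
bladder fills roughly evenly between voidings).  Gravity infusions without
a documented end run at 16 mL/min until their volume is exhausted.

Volumes are liters everywhere inside the numerical pipeline; milliliters
appear only at the CSV boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "INTAKE_CATEGORIES",
    "LOSS_CATEGORIES",
    "MODES",
    "GRAVITY_RATE_ML_PER_MIN",
    "FluidEvent",
    "CumulativeSeries",
    "PatientRecord",
    "ParseError",
    "ValidationResult",
    "parse_fluid_events",
    "validate_patient_record",
    "expand_event",
    "build_cumulative_series",
    "compute_cfb",
    "write_series_csv",
    "read_series_csv",
    "write_events_csv",
    "write_validation_report",
]

INTAKE_CATEGORIES = frozenset(
    {"colloid", "crystalloid", "medication", "oral", "parenteral_nutrition", "blood_product"}
)
LOSS_CATEGORIES = frozenset(
    {"urine", "drainage", "renal_replacement", "vomiting", "blood_sample", "stool", "miscellaneous"}
)
MODES = frozenset({"bolus", "continuous", "gravity"})

#: assumed flow of a gravity infusion lacking a documented end timestamp
GRAVITY_RATE_ML_PER_MIN = 16.0

SECONDS_PER_MINUTE = 60.0


class GridMismatchError(ValueError):
    """Two series do not share the same time grid."""


class EmptyRecordError(ValueError):
    """A patient record contains no events."""


@dataclass(frozen=True)
class FluidEvent:
    """One documented intake or loss.

    ``volume_ml`` is the total documented volume in milliliters; ``mode``
    describes how it was administered (irrelevant for losses, which are
    documented as point entries).
    """

    patient_id: str
    start_time: pd.Timestamp
    end_time: pd.Timestamp | None
    direction: str  # "intake" | "loss"
    category: str
    volume_ml: float
    mode: str = "bolus"

    def __post_init__(self) -> None:
        if self.direction not in ("intake", "loss"):
            raise ValueError(f"unknown direction {self.direction!r}")
        allowed = INTAKE_CATEGORIES if self.direction == "intake" else LOSS_CATEGORIES
        if self.category not in allowed:
            raise ValueError(
                f"category {self.category!r} inconsistent with direction {self.direction!r}"
            )
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not np.isfinite(self.volume_ml) or self.volume_ml < 0:
            raise ValueError(f"negative fluid volume: {self.volume_ml}")
        if self.end_time is not None and self.end_time < self.start_time:
            raise ValueError("end_time precedes start_time")


@dataclass
class CumulativeSeries:
    """A uniformly sampled cumulative volume curve in liters.

    ``values[k]`` is the volume at ``t0 + k * dt``; ``dt`` is 60 s
    throughout the pipeline.  ``kind`` is one of CFI, CFL, CFB.
    """

    t0: pd.Timestamp
    values: np.ndarray
    kind: str
    dt: float = SECONDS_PER_MINUTE

    def __post_init__(self) -> None:
        if self.kind not in ("CFI", "CFL", "CFB"):
            raise ValueError(f"unknown series kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def minutes(self) -> np.ndarray:
        """Sample times in minutes from ``t0``."""
        return np.arange(len(self.values), dtype=float) * (self.dt / SECONDS_PER_MINUTE)

    def same_grid(self, other: "CumulativeSeries") -> bool:
        return (
            self.t0 == other.t0
            and self.dt == other.dt
            and len(self.values) == len(other.values)
        )


@dataclass
class PatientRecord:
    """Events plus derived cumulative series for one ICU stay."""

    patient_id: str
    admission_time: pd.Timestamp
    discharge_time: pd.Timestamp
    events: list[FluidEvent] = field(default_factory=list)
    cfi: CumulativeSeries | None = None
    cfl: CumulativeSeries | None = None
    cfb: CumulativeSeries | None = None

    @property
    def los_days(self) -> float:
        return (self.discharge_time - self.admission_time) / pd.Timedelta(days=1)

    @property
    def n_samples(self) -> int:
        """Number of minute-grid samples covering the stay (inclusive ends)."""
        los_min = (self.discharge_time - self.admission_time) / pd.Timedelta(minutes=1)
        return int(round(los_min)) + 1


@dataclass(frozen=True)
class ParseError:
    """A structured per-row parse failure."""

    row: int
    message: str


@dataclass(frozen=True)
class ValidationResult:
    included: bool
    reasons: tuple[str, ...]


# ---------------------------------------------------------------------------
# parsing

_CSV_COLUMNS = ["patient_id", "start_time", "end_time", "direction", "category", "volume_ml", "mode"]


def _parse_timestamp(raw: str) -> pd.Timestamp:
    try:
        ts = pd.Timestamp(raw)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed timestamp {raw!r}") from exc
    if pd.isna(ts):
        raise ValueError(f"malformed timestamp {raw!r}")
    return ts


def parse_fluid_events(source) -> tuple[list[PatientRecord], list[ParseError]]:
    """Parse a CSV event log into per-patient records.

    Every row becomes exactly one :class:`FluidEvent` or one
    :class:`ParseError` carrying the 0-based data row index.  Events are
    grouped by patient and sorted by start time; admission and discharge
    are taken as the earliest event start and the latest event end (or
    start), snapped outward to whole minutes.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event file missing columns: {missing}")

    events: dict[str, list[FluidEvent]] = {}
    errors: list[ParseError] = []
    for row_idx, row in enumerate(df.itertuples(index=False)):
        try:
            start = _parse_timestamp(row.start_time)
            end = _parse_timestamp(row.end_time) if row.end_time.strip() else None
            volume = float(row.volume_ml)
            if volume < 0:
                raise ValueError("negative fluid intake")
            ev = FluidEvent(
                patient_id=row.patient_id,
                start_time=start,
                end_time=end,
                direction=row.direction,
                category=row.category,
                volume_ml=volume,
                mode=row.mode or "bolus",
            )
        except (ValueError, TypeError) as exc:
            errors.append(ParseError(row=row_idx, message=str(exc)))
            continue
        events.setdefault(ev.patient_id, []).append(ev)

    records = []
    for pid in sorted(events):
        evs = sorted(events[pid], key=lambda e: e.start_time)
        t_start = min(e.start_time for e in evs).floor("min")
        t_end = max((e.end_time or e.start_time) for e in evs).ceil("min")
        records.append(
            PatientRecord(patient_id=pid, admission_time=t_start, discharge_time=t_end, events=evs)
        )
    return records, errors


def validate_patient_record(
    record: PatientRecord,
    min_los: float = 4.0,
    max_los: float = 7.0,
    max_gap_hours: float = 24.0,
) -> ValidationResult:
    """Cohort inclusion decision with reason codes.

    Exclusion reasons: ``los_below_min`` (< ``min_los`` days),
    ``los_above_max`` (> ``max_los`` days), ``negative_volume``,
    ``coverage_gap`` (no documented event over ``max_gap_hours``),
    ``empty_record``.  Pure function of its arguments.
    """
    reasons: list[str] = []
    if not record.events:
        return ValidationResult(False, ("empty_record",))
    los = record.los_days
    if los < min_los:
        reasons.append("los_below_min")
    if los > max_los:
        reasons.append("los_above_max")
    if any(e.volume_ml < 0 for e in record.events):
        reasons.append("negative_volume")

    gap = pd.Timedelta(hours=max_gap_hours)
    times = sorted(e.start_time for e in record.events)
    anchors = [record.admission_time, *times]
    last_cover = max((e.end_time or e.start_time) for e in record.events)
    anchors.append(max(last_cover, times[-1]))
    anchors.append(record.discharge_time)
    if any(b - a > gap for a, b in zip(anchors, anchors[1:])):
        reasons.append("coverage_gap")

    return ValidationResult(included=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# series construction


def _minute_index(ts: pd.Timestamp, t0: pd.Timestamp) -> int:
    return int(round((ts - t0) / pd.Timedelta(minutes=1)))


def expand_event(event: FluidEvent, t0: pd.Timestamp, n_steps: int) -> np.ndarray:
    """Allocate an event's volume to the minute grid, in liters per step.

    * bolus — full volume in the step containing ``start_time``;
    * continuous with a documented end — volume spread uniformly over
      [start, end) (a linear ramp of the cumulative curve);
    * gravity (or continuous) without an end — 16 mL per minute from
      ``start_time`` until the volume is exhausted, remainder in the final
      minute.

    The increments always sum to the documented volume exactly; volume that
    would run past the grid end is carried in the last step.
    """
    inc = np.zeros(n_steps)
    start = _minute_index(event.start_time, t0)
    if start < 0 or start >= n_steps:
        raise ValueError(
            f"event at {event.start_time} outside grid for patient {event.patient_id}"
        )
    vol_l = event.volume_ml / 1000.0

    if event.mode == "bolus" or vol_l == 0.0:
        inc[start] += vol_l
        return inc

    if event.end_time is not None:
        n_min = _minute_index(event.end_time, t0) - start
        if n_min <= 0:  # zero-duration continuous event is a bolus
            inc[start] += vol_l
            return inc
        stop = min(start + n_min, n_steps)
        inc[start:stop] += vol_l / n_min
        if start + n_min > n_steps:  # ran past discharge: conserve volume
            inc[-1] += vol_l * (start + n_min - n_steps) / n_min
        return inc

    # no documented end: assumed gravity flow at 16 mL/min
    rate_l = GRAVITY_RATE_ML_PER_MIN / 1000.0
    n_full = int(vol_l / rate_l)
    remainder = vol_l - n_full * rate_l
    stop = min(start + n_full, n_steps)
    inc[start:stop] += rate_l
    overflow = rate_l * (start + n_full - stop)
    rem_idx = min(start + n_full, n_steps - 1)
    inc[rem_idx] += remainder + overflow
    return inc


def _urine_curve(events: Sequence[FluidEvent], t0: pd.Timestamp, n_steps: int) -> np.ndarray:
    """Cumulative urine in liters: linear between documented entries.

    Anchored at (admission, 0); after the last documented entry the curve
    holds its final value.
    """
    by_minute: dict[int, float] = {}
    for ev in events:
        idx = _minute_index(ev.start_time, t0)
        if idx < 0 or idx >= n_steps:
            raise ValueError(f"urine entry at {ev.start_time} outside grid")
        by_minute[idx] = by_minute.get(idx, 0.0) + ev.volume_ml / 1000.0
    idxs = sorted(by_minute)
    cum = np.cumsum([by_minute[i] for i in idxs])
    if idxs[0] > 0:
        xs = np.concatenate(([0.0], np.asarray(idxs, dtype=float)))
        ys = np.concatenate(([0.0], cum))
    else:
        xs = np.asarray(idxs, dtype=float)
        ys = cum
    grid = np.arange(n_steps, dtype=float)
    return np.interp(grid, xs, ys)


def build_cumulative_series(
    record: PatientRecord,
) -> tuple[CumulativeSeries, CumulativeSeries]:
    """Build the minute-sampled (CFI, CFL) pair for one patient.

    All categories use step interpolation of their cumulative curve via
    :func:`expand_event`, except urine, whose cumulative curve is linearly
    interpolated between documented entries.
    """
    if not record.events:
        raise EmptyRecordError(f"empty record for patient {record.patient_id}")
    n = record.n_samples
    t0 = record.admission_time

    intake_inc = np.zeros(n)
    loss_inc = np.zeros(n)
    urine_events: list[FluidEvent] = []
    for ev in record.events:
        if ev.direction == "intake":
            intake_inc += expand_event(ev, t0, n)
        elif ev.category == "urine":
            urine_events.append(ev)
        else:
            loss_inc += expand_event(ev, t0, n)

    cfi = np.cumsum(intake_inc)
    cfl = np.cumsum(loss_inc)
    if urine_events:
        cfl = cfl + _urine_curve(urine_events, t0, n)
    return (
        CumulativeSeries(t0=t0, values=cfi, kind="CFI"),
        CumulativeSeries(t0=t0, values=cfl, kind="CFL"),
    )


def compute_cfb(cfi: CumulativeSeries, cfl: CumulativeSeries) -> CumulativeSeries:
    """CFB = CFI - CFL on a shared grid; may be negative."""
    if not cfi.same_grid(cfl):
        raise GridMismatchError("CFI and CFL are not on the same grid")
    return CumulativeSeries(t0=cfi.t0, values=cfi.values - cfl.values, kind="CFB")


def attach_series(record: PatientRecord) -> PatientRecord:
    """Derive and attach cfi/cfl/cfb to a parsed record (in place)."""
    cfi, cfl = build_cumulative_series(record)
    record.cfi, record.cfl = cfi, cfl
    record.cfb = compute_cfb(cfi, cfl)
    return record


# ---------------------------------------------------------------------------
# I/O


def write_series_csv(record: PatientRecord, path) -> None:
    """Per-patient minute grid: columns t_min, cfi_l, cfl_l, cfb_l."""
    if record.cfi is None or record.cfl is None or record.cfb is None:
        raise ValueError("record has no derived series; call attach_series first")
    pd.DataFrame(
        {
            "t_min": np.arange(len(record.cfi)),
            "cfi_l": record.cfi.values,
            "cfl_l": record.cfl.values,
            "cfb_l": record.cfb.values,
        }
    ).to_csv(path, index=False)


def read_series_csv(path, patient_id: str | None = None) -> PatientRecord:
    """Load a per-patient series CSV back into a series-only record."""
    df = pd.read_csv(path)
    pid = patient_id or Path(path).stem
    t0 = pd.Timestamp("2000-01-01")  # series files carry no absolute clock
    n = len(df)
    rec = PatientRecord(
        patient_id=pid,
        admission_time=t0,
        discharge_time=t0 + pd.Timedelta(minutes=n - 1),
    )
    rec.cfi = CumulativeSeries(t0=t0, values=df["cfi_l"].to_numpy(), kind="CFI")
    rec.cfl = CumulativeSeries(t0=t0, values=df["cfl_l"].to_numpy(), kind="CFL")
    rec.cfb = CumulativeSeries(t0=t0, values=df["cfb_l"].to_numpy(), kind="CFB")
    return rec


def write_events_csv(records: Iterable[PatientRecord], path) -> None:
    """Write event logs in the canonical CSV schema (mL at the boundary)."""
    rows = []
    for rec in records:
        for ev in rec.events:
            rows.append(
                {
                    "patient_id": ev.patient_id,
                    "start_time": ev.start_time.isoformat(),
                    "end_time": ev.end_time.isoformat() if ev.end_time is not None else "",
                    "direction": ev.direction,
                    "category": ev.category,
                    "volume_ml": ev.volume_ml,
                    "mode": ev.mode,
                }
            )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def write_validation_report(decisions: dict[str, ValidationResult], path) -> None:
    payload = {
        pid: {"included": d.included, "reasons": list(d.reasons)} for pid, d in decisions.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
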