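"""Seedable virtual ICU cohorts for exercising the prediction pipeline.

The clinical fluid dataset behind this kind of model is never public, so
the package ships two families of virtual patients emitted as raw event
logs in the same CSV schema the parser reads:

* *phase-profile patients* — phenomenological four-phase stays (rescue,
  optimization, stabilization, evacuation): high intake and low losses
  early, a CFB plateau, then net evacuation.  Defaults are calibrated so
  the cohort echoes a typical post-cardiac-surgery ICU population: length
  of stay 5 +/- 1 days and mean end-of-stay CFB of 1.67 L.
* *transfer-function ground-truth patients* — CFB generated by a known
  discrete-time transfer function from a piecewise-linear CFI, with
  optional Gaussian output noise; these make parameter recovery and
  closed-loop prediction exactness checkable.

All randomness flows from ``numpy.random.SeedSequence`` spawns, so any
cohort is reproducible from (n, seed) at every granularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import (
    CumulativeSeries,
    FluidEvent,
    PatientRecord,
    attach_series,
)
from .sysid import TransferFunctionModel, simulate_tf

__all__ = [
    "PhaseProfile",
    "GroundTruthPatient",
    "generate_phase_profile",
    "generate_events_from_profile",
    "generate_tf_patient",
    "generate_cohort",
]

_EPOCH = pd.Timestamp("2020-01-01 00:00")

#: mean phase durations in hours (sum = 120 h, a 5-day stay)
_MEAN_DURATIONS_H = (12.0, 30.0, 42.0, 36.0)
#: mean total intake rates per phase, mL/h (decreasing across phases)
_MEAN_INTAKE_RATES = (250.0, 150.0, 90.0, 70.0)
#: mean total loss rates per phase, mL/h (net evacuation at the end);
#: chosen so the expected end-of-stay CFB is 1.67 L
_MEAN_LOSS_RATES = (60.0, 100.0, 90.0, 128.6)


@dataclass(frozen=True)
class PhaseProfile:
    """Parameters of one four-phase virtual stay.

    Rates are total mL/h per phase; a fixed expected share of the intake
    is delivered as boluses, the rest as continuous/gravity infusions.
    """

    durations_h: tuple[float, float, float, float] = _MEAN_DURATIONS_H
    intake_rates_ml_h: tuple[float, float, float, float] = _MEAN_INTAKE_RATES
    loss_rates_ml_h: tuple[float, float, float, float] = _MEAN_LOSS_RATES
    bolus_rate_per_h: float = 0.15
    bolus_volume_ml: float = 100.0
    urine_interval_min: float = 120.0
    urine_fraction: float = 0.8
    gravity_missing_end_fraction: float = 0.3
    infusion_chunk_h: float = 6.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.durations_h):
            raise ValueError("phase durations must be positive")
        if any(r < 0 for r in self.intake_rates_ml_h + self.loss_rates_ml_h):
            raise ValueError("rates must be nonnegative")
        if not 0 <= self.gravity_missing_end_fraction <= 1:
            raise ValueError("gravity_missing_end_fraction must be in [0, 1]")

    @property
    def los_hours(self) -> float:
        return float(sum(self.durations_h))


@dataclass
class GroundTruthPatient:
    """A record whose CFB truly follows a known transfer function."""

    record: PatientRecord
    true_model: TransferFunctionModel
    noise_sd: float
    cfi_breakpoints_min: tuple[float, ...]
    n_clipped: int = 0


def _sym_jitter(rng: np.random.Generator, mean: float, rel_sd: float) -> float:
    """Mean-preserving multiplicative jitter (normal truncated at +/- 2 SD)."""
    z = rng.normal()
    while abs(z) > 2.0:
        z = rng.normal()
    return mean * (1.0 + rel_sd * z)


def generate_phase_profile(seed) -> PhaseProfile:
    """Draw one patient's phase profile around the calibrated defaults.

    The length of stay is a symmetric truncated normal (120 +/- 18 h,
    truncated at +/- 24 h) so every default-profile stay lies inside the
    4-7 day inclusion band; jittered phase weights split it into the four
    phases.
    """
    rng = np.random.default_rng(seed)
    los_h = rng.normal(120.0, 18.0)
    while not 96.0 <= los_h <= 144.0:
        los_h = rng.normal(120.0, 18.0)
    raw = np.array([_sym_jitter(rng, d, 0.15) for d in _MEAN_DURATIONS_H])
    durations = tuple(raw * (los_h / raw.sum()))
    intakes = tuple(_sym_jitter(rng, r, 0.10) for r in _MEAN_INTAKE_RATES)
    losses = tuple(_sym_jitter(rng, r, 0.10) for r in _MEAN_LOSS_RATES)
    return PhaseProfile(
        durations_h=durations,
        intake_rates_ml_h=intakes,
        loss_rates_ml_h=losses,
    )


_INTAKE_CATEGORY_CYCLE = ("crystalloid", "colloid", "medication", "parenteral_nutrition")


def generate_events_from_profile(
    profile: PhaseProfile,
    seed,
    patient_id: str = "synthetic",
) -> PatientRecord:
    """Emit a four-phase stay as a raw fluid event log.

    Intake per phase is delivered as ~6 h continuous infusion chunks (a
    configured fraction of them as gravity infusions with the end
    timestamp missing), plus occasional boluses drawn from the phase
    budget.  Losses are sparse urine documentation at the configured
    interval (cumulative urine is linear between entries) and periodic
    drainage entries.  Total intake and loss volumes match the phase
    budgets exactly, so the end-of-stay CFB is set by the profile.
    """
    rng = np.random.default_rng(seed)
    t0 = _EPOCH
    events: list[FluidEvent] = []
    phase_start_h = 0.0

    for p, dur_h in enumerate(profile.durations_h):
        intake_budget = profile.intake_rates_ml_h[p] * dur_h
        # boluses first: Poisson count, then the continuous remainder
        n_bolus = rng.poisson(profile.bolus_rate_per_h * dur_h)
        bolus_total = 0.0
        for _ in range(n_bolus):
            vol = max(_sym_jitter(rng, profile.bolus_volume_ml, 0.3), 0.0)
            if bolus_total + vol > 0.8 * intake_budget:
                break
            at = phase_start_h + rng.uniform(0, dur_h)
            events.append(
                FluidEvent(
                    patient_id=patient_id,
                    start_time=(t0 + pd.Timedelta(hours=at)).round("min"),
                    end_time=None,
                    direction="intake",
                    category="oral" if rng.random() < 0.5 else "medication",
                    volume_ml=round(vol, 1),
                    mode="bolus",
                )
            )
            bolus_total += round(vol, 1)

        continuous_total = intake_budget - bolus_total
        n_chunks = max(int(np.ceil(dur_h / profile.infusion_chunk_h)), 1)
        bounds = np.linspace(phase_start_h, phase_start_h + dur_h, n_chunks + 1)
        for ci in range(n_chunks):
            vol = continuous_total * (bounds[ci + 1] - bounds[ci]) / dur_h
            if vol <= 0:
                continue
            start = (t0 + pd.Timedelta(hours=bounds[ci])).round("min")
            end = (t0 + pd.Timedelta(hours=bounds[ci + 1])).round("min")
            gravity = rng.random() < profile.gravity_missing_end_fraction
            events.append(
                FluidEvent(
                    patient_id=patient_id,
                    start_time=start,
                    end_time=None if gravity else end,
                    direction="intake",
                    category=_INTAKE_CATEGORY_CYCLE[ci % len(_INTAKE_CATEGORY_CYCLE)],
                    volume_ml=round(vol, 3),
                    mode="gravity" if gravity else "continuous",
                )
            )

        phase_start_h += dur_h

    # losses: urine documented sparsely, drainage as periodic boluses
    los_h = profile.los_hours
    grid_h = np.arange(profile.urine_interval_min / 60.0, los_h, profile.urine_interval_min / 60.0)
    doc_times = np.append(grid_h, los_h)
    prev = 0.0
    for td in doc_times:
        # loss volume accrued since the previous documentation
        vol = 0.0
        a = prev
        cursor = 0.0
        for p, dur_h in enumerate(profile.durations_h):
            lo, hi = cursor, cursor + dur_h
            overlap = max(0.0, min(hi, td) - max(lo, a))
            vol += overlap * profile.loss_rates_ml_h[p]
            cursor = hi
        urine_vol = vol * profile.urine_fraction
        drain_vol = vol - urine_vol
        when = (t0 + pd.Timedelta(hours=float(td))).round("min")
        if urine_vol > 0:
            events.append(
                FluidEvent(
                    patient_id=patient_id,
                    start_time=when,
                    end_time=None,
                    direction="loss",
                    category="urine",
                    volume_ml=round(urine_vol, 3),
                    mode="bolus",
                )
            )
        if drain_vol > 0:
            events.append(
                FluidEvent(
                    patient_id=patient_id,
                    start_time=when,
                    end_time=None,
                    direction="loss",
                    category="drainage",
                    volume_ml=round(drain_vol, 3),
                    mode="bolus",
                )
            )
        prev = td

    events.sort(key=lambda e: e.start_time)
    record = PatientRecord(
        patient_id=patient_id,
        admission_time=t0,
        discharge_time=(t0 + pd.Timedelta(hours=los_h)).round("min"),
        events=events,
    )
    return record


# poles 0.9 and 0.8, DC gain 0.25: a well-damped patient retaining a
# quarter of the administered volume, so implied losses stay nondecreasing
_DEFAULT_TRUE_MODEL = TransferFunctionModel(b=(0.002, 0.003), a=(-1.7, 0.72))


def generate_tf_patient(
    true_model: TransferFunctionModel = _DEFAULT_TRUE_MODEL,
    cfi_segments: tuple[tuple[float, float], ...] = ((720.0, 4.0), (6480.0, 1.5)),
    noise_sd: float = 0.0,
    seed=0,
    patient_id: str = "tf_patient",
    loss_doc_interval_min: int = 10,
) -> GroundTruthPatient:
    """A patient whose CFB is exactly (or noisily) in the model class.

    ``cfi_segments`` is a piecewise-linear intake profile as
    (duration_min, rate_mL_per_min) pairs; the CFB is the transfer
    function's response to that CFI plus iid Gaussian noise of SD
    ``noise_sd`` liters.  Losses are back-derived as CFL = CFI - CFB and
    clipped to be nondecreasing (the clip count is reported).  The record
    carries exact minute series; its event log re-expresses the CFI as
    continuous infusions and the CFL as documentation entries every
    ``loss_doc_interval_min`` minutes.
    """
    rng = np.random.default_rng(seed)
    rates = np.concatenate(
        [np.full(int(round(d)), r / 1000.0) for d, r in cfi_segments]
    )
    cfi = np.concatenate(([0.0], np.cumsum(rates)))
    n = len(cfi)
    cfb = simulate_tf(true_model, cfi)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=n)
        noise[0] = 0.0  # the CFB offset is zero at admission by definition
        cfb = cfb + noise
    cfl = cfi - cfb
    cfl_mono = np.maximum.accumulate(cfl)
    n_clipped = int(np.sum(cfl_mono > cfl + 1e-12))
    cfl = cfl_mono
    cfb = cfi - cfl

    t0 = _EPOCH
    events: list[FluidEvent] = []
    cursor_min = 0.0
    for d, r in cfi_segments:
        if r > 0:
            events.append(
                FluidEvent(
                    patient_id=patient_id,
                    start_time=t0 + pd.Timedelta(minutes=cursor_min),
                    end_time=t0 + pd.Timedelta(minutes=cursor_min + d),
                    direction="intake",
                    category="crystalloid",
                    volume_ml=r * d,
                    mode="continuous",
                )
            )
        cursor_min += d
    # losses: cumulative-increment documentation entries
    doc_idx = np.arange(loss_doc_interval_min, n, loss_doc_interval_min)
    if len(doc_idx) == 0 or doc_idx[-1] != n - 1:
        doc_idx = np.append(doc_idx, n - 1)
    prev_val = 0.0
    for idx in doc_idx:
        inc = cfl[idx] - prev_val
        if inc > 0:
            events.append(
                FluidEvent(
                    patient_id=patient_id,
                    start_time=t0 + pd.Timedelta(minutes=int(idx)),
                    end_time=None,
                    direction="loss",
                    category="miscellaneous",
                    volume_ml=inc * 1000.0,
                    mode="bolus",
                )
            )
        prev_val = cfl[idx]

    events.sort(key=lambda e: e.start_time)
    record = PatientRecord(
        patient_id=patient_id,
        admission_time=t0,
        discharge_time=t0 + pd.Timedelta(minutes=n - 1),
        events=events,
    )
    # exact series attached directly; the event log is the CSV-facing view
    record.cfi = CumulativeSeries(t0=t0, values=cfi, kind="CFI")
    record.cfl = CumulativeSeries(t0=t0, values=cfl, kind="CFL")
    record.cfb = CumulativeSeries(t0=t0, values=cfb, kind="CFB")

    breakpoints = tuple(np.cumsum([d for d, _ in cfi_segments])[:-1])
    return GroundTruthPatient(
        record=record,
        true_model=true_model,
        noise_sd=noise_sd,
        cfi_breakpoints_min=breakpoints,
        n_clipped=n_clipped,
    )


def _random_stable_model(rng: np.random.Generator) -> TransferFunctionModel:
    """A random stable 2-pole/1-zero model with moderate DC gain."""
    p1 = rng.uniform(0.5, 0.95)
    p2 = rng.uniform(0.3, p1)
    a1, a2 = -(p1 + p2), p1 * p2
    dc_gain = rng.uniform(0.3, 0.9)
    # choose b0, b1 so that B(1)/A(1) = dc_gain; small positive feedthrough
    a_at_1 = 1.0 + a1 + a2
    b0 = rng.uniform(0.1, 0.5) * dc_gain * a_at_1
    b1 = dc_gain * a_at_1 - b0
    return TransferFunctionModel(b=(b0, b1), a=(a1, a2))


def _random_tf_patient(rng: np.random.Generator, pid: str, noise_sd: float) -> PatientRecord:
    los_min = int(round(np.clip(rng.normal(120.0, 24.0), 96.0, 168.0) * 60))
    bp = int(round(rng.uniform(0.2, 0.5) * los_min / 15.0)) * 15
    r1 = rng.uniform(2.5, 5.0)
    r2 = rng.uniform(0.5, 0.6 * r1)
    gt = generate_tf_patient(
        true_model=_random_stable_model(rng),
        cfi_segments=((float(bp), r1), (float(los_min - bp), r2)),
        noise_sd=noise_sd,
        seed=rng.integers(2**31),
        patient_id=pid,
    )
    return gt.record


def generate_cohort(
    n: int,
    seed: int = 0,
    tf_fraction: float = 0.3,
    tf_noise_sd: float = 0.05,
    n_out_of_band: int = 0,
    build_series: bool = True,
) -> list[PatientRecord]:
    """A deterministic mixed cohort of virtual patients.

    ``tf_fraction`` of the patients are transfer-function ground-truth
    patients (with output noise ``tf_noise_sd`` liters), the rest follow
    the four-phase profile; ``n_out_of_band`` additional patients get
    stays outside the 4-7 day inclusion band to exercise the exclusion
    filters.  Per-patient seeds are spawned from the cohort seed.
    """
    if n < 1:
        raise ValueError("need at least one patient")
    seeds = np.random.SeedSequence(seed).spawn(n + n_out_of_band)
    records: list[PatientRecord] = []
    width = len(str(n + n_out_of_band))
    for i in range(n):
        pid = f"P{i:0{width}d}"
        rng = np.random.default_rng(seeds[i])
        if rng.random() < tf_fraction:
            rec = _random_tf_patient(rng, pid, tf_noise_sd)
        else:
            profile = generate_phase_profile(seeds[i].spawn(1)[0])
            rec = generate_events_from_profile(profile, seeds[i].spawn(2)[1], patient_id=pid)
        records.append(rec)

    for j in range(n_out_of_band):
        pid = f"X{j:0{width}d}"
        rng = np.random.default_rng(seeds[n + j])
        short = rng.random() < 0.5
        los_h = rng.uniform(40.0, 90.0) if short else rng.uniform(170.0, 240.0)
        base = generate_phase_profile(seeds[n + j].spawn(1)[0])
        scale = los_h / sum(base.durations_h)
        profile = PhaseProfile(
            durations_h=tuple(d * scale for d in base.durations_h),
            intake_rates_ml_h=base.intake_rates_ml_h,
            loss_rates_ml_h=base.loss_rates_ml_h,
        )
        records.append(
            generate_events_from_profile(profile, seeds[n + j].spawn(2)[1], patient_id=pid)
        )

    if build_series:
        for rec in records:
            if rec.cfi is None:
                attach_series(rec)
    return records
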