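"""Event parsing, cohort filters, and cumulative series construction."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fluidbalance.records import (
    CumulativeSeries,
    FluidEvent,
    PatientRecord,
    attach_series,
    build_cumulative_series,
    compute_cfb,
    expand_event,
    parse_fluid_events,
    read_series_csv,
    validate_patient_record,
    write_events_csv,
    write_series_csv,
    GridMismatchError,
    EmptyRecordError,
)

T0 = pd.Timestamp("2020-01-01 00:00")


def _event(minute=0, direction="intake", category="crystalloid", volume=500.0,
           mode="bolus", end_minute=None, pid="p1"):
    return FluidEvent(
        patient_id=pid,
        start_time=T0 + pd.Timedelta(minutes=minute),
        end_time=None if end_minute is None else T0 + pd.Timedelta(minutes=end_minute),
        direction=direction,
        category=category,
        volume_ml=volume,
        mode=mode,
    )


def _record(events, los_minutes):
    return PatientRecord(
        patient_id="p1",
        admission_time=T0,
        discharge_time=T0 + pd.Timedelta(minutes=los_minutes),
        events=events,
    )


class TestFluidEvent:
    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            _event(volume=-100.0)

    def test_category_direction_mismatch_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            _event(direction="loss", category="crystalloid")

    def test_end_before_start_rejected(self):
        with pytest.raises(ValueError):
            _event(minute=10, end_minute=5, mode="continuous")


class TestParse:
    CSV = (
        "patient_id,start_time,end_time,direction,category,volume_ml,mode\n"
        "p1,2020-01-01T00:00,,intake,crystalloid,500,bolus\n"
    )

    def test_row_maps_to_event(self):
        recs, errs = parse_fluid_events(io.StringIO(self.CSV))
        assert not errs
        (rec,) = recs
        (ev,) = rec.events
        assert ev.patient_id == "p1"
        assert ev.category == "crystalloid"
        assert ev.volume_ml == 500.0
        assert ev.mode == "bolus"
        assert ev.end_time is None

    def test_negative_volume_becomes_row_error(self):
        csv = self.CSV + "p1,2020-01-01T01:00,,intake,crystalloid,-100,bolus\n"
        recs, errs = parse_fluid_events(io.StringIO(csv))
        assert len(errs) == 1
        assert errs[0].row == 1
        assert "negative" in errs[0].message
        assert len(recs[0].events) == 1  # good row survives

    @pytest.mark.parametrize(
        "bad_row,fragment",
        [
            ("p1,not-a-time,,intake,crystalloid,100,bolus", "timestamp"),
            ("p1,2020-01-01T01:00,,intake,plasma,100,bolus", "inconsistent"),
            ("p1,2020-01-01T01:00,,sideways,crystalloid,100,bolus", "direction"),
        ],
    )
    def test_malformed_rows_reported_with_index(self, bad_row, fragment):
        recs, errs = parse_fluid_events(io.StringIO(self.CSV + bad_row + "\n"))
        assert [e.row for e in errs] == [1]
        assert fragment in errs[0].message

    def test_empty_file(self):
        header = "patient_id,start_time,end_time,direction,category,volume_ml,mode\n"
        recs, errs = parse_fluid_events(io.StringIO(header))
        assert recs == [] and errs == []

    def test_events_sorted_by_start_time(self):
        csv = (
            "patient_id,start_time,end_time,direction,category,volume_ml,mode\n"
            "p1,2020-01-01T05:00,,intake,crystalloid,100,bolus\n"
            "p1,2020-01-01T01:00,,intake,oral,200,bolus\n"
        )
        recs, _ = parse_fluid_events(io.StringIO(csv))
        times = [e.start_time for e in recs[0].events]
        assert times == sorted(times)


class TestValidation:
    def _clean_events(self, los_minutes):
        # an event every 12 h keeps coverage gaps below threshold
        return [
            _event(minute=m, volume=100.0)
            for m in range(0, los_minutes + 1, 12 * 60)
        ]

    @pytest.mark.parametrize(
        "los_days,expect_included,expect_reason",
        [
            (5, True, None),
            (3, False, "los_below_min"),
            (8, False, "los_above_max"),
        ],
    )
    def test_length_of_stay_band(self, los_days, expect_included, expect_reason):
        los_min = los_days * 24 * 60
        rec = _record(self._clean_events(los_min), los_min)
        decision = validate_patient_record(rec)
        assert decision.included is expect_included
        if expect_reason:
            assert expect_reason in decision.reasons

    def test_coverage_gap_flagged(self):
        los_min = 5 * 24 * 60
        events = [_event(minute=0), _event(minute=los_min - 1)]  # ~5 d gap
        decision = validate_patient_record(_record(events, los_min))
        assert not decision.included
        assert "coverage_gap" in decision.reasons

    def test_empty_record_excluded(self):
        decision = validate_patient_record(_record([], 5 * 24 * 60))
        assert decision.reasons == ("empty_record",)

    def test_validation_is_pure(self):
        los_min = 5 * 24 * 60
        rec = _record(self._clean_events(los_min), los_min)
        assert validate_patient_record(rec) == validate_patient_record(rec)


class TestExpandEvent:
    N = 600

    def test_gravity_without_end_runs_at_16_ml_per_min(self):
        inc = expand_event(_event(minute=3, volume=160.0, mode="gravity"), T0, self.N)
        assert np.allclose(inc[3:13], 0.016)
        assert inc[:3].sum() == 0 and inc[13:].sum() == 0

    def test_gravity_remainder_in_final_minute(self):
        inc = expand_event(_event(minute=0, volume=40.0, mode="gravity"), T0, self.N)
        assert np.allclose(inc[:3], [0.016, 0.016, 0.008])

    def test_bolus_lands_in_its_minute(self):
        inc = expand_event(_event(minute=5, volume=250.0), T0, self.N)
        assert inc[5] == pytest.approx(0.250)
        assert inc.sum() == pytest.approx(0.250)

    def test_continuous_spread_uniformly(self):
        ev = _event(minute=0, end_minute=60, volume=120.0, mode="continuous")
        inc = expand_event(ev, T0, self.N)
        assert np.allclose(inc[:60], 0.002)
        assert inc.sum() == pytest.approx(0.120, abs=1e-12)

    def test_zero_duration_continuous_is_bolus(self):
        ev = _event(minute=7, end_minute=7, volume=50.0, mode="continuous")
        inc = expand_event(ev, T0, self.N)
        assert inc[7] == pytest.approx(0.050)

    def test_event_outside_grid_raises(self):
        with pytest.raises(ValueError, match="outside grid"):
            expand_event(_event(minute=self.N + 5), T0, self.N)

    @given(
        volume=st.floats(1.0, 5000.0),
        minute=st.integers(0, 500),
        mode=st.sampled_from(["bolus", "continuous", "gravity"]),
        duration=st.integers(1, 400),
    )
    def test_volume_conserved(self, volume, minute, mode, duration):
        end = minute + duration if mode == "continuous" else None
        ev = _event(minute=minute, end_minute=end, volume=volume, mode=mode)
        inc = expand_event(ev, T0, self.N)
        assert inc.sum() * 1000.0 == pytest.approx(volume, abs=1e-6)


class TestSeriesConstruction:
    def test_urine_is_linearly_interpolated(self):
        events = [
            _event(minute=0, direction="loss", category="urine", volume=0.0),
            _event(minute=60, direction="loss", category="urine", volume=120.0),
        ]
        rec = _record(events, 120)
        _, cfl = build_cumulative_series(rec)
        assert cfl.values[30] == pytest.approx(0.060)
        assert cfl.values[60] == pytest.approx(0.120)
        assert cfl.values[-1] == pytest.approx(0.120)  # held after last entry

    def test_single_bolus_step_hold(self):
        rec = _record([_event(minute=0, volume=1000.0)], 120)
        cfi, cfl = build_cumulative_series(rec)
        assert np.all(cfi.values == 1.0)
        assert np.all(cfl.values == 0.0)

    def test_drainage_steps(self):
        events = [
            _event(minute=10, direction="loss", category="drainage", volume=100.0),
            _event(minute=20, direction="loss", category="drainage", volume=50.0),
        ]
        rec = _record(events, 40)
        _, cfl = build_cumulative_series(rec)
        assert np.all(cfl.values[:10] == 0.0)
        assert np.all(cfl.values[10:20] == pytest.approx(0.100))
        assert np.all(cfl.values[20:] == pytest.approx(0.150))

    def test_empty_record_raises(self):
        with pytest.raises(EmptyRecordError):
            build_cumulative_series(_record([], 100))

    def test_cfi_cfl_nondecreasing(self, rng):
        events = []
        for _ in range(30):
            m = int(rng.integers(0, 500))
            if rng.random() < 0.5:
                events.append(_event(minute=m, volume=float(rng.uniform(10, 500))))
            else:
                events.append(
                    _event(minute=m, direction="loss", category="urine",
                           volume=float(rng.uniform(10, 300)))
                )
        cfi, cfl = build_cumulative_series(_record(events, 600))
        assert np.all(np.diff(cfi.values) >= -1e-12)
        assert np.all(np.diff(cfl.values) >= -1e-12)


class TestCFB:
    def test_identity_cancels(self):
        a = CumulativeSeries(t0=T0, values=np.arange(5.0), kind="CFI")
        b = CumulativeSeries(t0=T0, values=np.arange(5.0), kind="CFL")
        assert np.all(compute_cfb(a, b).values == 0.0)

    def test_elementwise_subtraction(self):
        cfi = CumulativeSeries(t0=T0, values=np.array([1.0, 2.0]), kind="CFI")
        cfl = CumulativeSeries(t0=T0, values=np.array([0.0, 0.5]), kind="CFL")
        assert np.allclose(compute_cfb(cfi, cfl).values, [1.0, 1.5])

    def test_rearrangement_property(self, rng):
        vals_i = np.cumsum(rng.uniform(0, 1, 100))
        vals_l = np.cumsum(rng.uniform(0, 1, 100))
        cfi = CumulativeSeries(t0=T0, values=vals_i, kind="CFI")
        cfl = CumulativeSeries(t0=T0, values=vals_l, kind="CFL")
        cfb = compute_cfb(cfi, cfl)
        assert np.allclose(cfb.values + cfl.values, cfi.values)

    def test_grid_mismatch_raises(self):
        cfi = CumulativeSeries(t0=T0, values=np.zeros(5), kind="CFI")
        cfl = CumulativeSeries(t0=T0, values=np.zeros(6), kind="CFL")
        with pytest.raises(GridMismatchError):
            compute_cfb(cfi, cfl)


class TestRoundTrip:
    def test_events_csv_round_trip_preserves_series(self, tmp_path):
        from fluidbalance.synthetic import generate_events_from_profile, generate_phase_profile

        rec = generate_events_from_profile(generate_phase_profile(3), 4, "p3")
        attach_series(rec)
        path = tmp_path / "events.csv"
        write_events_csv([rec], path)
        (rec2,), errs = parse_fluid_events(path)
        assert not errs
        attach_series(rec2)
        assert np.allclose(rec.cfi.values, rec2.cfi.values, atol=1e-12)
        assert np.allclose(rec.cfl.values, rec2.cfl.values, atol=1e-12)

    def test_series_csv_round_trip(self, tmp_path):
        rec = _record([_event(minute=0, volume=1000.0)], 120)
        attach_series(rec)
        path = tmp_path / "p1.csv"
        write_series_csv(rec, path)
        rec2 = read_series_csv(path)
        assert rec2.patient_id == "p1"
        assert np.allclose(rec2.cfb.values, rec.cfb.values)
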