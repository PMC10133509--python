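"""Sliding-window generation and the per-window prediction pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from fluidbalance.records import CumulativeSeries, PatientRecord
from fluidbalance.synthetic import generate_tf_patient
from fluidbalance.windowing import (
    WindowSpec,
    generate_windows,
    predict_window,
    results_to_frame,
    rezero_window,
    run_cohort,
    run_patient,
)

T0 = pd.Timestamp("2020-01-01")


def _series_record(n_minutes, pid="p1"):
    rec = PatientRecord(
        patient_id=pid,
        admission_time=T0,
        discharge_time=T0 + pd.Timedelta(minutes=n_minutes),
    )
    vals = np.linspace(0.0, 5.0, n_minutes + 1)
    rec.cfi = CumulativeSeries(t0=T0, values=vals, kind="CFI")
    rec.cfl = CumulativeSeries(t0=T0, values=vals * 0.4, kind="CFL")
    rec.cfb = CumulativeSeries(t0=T0, values=vals * 0.6, kind="CFB")
    return rec


class TestGenerateWindows:
    @pytest.mark.parametrize(
        "los_h,est_h,expected",
        [(96, 48, 13), (72, 48, 1), (71, 48, 0), (48, 24, 1), (47, 24, 0)],
    )
    def test_window_counts(self, los_h, est_h, expected):
        rec = _series_record(los_h * 60)
        assert len(generate_windows(rec, est_h)) == expected

    def test_starts_are_two_hour_steps_from_admission(self):
        rec = _series_record(96 * 60)
        starts = [w.start_min for w in generate_windows(rec, 48)]
        assert starts == list(range(0, 1441, 120))

    @given(los_h=st.integers(48, 200), est_h=st.sampled_from([24, 48, 72, 96, 120]))
    def test_count_matches_enumeration(self, los_h, est_h):
        rec = _series_record(los_h * 60)
        windows = generate_windows(rec, est_h)
        # brute-force enumeration of feasible starts
        feasible = [
            s for s in range(0, los_h * 60 + 1, 120)
            if s + (est_h + 24) * 60 <= los_h * 60
        ]
        assert [w.start_min for w in windows] == feasible

    def test_longer_estimation_never_more_windows(self):
        rec = _series_record(130 * 60)
        counts = [len(generate_windows(rec, e)) for e in (24, 48, 72, 96)]
        assert counts == sorted(counts, reverse=True)


class TestRezero:
    def test_offset_subtracted(self):
        rec = _series_record(72 * 60)
        rec.cfb.values = rec.cfb.values + 3.0
        w = WindowSpec("p1", 0, 24)
        est, pred = rezero_window(rec.cfb, w)
        assert est[0] == 0.0
        assert len(est) == 24 * 60 + 1
        assert len(pred) == 24 * 60 + 1
        assert pred[0] == est[-1]  # shared junction sample, same frame

    def test_mid_series_window_starts_at_zero(self):
        rec = _series_record(96 * 60)
        w = WindowSpec("p1", 240, 48)
        est, _ = rezero_window(rec.cfb, w)
        assert est[0] == 0.0

    def test_rezeroing_is_idempotent(self):
        rec = _series_record(72 * 60)
        w = WindowSpec("p1", 0, 24)
        est1, pred1 = rezero_window(rec.cfb, w)
        rezeroed = CumulativeSeries(
            t0=T0, values=np.concatenate([est1, pred1[1:]]), kind="CFB"
        )
        est2, pred2 = rezero_window(rezeroed, w)
        assert np.allclose(est2, est1) and np.allclose(pred2, pred1)

    def test_window_past_series_end_rejected(self):
        rec = _series_record(47 * 60)
        with pytest.raises(ValueError, match="past the end"):
            rezero_window(rec.cfb, WindowSpec("p1", 0, 24))


class TestPredictWindow:
    def test_exact_for_in_class_patient(self):
        gt = generate_tf_patient(noise_sd=0.0, seed=5)
        w = generate_windows(gt.record, 48)[0]
        res = predict_window(gt.record, w)
        assert abs(res.endpoint_error_by_horizon[24]) < 0.01
        assert res.rmse_by_horizon[24] < 0.01

    def test_series_lengths_match(self):
        gt = generate_tf_patient(noise_sd=0.02, seed=6)
        w = generate_windows(gt.record, 24)[2]
        res = predict_window(gt.record, w)
        assert len(res.predicted_cfb) == len(res.actual_cfb) == 24 * 60 + 1

    def test_too_short_record_rejected(self):
        rec = _series_record(40 * 60)
        with pytest.raises(ValueError):
            predict_window(rec, WindowSpec("p1", 0, 24))

    def test_horizon_maps_rmse_and_endpoint(self):
        gt = generate_tf_patient(noise_sd=0.0, seed=7)
        w = generate_windows(gt.record, 48)[0]
        res = predict_window(gt.record, w)
        assert set(res.rmse_by_horizon) == {8, 12, 16, 20, 24}
        assert all(v >= 0 for v in res.rmse_by_horizon.values())


class TestCohort:
    def _records(self, n=3):
        return [
            generate_tf_patient(noise_sd=0.02, seed=i, patient_id=f"p{i}").record
            for i in range(n)
        ]

    def test_counts_match_recount(self):
        recs = self._records()
        results, counts = run_cohort(recs, estimation_hours=(24, 48))
        frame = results_to_frame(results)
        for est in (24, 48):
            n = counts.loc[counts["estimation_h"] == est, "n_predictions"].item()
            assert n == (frame["estimation_h"] == est).sum()

    def test_empty_cohort(self):
        results, counts = run_cohort([], estimation_hours=(24,))
        assert results == []
        assert counts["n_predictions"].sum() == 0

    def test_deterministic_runs(self):
        recs = self._records(2)
        f1 = results_to_frame(run_cohort(recs, estimation_hours=(24,))[0])
        f2 = results_to_frame(run_cohort(recs, estimation_hours=(24,))[0])
        pd.testing.assert_frame_equal(f1, f2)

    def test_patient_count_per_estimation_time(self):
        recs = self._records(3)  # all stays exceed 72 h
        _, counts = run_cohort(recs, estimation_hours=(48,))
        assert counts.loc[counts["estimation_h"] == 48, "n_patients"].item() == 3

    def test_run_patient_orders_windows(self):
        rec = self._records(1)[0]
        results = run_patient(rec, estimation_hours=(24,))
        starts = [r.window.start_min for r in results]
        assert starts == sorted(starts)
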