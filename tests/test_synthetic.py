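import numpy as np
import pandas as pd
import pytest

from spo2delta import (
    HypoxiaProtocol,
    ReferencePoint,
    SyntheticCohortSpec,
    batch_delta,
    calibrate_irregularity,
    cox_fit,
    fit_reference,
    gen_patient_cohort,
    gen_reference_population,
    gen_spo2_signal,
    qc_record,
    sample_entropy,
)
from spo2delta.exceptions import CalibrationRangeError, DegenerateInputError
from spo2delta.signal_io import RawRecord


class TestGenSignal:
    def test_quantized_signal_is_integer(self):
        seg = gen_spo2_signal(96.0, 0.3, 300, seed=0, quantize=True)
        assert np.all(seg.values == np.round(seg.values))
        assert seg.values.min() >= 0 and seg.values.max() <= 100

    def test_realised_mean_near_target(self):
        for seed in range(5):
            seg = gen_spo2_signal(92.0, 0.4, 480, seed=seed, quantize=True)
            assert abs(seg.mean_spo2 - 92.0) <= 0.005 * 92.0

    def test_deterministic_limit_low_entropy(self):
        seg = gen_spo2_signal(97.0, 0.0, 480, seed=1)
        assert sample_entropy(seg.values).value < 0.15

    def test_irregularity_raises_entropy(self):
        lo = [sample_entropy(gen_spo2_signal(96.0, 0.0, 480, s).values).value
              for s in range(15)]
        hi = [sample_entropy(gen_spo2_signal(96.0, 0.5, 480, s).values).value
              for s in range(15)]
        assert np.mean(hi) > np.mean(lo)

    def test_same_seed_reproducible(self):
        a = gen_spo2_signal(95.0, 0.3, 200, seed=9)
        b = gen_spo2_signal(95.0, 0.3, 200, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            gen_spo2_signal(96.0, 1.5, 300, 0)
        with pytest.raises(ValueError):
            gen_spo2_signal(40.0, 0.1, 300, 0)
        with pytest.raises(DegenerateInputError):
            gen_spo2_signal(96.0, 0.1, 5, 0)


class TestCalibrate:
    def test_boundary_target_returns_small_p(self):
        base = np.mean([sample_entropy(
            gen_spo2_signal(96.0, 0.0, 480, s).values).value for s in range(10)])
        p = calibrate_irregularity(base, duration_s=480, seed=0, reps=8)
        assert p < 0.05

    def test_closed_loop_hits_target(self):
        target = 0.6
        p = calibrate_irregularity(target, duration_s=480, seed=1, reps=15)
        fresh = [sample_entropy(gen_spo2_signal(96.0, p, 480, 500 + s).values).value
                 for s in range(40)]
        assert abs(np.mean(fresh) - target) <= 0.15 * target

    def test_targets_monotone_in_p(self):
        ps = [calibrate_irregularity(t, duration_s=480, seed=2, reps=8)
              for t in (0.3, 0.7, 1.2)]
        assert ps[0] < ps[1] < ps[2]

    def test_unreachable_target_raises_with_interval(self):
        with pytest.raises(CalibrationRangeError) as exc:
            calibrate_irregularity(5.0, duration_s=480, seed=0, reps=5)
        assert exc.value.achievable_high < 5.0


class TestReferencePopulation:
    def test_one_row_per_level_when_single_subject(self):
        proto = HypoxiaProtocol(n_subjects=(1, 1, 1, 1))
        tab = gen_reference_population(proto, seed=0)
        assert len(tab) == 4
        assert sorted(tab["fio2"]) == [12.0, 14.5, 17.0, 21.0]

    def test_inverse_relationship_and_fit_quality(self):
        tab = gen_reference_population(seed=4)
        pts = [ReferencePoint(fio2=r.fio2, mean_spo2=r.mean_spo2, sampen=r.sampen)
               for r in tab.itertuples()]
        line = fit_reference(pts)
        assert line.slope < 0
        assert line.r_squared > 0.9

    def test_signals_pass_qc_at_protocol_duration(self):
        proto = HypoxiaProtocol(n_subjects=(2, 1, 1, 1))
        _, signals = gen_reference_population(proto, seed=0, return_signals=True)
        for seg in signals.values():
            rec = RawRecord(seg.subject_id, np.arange(len(seg)), seg.values)
            assert qc_record(rec, proto.exposure_duration_s).passed

    def test_invalid_protocol(self):
        with pytest.raises(ValueError):
            HypoxiaProtocol(fio2_levels=(21.0, 21.0), n_subjects=(2, 2))


class TestPatientCohort:
    def test_feature_level_round_trip_exact(self, line):
        co = gen_patient_cohort(SyntheticCohortSpec(n=100), line, seed=3)
        np.testing.assert_allclose(co["delta"], co["delta_planted"], atol=1e-9)

    def test_stratum_sizes_and_censoring(self, line):
        spec = SyntheticCohortSpec(n=164)
        co = gen_patient_cohort(spec, line, seed=8)
        assert co["event"].sum() == round(164 * spec.nonsurvivor_frac)
        assert (co.loc[co.event == 0, "time_days"] == spec.horizon).all()
        assert (co["time_days"] <= spec.horizon).all()

    def test_sampen_stays_nonnegative(self, line):
        co = gen_patient_cohort(SyntheticCohortSpec(n=400), line, seed=5)
        assert (co["sampen"] > 0).all()

    def test_same_seed_bit_reproducible(self, line):
        spec = SyntheticCohortSpec(n=50)
        a = gen_patient_cohort(spec, line, seed=11)
        b = gen_patient_cohort(spec, line, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_hazard_driven_null_beta_covered(self, line):
        spec = SyntheticCohortSpec(n=400, beta={"delta": 0.0},
                                   baseline_rate=0.02)
        co = gen_patient_cohort(spec, line, seed=21)
        z = (co["delta"] - co["delta"].mean()) / co["delta"].std(ddof=1)
        fit = cox_fit(pd.DataFrame({"delta": z}), co["time_days"], co["event"])
        e = fit.effect("delta")
        assert e.ci95_low < 1.0 < e.ci95_high

    def test_delta_column_consistent_with_line(self, line):
        co = gen_patient_cohort(SyntheticCohortSpec(n=30), line, seed=2)
        redo = batch_delta(co[["mean_spo2", "sampen"]], line)
        np.testing.assert_allclose(co["delta"], redo["delta"], atol=1e-12)

    def test_signal_level_signals_pass_qc(self, line):
        spec = SyntheticCohortSpec(n=3, mode="signal_level",
                                   signal_duration_s=600)
        co, signals = gen_patient_cohort(spec, line, seed=1, return_signals=True)
        assert len(signals) == 3
        for sid, seg in signals.items():
            rec = RawRecord(sid, np.arange(len(seg)), seg.values)
            assert qc_record(rec, 600).passed
        # features recomputed from the signal, not the planted values
        first = next(iter(signals.values()))
        assert co.iloc[0]["mean_spo2"] == pytest.approx(first.mean_spo2)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SyntheticCohortSpec(n=1)
        with pytest.raises(ValueError):
            SyntheticCohortSpec(mode="bogus")
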