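"""Continuous traces, onset rules, AUC oracle, cohort evaluation."""

import numpy as np
import pytest

from pgesdet.crops import CropSpec
from pgesdet.infer import (
    DetectionResult,
    EvaluationReport,
    OnsetRule,
    ProbabilityTrace,
    crop_auc,
    detect_onset,
    evaluate_cohort,
    export_trace_plot,
    probability_trace,
)
from pgesdet.io import MontagedRecording

from conftest import RmsProbe, make_flat_montaged


def _trace(probs, stride=0.1, window=10.0):
    probs = np.asarray(probs, dtype=float)
    times = window + stride * np.arange(len(probs))
    return ProbabilityTrace("t0", times, probs)


class TestProbabilityTrace:
    def test_grid_length_and_first_time(self):
        m = make_flat_montaged(n_montages=2, duration_s=300.0, rate_hz=20.0)
        tr = probability_trace(RmsProbe(), m, CropSpec(10.0, 0.1, 10.0))
        assert len(tr.times_s) == 2901
        assert tr.times_s[0] == 10.0
        assert abs(tr.times_s[-1] - 300.0) < 1e-9

    def test_whole_recording_is_scanned_past_annotation(self):
        # unlike training crops, the trace continues beyond pges_end + latency
        m = make_flat_montaged(n_montages=2, duration_s=100.0, rate_hz=20.0,
                               pges_end_s=20.0)
        tr = probability_trace(RmsProbe(), m, CropSpec(10.0, 0.5, 10.0))
        assert tr.times_s[-1] > 30.0 + 1e-9

    def test_batching_does_not_change_values(self):
        m = make_flat_montaged(n_montages=2, duration_s=60.0, rate_hz=20.0)
        spec = CropSpec(10.0, 0.5, 10.0)
        a = probability_trace(RmsProbe(), m, spec, batch_size=7)
        b = probability_trace(RmsProbe(), m, spec, batch_size=256)
        np.testing.assert_allclose(a.probs, b.probs, rtol=1e-6)

    def test_too_short_recording_rejected(self):
        m = make_flat_montaged(n_montages=2, duration_s=5.0, rate_hz=20.0,
                               pges_end_s=None)
        with pytest.raises(ValueError, match="shorter than one window"):
            probability_trace(RmsProbe(), m, CropSpec(10.0, 0.5, 10.0))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="length"):
            ProbabilityTrace("x", [1.0, 2.0], [0.5])
        with pytest.raises(ValueError, match="constant step"):
            ProbabilityTrace("x", [1.0, 2.0, 4.0], [0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            ProbabilityTrace("x", [1.0, 2.0], [0.5, 1.5])

    def test_causality_of_trace_values(self):
        """Changing samples after time t never changes trace values <= t."""
        m = make_flat_montaged(n_montages=2, duration_s=60.0, rate_hz=20.0, seed=3)
        spec = CropSpec(10.0, 0.5, 10.0)
        base = probability_trace(RmsProbe(), m, spec)
        t_cut = 30.0
        tampered = MontagedRecording(
            m.recording_id, list(m.montage_labels), m.data.copy(),
            m.sampling_rate_hz, m.pges_end_s,
        )
        tampered.data[:, int(t_cut * m.sampling_rate_hz):] += 500.0
        after = probability_trace(RmsProbe(), tampered, spec)
        sel = base.times_s <= t_cut + 1e-9
        np.testing.assert_array_equal(base.probs[sel], after.probs[sel])
        assert not np.array_equal(base.probs[~sel], after.probs[~sel])


class TestOnsetRule:
    def test_rule_contract(self):
        with pytest.raises(ValueError):
            OnsetRule(threshold=0.0)
        with pytest.raises(ValueError):
            OnsetRule(k_consecutive=0)

    def test_step_trace_detected_at_run_start(self):
        probs = [0.1] * 50 + [0.9] * 50
        det = detect_onset(_trace(probs), OnsetRule(0.5, 3))
        assert det.detected_s == 10.0 + 0.1 * 50

    def test_short_spike_rejected_by_k(self):
        probs = [0.1] * 20 + [0.9] * 2 + [0.1] * 20 + [0.9] * 5
        det = detect_onset(_trace(probs), OnsetRule(0.5, 3))
        assert det.detected_s == pytest.approx(10.0 + 0.1 * 42)

    def test_no_detection_below_threshold(self):
        det = detect_onset(_trace([0.4] * 100), OnsetRule(0.5, 3))
        assert det.detected_s is None

    def test_threshold_exactly_met_counts(self):
        det = detect_onset(_trace([0.5] * 10), OnsetRule(0.5, 3))
        assert det.detected_s == 10.0

    def test_k_equals_one(self):
        probs = [0.1, 0.9, 0.1]
        det = detect_onset(_trace(probs), OnsetRule(0.5, 1))
        assert det.detected_s == pytest.approx(10.1)

    def test_detection_time_monotone_in_threshold(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            tr = _trace(rng.random(80))
            prev = -np.inf
            for thr in (0.2, 0.5, 0.8):
                det = detect_onset(tr, OnsetRule(thr, 3))
                t = np.inf if det.detected_s is None else det.detected_s
                assert t >= prev
                prev = t


class TestDetectionScoring:
    def test_timely_detection_is_correct(self):
        d = DetectionResult("r", detected_s=32.0, true_end_s=30.0, latency_s=10.0)
        assert d.correct and not d.false_alarm
        assert d.latency_error_s == 2.0

    def test_boundaries_inclusive(self):
        assert DetectionResult("r", 30.0, 30.0, 10.0).correct
        assert DetectionResult("r", 40.0, 30.0, 10.0).correct
        assert not DetectionResult("r", 40.1, 30.0, 10.0).correct

    def test_early_detection_is_false_alarm(self):
        d = DetectionResult("r", detected_s=25.0, true_end_s=30.0, latency_s=10.0)
        assert d.false_alarm and not d.correct

    def test_missing_detection_is_incorrect(self):
        d = DetectionResult("r", detected_s=None, true_end_s=30.0, latency_s=10.0)
        assert not d.correct and not d.false_alarm
        assert d.latency_error_s is None


class TestCropAuc:
    def test_reference_example(self):
        assert crop_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_and_inverted(self):
        assert crop_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert crop_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_all_tied_scores_give_half(self):
        assert crop_auc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            crop_auc([0.1, 0.9], [1, 1])

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(99)
        for case in range(100):
            n = int(rng.integers(4, 40))
            # discrete score levels force ties
            scores = rng.choice([0.0, 0.25, 0.5, 0.75, 1.0], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum(
                1.0 if p > q else (0.5 if p == q else 0.0)
                for p in pos for q in neg
            )
            expected = wins / (len(pos) * len(neg))
            assert crop_auc(scores, labels) == pytest.approx(expected, abs=1e-12), case

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(5)
        scores = rng.random(200)
        labels = rng.integers(0, 2, size=200)
        assert crop_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


class _TimecodeOracle:
    """Reads the window end time back out of a ramp channel and compares it
    to a known suppression end: a perfect detector for evaluation-logic tests."""

    def __init__(self, true_end_s):
        self.true_end_s = true_end_s

    def predict_proba_crops(self, X):
        ends = np.asarray(X)[:, 0, -1]  # channel 0 encodes time in seconds
        return (ends >= self.true_end_s - 1e-9).astype(float)


class _ConstantModel:
    def __init__(self, p):
        self.p = p

    def predict_proba_crops(self, X):
        return np.full(len(X), self.p)


def _ramp_recording(rid="ramp0", duration=60.0, rate=20.0, pges=25.0):
    n = int(duration * rate)
    # sample i carries the time of its own end, so the last sample of a
    # window [s, e) reads exactly e
    t = (np.arange(n) + 1) / rate
    data = np.vstack([t, np.zeros(n)])
    return MontagedRecording(rid, ["time", "zero"], data, rate, pges)


class TestEvaluateCohort:
    def test_oracle_model_scores_perfectly(self):
        recs = [_ramp_recording(f"r{i}", pges=20.0 + 5 * i) for i in range(3)]
        spec = CropSpec(10.0, 0.5, 10.0)
        reports = []
        for r in recs:
            rep = evaluate_cohort(_TimecodeOracle(r.pges_end_s), [r], spec)
            reports.append(rep)
            assert rep.auc_pooled == 1.0
            assert rep.detection_rate == 1.0
            assert rep.false_alarm_rate == 0.0
            # detection at the first grid time >= true end
            err = rep.per_recording["latency_error_s"].iloc[0]
            assert 0.0 <= err < 0.5 + 1e-9

    def test_constant_model_is_chance_with_no_timely_detection(self):
        r = _ramp_recording(pges=25.0)
        rep = evaluate_cohort(_ConstantModel(0.5), [r], CropSpec(10.0, 0.5, 10.0))
        assert rep.auc_pooled == 0.5
        assert rep.detection_rate == 0.0

    def test_unannotated_only_rejected(self):
        m = make_flat_montaged(pges_end_s=None)
        with pytest.raises(ValueError, match="no annotated"):
            evaluate_cohort(_ConstantModel(0.2), [m])

    def test_report_save(self, tmp_path):
        r = _ramp_recording(pges=25.0)
        rep = evaluate_cohort(_TimecodeOracle(25.0), [r], CropSpec(10.0, 0.5, 10.0))
        out = rep.save(tmp_path / "report")
        assert (out / "report.json").exists()
        assert (out / "per_recording.csv").exists()
        import json

        loaded = json.loads((out / "report.json").read_text())
        assert loaded["n_recordings"] == 1

    def test_coarse_trace_stride_override(self):
        r = _ramp_recording(pges=25.0)
        rep = evaluate_cohort(
            _TimecodeOracle(25.0), [r], CropSpec(10.0, 0.5, 10.0),
            trace_stride_s=1.0,
        )
        assert rep.detection_rate == 1.0


class TestPlot:
    def test_plot_file_written(self, tmp_path):
        m = make_flat_montaged(n_montages=3, duration_s=30.0, rate_hz=20.0,
                               pges_end_s=15.0)
        tr = probability_trace(RmsProbe(), m, CropSpec(10.0, 0.5, 10.0))
        det = detect_onset(tr)
        out = export_trace_plot(m, tr, tmp_path / "fig.png",
                                true_end_s=15.0, detection=det)
        assert out.exists() and out.stat().st_size > 1000

    def test_plot_without_annotation_or_detection(self, tmp_path):
        m = make_flat_montaged(n_montages=2, duration_s=30.0, rate_hz=20.0)
        tr = probability_trace(RmsProbe(), m, CropSpec(10.0, 0.5, 10.0))
        out = export_trace_plot(m, tr, tmp_path / "fig2.png")
        assert out.exists()
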