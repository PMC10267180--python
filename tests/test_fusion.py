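"""Fusion, delay arithmetic, thresholding and onset-detection contracts."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytostress.config import ConfigError
from phytostress.fusion import (
    OnsetError,
    PredictionTrace,
    combine_predictions,
    delay_hours,
    delay_minutes,
    detect_stress_onset,
    prediction_delay,
    read_trace_csv,
    threshold_trace,
    write_trace_csv,
)


def make_trace(confs, window_s=16.0, fused=False):
    confs = np.asarray(confs, dtype=float)
    return PredictionTrace(
        plant_id="B0",
        start_times=np.arange(len(confs)) * window_s,
        confidences=confs,
        window_length_s=window_s,
        fused=fused,
        fusion_params={"L": 1, "method": "mean"} if fused else None,
    )


def brute_causal_fuse(c, l, method):
    """Independent oracle: explicit python loop over shrinking windows."""
    fn = np.mean if method == "mean" else np.median
    return np.array([fn(c[max(0, i - l + 1) : i + 1]) for i in range(len(c))])


class TestCombinePredictions:
    def test_constant_trace_unchanged(self):
        for method in ("mean", "median"):
            for l in (1, 2, 7):
                out = combine_predictions(make_trace([0.3] * 9), l, method)
                assert np.allclose(out.confidences, 0.3)

    def test_hand_computed_mean_l2(self):
        out = combine_predictions(make_trace([1, 0, 1, 1]), 2, "mean")
        assert np.allclose(out.confidences, [1.0, 0.5, 0.5, 1.0])

    def test_hand_computed_median_l3(self):
        # warm-up: med[1]=med(1,0)=0.5 (even-count midpoint), med[2]=med(1,0,1)=1
        out = combine_predictions(make_trace([1, 0, 1, 1]), 3, "median")
        assert np.allclose(out.confidences, [1.0, 0.5, 1.0, 1.0])

    def test_invalid_l(self):
        with pytest.raises(ConfigError):
            combine_predictions(make_trace([0.5]), 0, "mean")

    def test_refusing_to_refuse(self):
        fused = combine_predictions(make_trace([0.2, 0.8]), 2, "mean")
        with pytest.raises(ValueError, match="already fused"):
            combine_predictions(fused, 2, "mean")

    def test_output_metadata(self):
        out = combine_predictions(make_trace([0.2, 0.8]), 2, "median")
        assert out.fused
        assert out.fusion_params == {"L": 2, "method": "median"}
        assert len(out) == 2

    @settings(max_examples=60, deadline=None)
    @given(
        confs=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
        l=st.integers(1, 12),
        method=st.sampled_from(["mean", "median"]),
    )
    def test_matches_brute_force(self, confs, l, method):
        out = combine_predictions(make_trace(confs), l, method)
        assert np.allclose(out.confidences, brute_causal_fuse(np.asarray(confs), l, method))

    @settings(max_examples=60, deadline=None)
    @given(
        confs=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=40),
        l=st.integers(1, 12),
        method=st.sampled_from(["mean", "median"]),
    )
    def test_causality_property(self, confs, l, method):
        """Changing raw confidences at indices > i never changes fused[<=i]."""
        c = np.asarray(confs)
        cut = len(c) // 2
        tampered = c.copy()
        tampered[cut:] = 1.0 - tampered[cut:]
        a = combine_predictions(make_trace(c), l, method).confidences
        b = combine_predictions(make_trace(tampered), l, method).confidences
        assert np.allclose(a[:cut], b[:cut])

    @settings(max_examples=60, deadline=None)
    @given(
        confs=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40),
        l=st.integers(1, 12),
        method=st.sampled_from(["mean", "median"]),
    )
    def test_bounds_property(self, confs, l, method):
        """Fused value i lies within [min, max] of its raw source window."""
        c = np.asarray(confs)
        fused = combine_predictions(make_trace(c), l, method).confidences
        for i in range(len(c)):
            lo, hi = max(0, i - l + 1), i + 1
            assert c[lo:hi].min() - 1e-12 <= fused[i] <= c[lo:hi].max() + 1e-12

    def test_mean_permutation_symmetry(self):
        """Mean fusion only sees the multiset of the last L raw values."""
        rng = np.random.default_rng(0)
        c = rng.random(20)
        l = 6
        c2 = c.copy()
        c2[-l:] = rng.permutation(c2[-l:])
        a = combine_predictions(make_trace(c), l, "mean").confidences
        b = combine_predictions(make_trace(c2), l, "mean").confidences
        assert np.isclose(a[-1], b[-1])

    def test_fusion_gain_on_constant_label_segment(self):
        """Analytic cross-check: i.i.d. confidences with accuracy p > 0.5 on
        an all-stressed segment; mean fusion must raise accuracy with L,
        consistent with the normal approximation of the fused mean."""
        rng = np.random.default_rng(1)
        p = 0.7
        n = 4000
        correct = rng.random(n) < p
        conf = np.where(correct, rng.uniform(0.55, 1.0, n), rng.uniform(0.0, 0.45, n))
        raw_acc = float((conf >= 0.5).mean())
        accs = [raw_acc]
        for l in (10, 100):
            fused = combine_predictions(make_trace(conf), l, "mean").confidences
            accs.append(float((fused >= 0.5).mean()))
        assert accs[0] < accs[1] <= accs[2]
        # normal approximation: P(mean of L confidences >= 0.5) for large L
        mu = conf.mean()
        sd = conf.std() / np.sqrt(100)
        from scipy.stats import norm

        approx = 1.0 - norm.cdf((0.5 - mu) / sd)
        assert abs(accs[2] - approx) < 0.05


class TestPredictionDelay:
    def test_l1000_16s_is_4_44_hours(self):
        assert prediction_delay(1000, 16.0) == 16000.0
        assert delay_hours(1000, 16.0) == 4.44

    def test_l10_16s_is_2_66_minutes(self):
        assert prediction_delay(10, 16.0) == 160.0
        assert delay_minutes(10, 16.0) == 2.66

    def test_single_window_delay(self):
        for s in (1.0, 4.0, 16.0):
            assert prediction_delay(1, s) == s


class TestThresholdTrace:
    def test_tie_goes_to_stressed(self):
        out = threshold_trace(make_trace([0.49, 0.50, 0.51]), 0.5)
        assert out.tolist() == [0, 1, 1]

    def test_all_zero(self):
        assert threshold_trace(make_trace([0.0, 0.0]), 0.5).tolist() == [0, 0]

    def test_custom_threshold(self):
        out = threshold_trace(make_trace([0.6, 0.7]), 0.65)
        assert out.tolist() == [0, 1]


class TestDetectStressOnset:
    def test_first_peak_above_threshold(self):
        trace = make_trace([0.2, 0.7, 0.6, 0.9], fused=True)
        res = detect_stress_onset(trace, 0.65)
        assert res.onset_time == trace.start_times[1]

    def test_no_peak_below_threshold(self):
        trace = make_trace([0.2, 0.6, 0.3], fused=True)
        assert detect_stress_onset(trace, 0.65).onset_time is None

    def test_monotone_rise_peaks_at_end(self):
        trace = make_trace([0.1, 0.3, 0.5, 0.7, 0.9], fused=True)
        res = detect_stress_onset(trace, 0.65)
        assert res.onset_time == trace.start_times[-1]

    def test_plateau_not_a_peak_until_drop(self):
        # 0.7 plateau: index 1 rises and index 2 does not drop below, so the
        # first index satisfying strict-rise/>=-next is index 1
        trace = make_trace([0.2, 0.7, 0.7, 0.2], fused=True)
        res = detect_stress_onset(trace, 0.65)
        assert res.onset_time == trace.start_times[1]

    def test_search_from_skips_early_peaks(self):
        trace = make_trace([0.9, 0.1, 0.1, 0.8, 0.2], fused=True)
        res = detect_stress_onset(trace, 0.65, search_from=trace.start_times[1])
        assert res.onset_time == trace.start_times[3]

    def test_empty_trace_raises(self):
        trace = make_trace([], fused=True)
        with pytest.raises(OnsetError):
            detect_stress_onset(trace, 0.65)

    def test_onset_time_is_a_trace_start_time(self):
        rng = np.random.default_rng(2)
        trace = make_trace(rng.random(50), fused=True)
        res = detect_stress_onset(trace, 0.66)
        if res.onset_time is not None:
            assert res.onset_time in trace.start_times


class TestTraceInvariantsAndIo:
    def test_confidence_bounds_enforced(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            make_trace([0.5, 1.2])

    def test_strictly_increasing_times_enforced(self):
        with pytest.raises(ValueError, match="increasing"):
            PredictionTrace("B0", np.array([0.0, 0.0]), np.array([0.1, 0.2]), 16.0)

    def test_csv_round_trip(self, tmp_path):
        trace = combine_predictions(make_trace([0.1, 0.9, 0.4]), 2, "median")
        path = write_trace_csv(trace, tmp_path / "t.csv")
        back = read_trace_csv(path)
        assert np.allclose(back.confidences, trace.confidences)
        assert back.fused and back.fusion_params == {"L": 2, "method": "median"}
        assert back.plant_id == "B0"
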