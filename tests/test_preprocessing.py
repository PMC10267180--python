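"""Conditioning-chain oracles: every transform is checked against an
independent brute-force computation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytostress.config import ConfigError, ProtocolParams
from phytostress.io import Recording
from phytostress.preprocessing import (
    LabelError,
    WindowSet,
    compute_plant_extrema,
    downsample,
    label_windows,
    make_windows,
    normalize,
    notch_filter,
    read_windows,
    rolling_median,
    simplify,
    write_windows,
)


def brute_rolling_median(x: np.ndarray, n: int) -> np.ndarray:
    """Independent oracle: explicit centered, truncated windows."""
    hl, hr = (n - 1) // 2, n // 2
    out = np.empty(len(x))
    for i in range(len(x)):
        lo, hi = max(0, i - hl), min(len(x), i + hr + 1)
        out[i] = np.median(x[lo:hi])
    return out


def rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.asarray(x) ** 2)))


class TestNotchFilter:
    FS = 500.0

    def test_dc_passes(self):
        x = np.full(4000, 3.7)
        y = notch_filter(x, self.FS, [50.0, 100.0])
        assert np.max(np.abs(y - x)) / 3.7 < 1e-6

    def test_50hz_attenuated_20db(self):
        t = np.arange(0, 10, 1 / self.FS)
        x = np.sin(2 * np.pi * 50.0 * t)
        y = notch_filter(x, self.FS, [50.0, 100.0])
        atten_db = 20 * np.log10(rms(y) / rms(x))
        assert atten_db <= -20.0

    def test_5hz_nearly_untouched(self):
        t = np.arange(0, 10, 1 / self.FS)
        x = np.sin(2 * np.pi * 5.0 * t)
        y = notch_filter(x, self.FS, [50.0, 100.0])
        atten_db = 20 * np.log10(rms(y) / rms(x))
        assert atten_db > -1.0

    def test_length_preserved(self):
        x = np.random.default_rng(0).standard_normal(1234)
        assert len(notch_filter(x, self.FS, [50.0])) == 1234

    def test_frequency_at_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            notch_filter(np.zeros(100), 100.0, [50.0])


class TestRollingMedian:
    def test_constant_signal_identity(self):
        x = np.full(37, 2.5)
        for n in (1, 2, 3, 50):
            assert np.array_equal(rolling_median(x, n), x)

    def test_hand_computed_example(self):
        # centered truncated windows: [1,9] [1,9,2] [9,2,8] [2,8,3] [8,3]
        x = np.array([1.0, 9.0, 2.0, 8.0, 3.0])
        expected = np.array([5.0, 2.0, 8.0, 3.0, 5.5])
        assert np.array_equal(rolling_median(x, 3), expected)

    def test_n1_identity(self):
        x = np.random.default_rng(1).standard_normal(20)
        assert np.array_equal(rolling_median(x, 1), x)

    def test_invalid_n(self):
        with pytest.raises(ConfigError):
            rolling_median(np.zeros(5), 0)

    def test_matches_brute_force_1000_random_cases(self):
        """Property: vectorized implementation == per-position brute force."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n_samples = int(rng.integers(1, 40))
            n = int(rng.integers(1, 12))
            x = rng.standard_normal(n_samples)
            assert np.allclose(rolling_median(x, n), brute_rolling_median(x, n))

    @settings(max_examples=100, deadline=None)
    @given(
        data=st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=60),
        n=st.integers(1, 15),
    )
    def test_matches_brute_force_hypothesis(self, data, n):
        x = np.asarray(data)
        assert np.allclose(rolling_median(x, n), brute_rolling_median(x, n))

    def test_even_window_uses_mean_of_middles(self):
        # N=2 window at i covers [i, i+1]: medians are pairwise means
        x = np.array([0.0, 1.0, 3.0])
        assert np.array_equal(rolling_median(x, 2), np.array([0.5, 2.0, 3.0]))


class TestDownsample:
    def test_index_enumeration(self):
        assert np.array_equal(downsample(np.arange(6), 2), np.array([0, 2, 4]))

    def test_f1_identity(self):
        x = np.arange(7.0)
        assert np.array_equal(downsample(x, 1), x)

    def test_16s_window_at_500hz_f10(self):
        # 16 s x 500 Hz = 8000 samples -> 800 after decimation by 10
        assert len(downsample(np.zeros(8000), 10)) == 800

    def test_invalid_factor(self):
        with pytest.raises(ConfigError):
            downsample(np.zeros(5), 0)


class TestSimplify:
    def test_window_count_floor(self):
        fs = 50.0
        rec = Recording("B0", fs, np.zeros(int(100 * fs)), 10.0, 20.0)
        ws = simplify(rec, 16.0, 50, 10)
        assert ws.n_windows == 100 // 16  # trailing partial window discarded
        assert ws.window_samples == int(16 * fs) // 10
        assert ws.fs_effective == fs / 10

    def test_full_scale_window_arithmetic(self):
        # 15 days at 500 Hz with 16 s windows: floor(15*86400/16) windows of
        # 16*500/10 samples (arithmetic only; the array is never materialized)
        assert 15 * 86400 // 16 == 81000
        assert 16 * 500 // 10 == 800

    def test_constant_recording_constant_windows(self):
        rec = Recording("B0", 50.0, np.full(50 * 64, 1.25), 10.0, 20.0)
        ws = simplify(rec, 16.0, 50, 10)
        assert np.all(ws.windows == 1.25)

    def test_equivalence_with_independent_chain(self, desk_recording):
        """simplify row k == downsample(brute_rolling_median(raw window k))."""
        s, n, f = 16.0, 50, 10
        ws = simplify(desk_recording, s, n, f)
        win = int(s * desk_recording.fs)
        rng = np.random.default_rng(5)
        for k in rng.choice(ws.n_windows, size=8, replace=False):
            raw = desk_recording.samples[k * win : (k + 1) * win]
            expected = brute_rolling_median(raw, n)[::f]
            assert np.allclose(ws.windows[k], expected)

    def test_short_recording_warns_and_is_empty(self):
        rec = Recording("B0", 50.0, np.zeros(100), 0.5, 1.0)
        with pytest.warns(UserWarning, match="shorter"):
            ws = simplify(rec, 16.0, 50, 10)
        assert ws.n_windows == 0

    def test_plant_order_independence(self, desk_cohort):
        parts_fwd = [simplify(r, 16.0, 50, 10) for r in desk_cohort[:3]]
        parts_rev = [simplify(r, 16.0, 50, 10) for r in reversed(desk_cohort[:3])]
        a = WindowSet.concatenate(parts_fwd)
        b = WindowSet.concatenate(list(reversed(parts_rev)))
        assert np.array_equal(a.windows, b.windows)
        assert np.array_equal(a.plant_ids, b.plant_ids)


class TestMakeWindows:
    def test_4s_windows_at_500hz_have_2000_samples(self):
        fs = 500.0
        rec = Recording("B0", fs, np.zeros(int(8 * fs)), 2.0, 4.0)
        ws = make_windows(rec, 4.0)
        assert ws.window_samples == 2000
        assert ws.n_windows == 2

    def test_30s_downsampled_by_3_gives_5000(self):
        fs = 500.0
        rec = Recording("B0", fs, np.zeros(int(30 * fs)), 10.0, 20.0)
        ws = make_windows(rec, 30.0, extra_downsample=3)
        assert ws.window_samples == 5000

    def test_exact_division(self):
        rec = Recording("B0", 50.0, np.zeros(500), 2.0, 4.0)
        ws = make_windows(rec, 1.0)
        assert ws.n_windows == 10

    def test_no_overlap_stride_equals_length(self):
        rec = Recording("B0", 50.0, np.arange(500.0), 2.0, 4.0)
        ws = make_windows(rec, 1.0)
        assert np.allclose(np.diff(ws.start_times), 1.0)
        # consecutive windows tile the signal without overlap
        assert np.array_equal(ws.windows.reshape(-1), np.arange(500.0))


class TestLabelWindows:
    @pytest.fixture()
    def rec(self):
        fs = 10.0
        n = int(fs * 4000)
        return Recording("B0", fs, np.zeros(n), stimulus_time=1000.0, symptom_time=2000.0)

    def protocol(self, hours: float, mode: str = "post_symptom") -> ProtocolParams:
        return ProtocolParams(train_hours_per_state=hours, mode=mode)

    def test_window_at_start_is_normal(self, rec):
        ws = label_windows(make_windows(rec, 10.0), rec, self.protocol(800 / 3600))
        assert ws.labels[0] == 0

    def test_window_at_symptom_time_is_stressed(self, rec):
        ws = label_windows(make_windows(rec, 10.0), rec, self.protocol(800 / 3600))
        idx = int(np.argmin(np.abs(ws.start_times - rec.symptom_time)))
        assert ws.start_times[idx] == rec.symptom_time
        assert ws.labels[idx] == 1

    def test_window_straddling_span_boundary_excluded(self, rec):
        # span of 795 s does not divide the 10 s window grid: the window
        # straddling t0+795 must be -1
        ws = label_windows(make_windows(rec, 10.0), rec, self.protocol(795 / 3600))
        straddler = int(790 // 10)
        assert ws.start_times[straddler] == 790.0
        assert ws.labels[straddler] == -1
        assert ws.labels[straddler - 1] == 0

    def test_transition_windows_unlabelled(self, rec):
        ws = label_windows(make_windows(rec, 10.0), rec, self.protocol(800 / 3600))
        mid = (ws.start_times > rec.stimulus_time) & (
            ws.start_times + 10.0 < rec.symptom_time
        )
        assert np.all(ws.labels[mid] == -1)

    def test_extended_mode_labels_tail(self, rec):
        ws = label_windows(make_windows(rec, 10.0), rec, self.protocol(800 / 3600, "extended"))
        end = rec.t0 + rec.duration_s
        tail = ws.start_times >= end - 800.0
        assert np.all(ws.labels[tail] == 1)

    def test_span_exceeding_recording_raises(self, rec):
        with pytest.raises(LabelError):
            label_windows(make_windows(rec, 10.0), rec, self.protocol(3000 / 3600))

    def test_balanced_label_counts(self, rec):
        ws = label_windows(make_windows(rec, 10.0), rec, self.protocol(800 / 3600))
        assert (ws.labels == 0).sum() == (ws.labels == 1).sum() == 80


class TestNormalize:
    def make_ws(self, rows, pids=None):
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        n = rows.shape[0]
        pids = np.asarray(pids) if pids is not None else np.full(n, "B0")
        starts = np.empty(n)
        for pid in np.unique(pids):
            m = pids == pid
            starts[m] = np.arange(m.sum()) * 16.0
        return WindowSet(rows, pids, starts, np.zeros(n, int), 5.0, 16.0)

    def test_per_window_minmax_formula(self):
        ws = normalize(self.make_ws([[2.0, 4.0, 6.0]]), "per_window_minmax")
        assert np.allclose(ws.windows[0], [0.0, 0.5, 1.0])

    def test_per_window_minmax_idempotent_on_unit_range(self):
        ws0 = self.make_ws([[0.0, 0.25, 1.0]])
        ws1 = normalize(ws0, "per_window_minmax")
        assert np.allclose(ws1.windows, ws0.windows)

    def test_per_window_demean_formula(self):
        ws = normalize(self.make_ws([[2.0, 4.0, 6.0]]), "per_window_demean")
        assert np.allclose(ws.windows[0], [-2.0, 0.0, 2.0])
        assert abs(ws.windows[0].mean()) < 1e-9

    def test_constant_window_maps_to_zeros(self):
        ws = normalize(self.make_ws([[3.0, 3.0, 3.0]]), "per_window_minmax")
        assert np.all(ws.windows == 0.0)

    def test_none_is_identity(self):
        ws0 = self.make_ws([[1.0, -5.0, 2.0]])
        assert np.array_equal(normalize(ws0, "none").windows, ws0.windows)

    def test_per_plant_minmax_uses_plant_extrema(self):
        ws0 = self.make_ws(
            [[0.0, 5.0], [5.0, 10.0], [100.0, 200.0]],
            pids=["A", "A", "B"],
        )
        ws = normalize(ws0, "per_plant_minmax",
                       {"A": (0.0, 10.0), "B": (100.0, 200.0)})
        assert np.allclose(ws.windows[0], [0.0, 0.5])
        assert np.allclose(ws.windows[1], [0.5, 1.0])
        assert np.allclose(ws.windows[2], [0.0, 1.0])

    def test_per_plant_extrema_from_labelled_only(self):
        ws0 = self.make_ws([[0.0, 1.0], [10.0, 20.0]])
        ws0.labels[1] = -1  # test-period window must not leak into extrema
        ext = compute_plant_extrema(ws0)
        assert ext["B0"] == (0.0, 1.0)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
    def test_minmax_bounds_property(self, data):
        row = np.asarray(data)
        ws = normalize(self.make_ws([row]), "per_window_minmax")
        out = ws.windows[0]
        assert out.min() >= -1e-12 and out.max() <= 1 + 1e-12
        if row.max() > row.min():
            assert np.isclose(out.min(), 0.0) and np.isclose(out.max(), 1.0)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
    def test_demean_zero_mean_property(self, data):
        ws = normalize(self.make_ws([np.asarray(data)]), "per_window_demean")
        assert abs(ws.windows[0].mean()) < 1e-9

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigError):
            normalize(self.make_ws([[1.0, 2.0]]), "zscore")


class TestWindowSetSerialization:
    def test_round_trip(self, tmp_path, toy_recording):
        ws = simplify(toy_recording, 16.0, 50, 10)
        path = write_windows(ws, tmp_path / "w.h5")
        back = read_windows(path)
        assert np.array_equal(back.windows, ws.windows)
        assert np.array_equal(back.plant_ids, ws.plant_ids)
        assert np.array_equal(back.labels, ws.labels)
        assert back.fs_effective == ws.fs_effective
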