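"""Feature formulas against brute-force oracles; detectors against truth."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from vo2wear import SimParams, SubjectInfo, simulate_subject
from vo2wear.features import (
    BeatSeries,
    dapt_series,
    detect_breaths,
    detect_r_peaks,
    build_feature_frame,
    hr_max,
    hr_percent,
    hr_series,
    mads_series,
    read_feature_frame,
    resample_1hz,
    rr_series,
    smooth_ma,
    svm_series,
    write_feature_frame,
)
from vo2wear.preprocess import filter_ecg, filter_respiration, respiration_response


# ---------------------------------------------------------------------------
# Closed-form feature oracles (brute-force, loop-based recomputation)
# ---------------------------------------------------------------------------

class TestFormulaOracles:
    def test_hr_from_rr_intervals_random(self):
        rng = np.random.default_rng(11)
        rr = rng.uniform(0.3, 2.0, 1000)
        hr = 60.0 / rr
        oracle = np.array([60.0 / v for v in rr])
        np.testing.assert_allclose(hr, oracle, rtol=1e-12)

    def test_hr_max_arithmetic(self):
        assert hr_max(40) == pytest.approx(180.0)
        assert hr_max(24) == pytest.approx(191.2)
        with pytest.raises(ValueError):
            hr_max(0)

    def test_hr_percent(self):
        assert hr_percent(95.6, 24) == pytest.approx(50.0)
        assert hr_percent(hr_max(31), 31) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            hr_percent(0.0, 24)

    def test_rr_from_peak_intervals(self):
        b = _breaths_from_peaks([0.0, 3.0, 8.0])
        _, rates = rr_series(b)
        np.testing.assert_allclose(rates, [20.0, 12.0])

    def test_rr_constant_spacing(self):
        b = _breaths_from_peaks(np.arange(10) * 4.0 + 1.0)
        _, rates = rr_series(b)
        np.testing.assert_allclose(rates, 15.0)

    def test_svm_random_against_bruteforce(self):
        rng = np.random.default_rng(5)
        x, y, z = rng.normal(size=(3, 1000))
        got = svm_series(x, y, z)
        oracle = np.array([np.sqrt(a * a + b * b + c * c) for a, b, c in zip(x, y, z)])
        np.testing.assert_allclose(got, oracle, rtol=1e-9)

    def test_svm_examples(self):
        np.testing.assert_allclose(svm_series([3.0], [4.0], [0.0]), [5.0])
        np.testing.assert_allclose(svm_series([1.0], [1.0], [1.0]), [np.sqrt(3.0)])
        np.testing.assert_allclose(svm_series([0.0], [0.0], [0.0]), [0.0])

    def test_mads_random_against_bruteforce(self):
        rng = np.random.default_rng(6)
        svm = rng.normal(size=1000)
        got = mads_series(svm, T=1.0, fs=25.0)
        oracle = []
        for k in range(len(svm) // 25):
            block = svm[k * 25 : (k + 1) * 25]
            oracle.append(sum(abs(block[i + 1] - block[i]) for i in range(24)) / 24.0)
        np.testing.assert_allclose(got, oracle, rtol=1e-9)

    def test_mads_examples(self):
        assert mads_series(np.full(50, 3.3))[0] == 0.0
        alternating = np.tile([0.0, 1.0], 13)[:25]
        assert mads_series(alternating)[0] == pytest.approx(1.0)
        ramp = np.arange(25) * 0.25
        assert mads_series(ramp)[0] == pytest.approx(0.25)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        axes=hnp.arrays(
            float,
            (3, 50),
            elements=st.floats(-10, 10, allow_nan=False),
        ),
        perm=st.permutations([0, 1, 2]),
        signs=st.tuples(*[st.sampled_from([-1.0, 1.0])] * 3),
    )
    def test_svm_invariant_under_axis_permutation_and_sign_flips(
        self, axes, perm, signs
    ):
        base = svm_series(*axes)
        flipped = [signs[i] * axes[perm[i]] for i in range(3)]
        np.testing.assert_allclose(svm_series(*flipped), base, rtol=1e-12, atol=1e-12)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(
        svm=hnp.arrays(float, 75, elements=st.floats(-5, 5, allow_nan=False)),
        shift=st.floats(-100, 100, allow_nan=False),
    )
    def test_mads_invariant_under_constant_shift(self, svm, shift):
        np.testing.assert_allclose(
            mads_series(svm + shift), mads_series(svm), rtol=1e-9, atol=1e-9
        )

    def test_dapt_examples(self):
        b = _breaths(peaks=[(1.0, 2.0), (4.0, 1.0)], troughs=[(0.5, -1.0), (3.5, 1.0)])
        _, d = dapt_series(b)
        np.testing.assert_allclose(d, [3.0, 0.0])


def _breaths_from_peaks(peak_times):
    peak_times = np.asarray(peak_times, dtype=float)
    return _breaths(
        peaks=[(t, 1.0) for t in peak_times],
        troughs=[(t - 0.5, -1.0) for t in peak_times],
    )


def _breaths(peaks, troughs):
    from vo2wear.features import BreathSeries

    return BreathSeries(
        peak_times=np.array([t for t, _ in peaks]),
        peak_amplitudes=np.array([a for _, a in peaks]),
        trough_times=np.array([t for t, _ in troughs]),
        trough_amplitudes=np.array([a for _, a in troughs]),
    )


# ---------------------------------------------------------------------------
# Heart-rate windowing
# ---------------------------------------------------------------------------

class TestHrSeries:
    def test_uniform_spacing(self):
        beats = BeatSeries.from_peaks(np.arange(0.5, 60.0, 1.0))
        np.testing.assert_allclose(hr_series(beats, 60), 60.0)
        beats = BeatSeries.from_peaks(np.arange(0.25, 60.0, 0.5))
        np.testing.assert_allclose(hr_series(beats, 60), 120.0)

    def test_windowed_mean_against_bruteforce(self):
        """Trailing-window HR equals a loop-based recomputation."""
        rng = np.random.default_rng(3)
        intervals = rng.uniform(0.4, 1.4, 120)
        peaks = np.concatenate([[0.2], 0.2 + np.cumsum(intervals)])
        beats = BeatSeries.from_peaks(peaks)
        n = int(peaks[-1])
        got = hr_series(beats, n)
        expected = np.full(n, np.nan)
        for t in range(n):
            vals = [
                60.0 / rr
                for rr, end in zip(beats.rr_intervals, beats.rr_end_times)
                if t - 4.0 < end <= t
            ]
            if vals:
                expected[t] = np.mean(vals)
        expected = pd.Series(expected).ffill().bfill().to_numpy()
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_gap_carried_forward(self):
        peaks = np.concatenate([np.arange(0.5, 10.0, 1.0), [20.0, 21.0]])
        beats = BeatSeries.from_peaks(peaks)
        hr = hr_series(beats, 20)
        # ticks 14..19 have no interval in their window -> carry forward
        assert np.all(hr[14:20] == hr[13])

    def test_depends_only_on_peak_times(self):
        peaks = np.arange(0.5, 30.0, 0.75)
        a = hr_series(BeatSeries.from_peaks(peaks), 30)
        b = hr_series(BeatSeries.from_peaks(peaks.copy()), 30)
        np.testing.assert_array_equal(a, b)

    def test_empty_beats(self):
        with pytest.raises(ValueError, match="no beats"):
            hr_series(BeatSeries.from_peaks(np.array([1.0])), 10)

    def test_physiological_gate_drops_extreme_intervals(self):
        peaks = np.array([0.0, 0.1, 1.1, 2.1, 6.0])  # 0.1 s and 3.9 s gated out
        beats = BeatSeries.from_peaks(peaks)
        np.testing.assert_allclose(beats.rr_intervals, [1.0, 1.0])


# ---------------------------------------------------------------------------
# Detectors
# ---------------------------------------------------------------------------

def _f1(det, tru, tol):
    det, tru = np.asarray(det), np.asarray(tru)
    used = np.zeros(len(tru), bool)
    tp = 0
    for d in det:
        i = int(np.argmin(np.abs(tru - d)))
        if abs(tru[i] - d) <= tol and not used[i]:
            used[i] = True
            tp += 1
    precision = tp / len(det) if len(det) else 0.0
    recall = tp / len(tru)
    return 2 * precision * recall / (precision + recall) if precision + recall else 0.0


def _synthetic_ecg(spacing, duration, fs=200.0, snr_db=None, seed=0):
    rng = np.random.default_rng(seed)
    truth = np.arange(0.5, duration - 0.5, spacing)
    t = np.arange(int(duration * fs)) / fs
    x = np.zeros_like(t)
    for bt in truth:
        x += np.exp(-0.5 * ((t - bt) / 0.01) ** 2)
    if snr_db is not None:
        x = x + rng.normal(0, np.sqrt(np.mean(x**2)) * 10 ** (-snr_db / 20), len(t))
    return x, truth


class TestRPeakDetection:
    def test_clean_one_hz_train(self):
        x, truth = _synthetic_ecg(1.0, 60.0)
        beats = detect_r_peaks(filter_ecg(x))
        assert abs(len(beats.r_peak_times) - 60) <= 1
        for d in beats.r_peak_times:
            assert np.min(np.abs(truth - d)) <= 0.010

    def test_flat_signal(self):
        with pytest.raises(ValueError, match="no QRS detected"):
            detect_r_peaks(np.zeros(4000))

    def test_noisy_120bpm_f1(self):
        x, truth = _synthetic_ecg(0.5, 60.0, snr_db=20.0, seed=1)
        beats = detect_r_peaks(filter_ecg(x))
        assert _f1(beats.r_peak_times, truth, tol=0.05) >= 0.99

    def test_refractory_enforced(self):
        x, _ = _synthetic_ecg(1.0, 30.0)
        beats = detect_r_peaks(filter_ecg(x))
        assert np.all(np.diff(beats.r_peak_times) >= 0.2)


class TestBreathDetection:
    def test_quarter_hz_sinusoid(self):
        t = np.arange(int(60 * 25)) / 25.0
        filtered = filter_respiration(np.sin(2 * np.pi * 0.25 * t))
        br = detect_breaths(filtered)
        assert abs(len(br.peak_times) - 15) <= 1
        gain = respiration_response(np.array([0.25]))[0]
        _, dapt = dapt_series(br)
        # unit sinusoid: peak - trough = 2 before filter attenuation
        expected = 2.0 * gain
        assert np.all(np.abs(dapt[1:-1] - expected) < 0.1)

    def test_constant_signal(self):
        with pytest.raises(ValueError, match="too few breaths"):
            detect_breaths(np.ones(3000))

    def test_amplitude_ramp_gives_nondecreasing_dapt(self):
        t = np.arange(int(120 * 25)) / 25.0
        amp = 1.0 + t / 120.0
        filtered = filter_respiration(amp * np.sin(2 * np.pi * 0.25 * t))
        _, dapt = dapt_series(detect_breaths(filtered))
        interior = dapt[2:-2]
        assert np.all(np.diff(interior) > -0.05)

    def test_troughs_precede_peaks(self):
        t = np.arange(int(90 * 25)) / 25.0
        br = detect_breaths(filter_respiration(np.sin(2 * np.pi * 0.2 * t)))
        assert np.all(br.trough_times < br.peak_times)


# ---------------------------------------------------------------------------
# Resampling and smoothing
# ---------------------------------------------------------------------------

class TestResample1hz:
    def test_constant_support(self):
        out = resample_1hz([0.0, 10.0], [10.0, 10.0], 11)
        np.testing.assert_allclose(out, 10.0)

    def test_linear_data_reproduced(self):
        out = resample_1hz([0.0, 5.0, 10.0], [0.0, 5.0, 10.0], 11)
        np.testing.assert_allclose(out, np.arange(11.0), atol=1e-12)

    def test_no_overshoot_beyond_envelope(self):
        times = [0.0, 2.0, 4.0, 6.0, 8.0]
        values = [1.0, 3.0, 10.0, 3.0, 1.0]
        out = resample_1hz(times, values, 9)
        assert out.max() <= 10.0 + 1e-12
        assert out.min() >= 1.0 - 1e-12

    def test_extrapolation_clamps_to_endpoints(self):
        out = resample_1hz([3.0, 5.0], [1.0, 2.0], 10)
        assert np.all(out[:3] == 1.0)
        assert np.all(out[6:] == 2.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            resample_1hz([1.0], [2.0], 5)


class TestSmoothMa:
    def test_constant_preserved(self):
        np.testing.assert_allclose(smooth_ma(np.full(100, 7.2)), 7.2)

    def test_impulse_spreads_to_one_thirty_first(self):
        x = np.zeros(101)
        x[50] = 1.0
        y = smooth_ma(x)
        assert y[50] == pytest.approx(1 / 31)

    def test_linear_ramp_interior_unchanged(self):
        x = np.arange(100.0)
        y = smooth_ma(x)
        np.testing.assert_allclose(y[15:-15], x[15:-15], atol=1e-9)

    def test_length_preserved_with_edges_renormalized(self):
        y = smooth_ma(np.ones(10))
        assert len(y) == 10
        np.testing.assert_allclose(y, 1.0)


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

class TestBuildFeatureFrame:
    def test_tracks_generative_truth(self, sim_pair):
        """Extracted HR/RR track the smoothed generative truth closely."""
        rec, truth = sim_pair
        frame = build_feature_frame(rec)
        n = len(frame)
        hr_truth = smooth_ma(truth.hr[:n])
        rr_truth = smooth_ma(truth.rr[:n])
        assert np.mean(np.abs(frame["hr"].to_numpy() - hr_truth)) < 2.0
        assert np.mean(np.abs(frame["rr"].to_numpy() - rr_truth)) < 1.0

    def test_columns_share_time_base(self, sim_pair):
        rec, _ = sim_pair
        frame = build_feature_frame(rec)
        assert list(frame["t"]) == list(range(len(frame)))
        for col in ("hr", "hr_pct", "rr", "dapt", "mads", "vo2"):
            assert frame[col].notna().all()
        assert (frame["hr"] > 0).all()
        assert (frame["mads"] >= 0).all()

    def test_prediction_only_when_vo2_missing(self, sim_pair):
        rec, _ = sim_pair
        import copy

        rec2 = copy.copy(rec)
        rec2.channels = {k: v for k, v in rec.channels.items() if k != "vo2_ref"}
        with pytest.warns(UserWarning, match="prediction-only"):
            frame = build_feature_frame(rec2)
        assert "vo2" not in frame.columns
        assert frame.attrs["prediction_only"]

    def test_unlabeled_gap(self, sim_pair):
        rec, _ = sim_pair
        import copy

        rec2 = copy.copy(rec)
        rec2.activities = [a for a in rec.activities if a.label != "walk"]
        frame = build_feature_frame(rec2)
        walk = next(a for a in rec.activities if a.label == "walk")
        sel = (frame["t"] >= walk.t_start) & (frame["t"] < walk.t_end)
        assert (frame.loc[sel, "activity"] == "unlabeled").all()

    def test_round_trip_serialization(self, sim_pair, tmp_path):
        rec, _ = sim_pair
        frame = build_feature_frame(rec)
        path = tmp_path / "frame.csv"
        write_feature_frame(frame, path)
        back = read_feature_frame(path)
        assert back.attrs["subject"].subject_id == rec.subject.subject_id
        np.testing.assert_allclose(back["hr"], frame["hr"], rtol=1e-9)
        assert list(back.columns) == [c for c in frame.columns]
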