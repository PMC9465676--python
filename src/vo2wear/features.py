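"""Feature extraction: HR, HR%, RR, DApt, MADs and the 1 Hz feature frame.

The model inputs are derived per modality and then synchronised to the 1 Hz
grid of the reference gas analyser:

* heart rate from ECG R-R intervals, ``HR = 60 / rr`` averaged over a
  trailing 4 s window stepped at 1 s, and its fraction of the age-predicted
  maximum ``HRmax = 208 - 0.7 * age``;
* respiration rate ``RR = 60 / (peak-to-peak interval)`` and the per-breath
  peak-to-trough amplitude difference DApt, an uncalibrated tidal-volume
  proxy;
* motion intensity as the mean absolute successive difference of the
  acceleration signal-vector magnitude (MADs) over non-overlapping 1 s
  blocks.

Per-breath values are resampled to 1 Hz with shape-preserving (monotone
cubic, PCHIP) interpolation; all traces are finally smoothed with a centred
31-point moving average, mirroring the conditioning applied to the
reference VO2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from . import preprocess
from .io import Recording

__all__ = [
    "BeatSeries",
    "BreathSeries",
    "detect_r_peaks",
    "hr_series",
    "hr_max",
    "hr_percent",
    "detect_breaths",
    "rr_series",
    "dapt_series",
    "svm_series",
    "mads_series",
    "resample_1hz",
    "smooth_ma",
    "build_feature_frame",
    "write_feature_frame",
    "read_feature_frame",
    "FEATURE_COLUMNS",
]

#: Canonical column order of the serialized feature frame.
FEATURE_COLUMNS = ["t", "hr", "hr_pct", "rr", "dapt", "mads", "vo2", "activity"]

#: Physiological gate on R-R intervals, seconds (20–250 BPM).
RR_GATE = (0.24, 3.0)


@dataclass(frozen=True)
class BeatSeries:
    """Detected R-peak times (s) and the gated successive R-R intervals."""

    r_peak_times: np.ndarray
    rr_intervals: np.ndarray  # seconds; entries outside the gate removed
    rr_end_times: np.ndarray  # time of the terminating peak of each interval

    @classmethod
    def from_peaks(cls, peak_times: np.ndarray) -> "BeatSeries":
        t = np.asarray(peak_times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("r_peak_times must be strictly increasing")
        rr = np.diff(t)
        keep = (rr >= RR_GATE[0]) & (rr <= RR_GATE[1])
        return cls(t, rr[keep], t[1:][keep])


@dataclass(frozen=True)
class BreathSeries:
    """Paired respiratory peaks and troughs.

    Each retained peak is paired with the nearest preceding trough; DApt per
    breath is ``peak_amplitude - trough_amplitude`` and is non-negative for
    any genuine oscillation.
    """

    peak_times: np.ndarray
    peak_amplitudes: np.ndarray
    trough_times: np.ndarray
    trough_amplitudes: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.trough_times >= self.peak_times):
            raise ValueError("each trough must precede its paired peak")


# ---------------------------------------------------------------------------
# R-peak detection (Hamilton / "E. P. Limited" open-source rules)
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float = 200.0) -> BeatSeries:
    """Detect QRS complexes in a band-passed (3–45 Hz) ECG.

    Implements the Hamilton open-source detector rules: rectified first
    difference, 80 ms moving-window integration, adaptive amplitude
    threshold from running QRS/noise peak medians, a 200 ms refractory
    period, a T-wave slope veto inside 360 ms, and a 1.5-RR search-back at
    half threshold. R times are refined to the local ECG maximum within
    ±100 ms of each integrator peak.
    """
    x = np.asarray(ecg, dtype=float)
    if len(x) < fs:
        raise ValueError("no QRS detected: signal too short")

    dx = np.abs(np.diff(x, prepend=x[0]))
    win = max(1, int(round(0.08 * fs)))
    mwi = np.convolve(dx, np.ones(win) / win, mode="same")

    # candidate peaks of the integrated signal
    cand, _ = sps.find_peaks(mwi, distance=max(1, int(round(0.2 * fs))))
    if len(cand) == 0:
        raise ValueError("no QRS detected")

    qrs_buf: list[float] = []
    noise_buf: list[float] = []
    rr_buf: list[float] = []
    detections: list[int] = []

    def threshold() -> float:
        q = np.mean(qrs_buf[-8:]) if qrs_buf else np.max(mwi[cand]) / 3.0
        n = np.mean(noise_buf[-8:]) if noise_buf else 0.0
        return n + 0.3125 * (q - n)

    def slope_at(i: int) -> float:
        lo, hi = max(0, i - win), min(len(dx), i + win)
        return float(np.max(dx[lo:hi]))

    last_det = -np.inf
    for idx in cand:
        h = float(mwi[idx])
        if h >= threshold():
            if detections and (idx - last_det) / fs < 0.36:
                # possible T wave: veto when slope is well below the last QRS
                if slope_at(idx) < 0.5 * slope_at(int(last_det)):
                    noise_buf.append(h)
                    continue
            if (idx - last_det) / fs < 0.2:  # refractory
                noise_buf.append(h)
                continue
            if detections:
                rr_buf.append((idx - last_det) / fs)
            detections.append(idx)
            qrs_buf.append(h)
            last_det = idx
        else:
            noise_buf.append(h)
            # search-back: a long gap relative to the running RR mean
            if rr_buf and (idx - last_det) / fs > 1.5 * np.mean(rr_buf[-8:]):
                if h >= 0.5 * threshold() and (idx - last_det) / fs >= 0.2:
                    rr_buf.append((idx - last_det) / fs)
                    detections.append(idx)
                    qrs_buf.append(h)
                    last_det = idx

    if not detections:
        raise ValueError("no QRS detected")

    # refine to the ECG local maximum within +-100 ms
    half = int(round(0.1 * fs))
    refined = []
    for idx in detections:
        lo, hi = max(0, idx - half), min(len(x), idx + half + 1)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    return BeatSeries.from_peaks(refined / fs)


def hr_series(
    beats: BeatSeries,
    n_ticks: int,
    window: float = 4.0,
    step: float = 1.0,
) -> np.ndarray:
    """1 Hz heart-rate trace from gated R-R intervals.

    At each tick t (seconds), HR is the mean of ``60 / rr`` over intervals
    whose terminating R peak lies in the trailing window ``(t - 4, t]``.
    Empty windows carry the previous tick's value forward (leading ticks are
    back-filled from the first defined value).
    """
    if len(beats.rr_intervals) == 0:
        raise ValueError("no beats")
    ticks = np.arange(n_ticks) * step
    hr = np.full(n_ticks, np.nan)
    ends = beats.rr_end_times
    rates = 60.0 / beats.rr_intervals
    for i, t in enumerate(ticks):
        m = (ends > t - window) & (ends <= t)
        if np.any(m):
            hr[i] = rates[m].mean()
    s = pd.Series(hr).ffill().bfill()
    if s.isna().any():
        raise ValueError("no beats inside any window")
    return s.to_numpy()


def hr_max(age: float) -> float:
    """Age-predicted maximum heart rate, ``208 - 0.7 * age`` (BPM)."""
    if age <= 0:
        raise ValueError("age must be positive")
    return 208.0 - 0.7 * age


def hr_percent(hr: np.ndarray | float, age: float) -> np.ndarray | float:
    """Heart rate as a percentage of the age-predicted maximum."""
    hr = np.asarray(hr, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("hr must be positive")
    out = 100.0 * hr / hr_max(age)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Respiration
# ---------------------------------------------------------------------------

def detect_breaths(resp: np.ndarray, fs: float = 25.0) -> BreathSeries:
    """Detect breath peak/trough pairs in a filtered respiration signal.

    Local extrema with a minimum peak-to-peak separation of 1/0.7 s (caps
    the rate at ~42 breaths/min); each peak is paired with the nearest
    preceding trough, unpaired extrema are dropped. Because breath
    amplitude varies widely across postures and breathing tasks, the
    waveform is normalised by a rolling 6 s amplitude envelope before peak
    picking; amplitudes are read off the unnormalised signal.
    """
    x = np.asarray(resp, dtype=float)
    dist = max(1, int(round(fs / 0.7)))
    if float(np.std(x)) == 0.0:
        raise ValueError("too few breaths: constant signal")
    env = (
        pd.Series(np.abs(x))
        .rolling(int(6 * fs), center=True, min_periods=max(1, int(fs)))
        .max()
        .to_numpy()
    )
    z = x / np.maximum(env, 1e-12)
    peaks, _ = sps.find_peaks(z, distance=dist, prominence=0.2)
    troughs, _ = sps.find_peaks(-z, distance=dist, prominence=0.2)
    if len(peaks) < 2:
        raise ValueError("too few breaths")

    p_keep, tr_match = [], []
    prev_peak = -np.inf
    for p in peaks:
        earlier = troughs[(troughs < p) & (troughs > prev_peak)]
        if len(earlier) == 0:
            continue
        p_keep.append(p)
        tr_match.append(earlier[-1])  # nearest preceding trough
        prev_peak = p
    if len(p_keep) < 2:
        raise ValueError("too few breaths")
    p_idx = np.asarray(p_keep)
    t_idx = np.asarray(tr_match)
    return BreathSeries(
        peak_times=p_idx / fs,
        peak_amplitudes=x[p_idx],
        trough_times=t_idx / fs,
        trough_amplitudes=x[t_idx],
    )


def rr_series(breaths: BreathSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-breath respiration rate, ``60 / peak-to-peak interval``.

    Returns (times, rates); each rate is stamped at its terminating peak.
    """
    if len(breaths.peak_times) < 2:
        raise ValueError("too few breaths")
    intervals = np.diff(breaths.peak_times)
    return breaths.peak_times[1:], 60.0 / intervals


def dapt_series(breaths: BreathSeries) -> tuple[np.ndarray, np.ndarray]:
    """Per-breath amplitude difference, peak minus paired trough."""
    return breaths.peak_times, breaths.peak_amplitudes - breaths.trough_amplitudes


# ---------------------------------------------------------------------------
# Acceleration
# ---------------------------------------------------------------------------

def svm_series(acc_x, acc_y, acc_z) -> np.ndarray:
    """Signal vector magnitude, the elementwise Euclidean norm of the axes."""
    x, y, z = (np.asarray(a, dtype=float) for a in (acc_x, acc_y, acc_z))
    if not (len(x) == len(y) == len(z)):
        raise ValueError("channel mismatch: acceleration axes differ in length")
    return np.sqrt(x * x + y * y + z * z)


def mads_series(svm: np.ndarray, T: float = 1.0, fs: float = 25.0) -> np.ndarray:
    """Mean absolute successive SVM difference per non-overlapping T-s block.

    With T = 1 s at 25 Hz each block holds 25 samples and 24 differences:
    ``MADs = sum |SVM[i+1] - SVM[i]| / (T*25 - 1)``.
    """
    x = np.asarray(svm, dtype=float)
    block = int(round(T * fs))
    if len(x) < block:
        raise ValueError("signal too short for one MADs block")
    n_blocks = len(x) // block
    x = x[: n_blocks * block].reshape(n_blocks, block)
    diffs = np.abs(np.diff(x, axis=1))
    return diffs.sum(axis=1) / (block - 1)


# ---------------------------------------------------------------------------
# Synchronisation to 1 Hz
# ---------------------------------------------------------------------------

def resample_1hz(times: np.ndarray, values: np.ndarray, n_ticks: int) -> np.ndarray:
    """Shape-preserving (PCHIP) interpolation onto the 1 Hz grid.

    Monotone cubic interpolation does not overshoot the local data envelope;
    ticks outside the support take the nearest endpoint value.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 support points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("support times must be strictly increasing")
    ticks = np.arange(n_ticks, dtype=float)
    out = PchipInterpolator(t, v)(np.clip(ticks, t[0], t[-1]))
    return out


def smooth_ma(series: np.ndarray, width: int = 31) -> np.ndarray:
    """Centred moving average, truncated and renormalised at the edges."""
    s = pd.Series(np.asarray(series, dtype=float))
    return s.rolling(width, center=True, min_periods=1).mean().to_numpy()


# ---------------------------------------------------------------------------
# Full per-recording chain
# ---------------------------------------------------------------------------

def _stage(name: str):
    """Context that re-raises stage failures with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise type(exc)(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def build_feature_frame(
    rec: Recording,
    resp_source: str = "thoracic",
    hr_source: str = "ecg",
    acc_lowpass: str = "axes",
    smooth_width: int = 31,
) -> pd.DataFrame:
    """Run the full chain on one recording and return the 1 Hz feature frame.

    Columns: t, hr, hr_pct, rr, dapt, mads, vo2 (absent for prediction-only
    recordings), activity. hr_pct is computed from the smoothed hr. The
    subject's demographics are attached as ``frame.attrs["subject"]``.

    Parameters
    ----------
    resp_source : which belt feeds RR/DApt: "thoracic" (default),
        "abdominal", or "sum" of both.
    hr_source : "ecg" (detect R peaks on the wearable ECG) or "hr_ref"
        (use the 1 Hz chest-strap reference).
    acc_lowpass : "axes" applies the 0.32 Hz low-pass to each raw axis
        before the SVM (the default chain); "svm" computes the SVM of the
        raw axes and low-passes the envelope instead.
    """
    n = int(math.floor(rec.duration + 1e-9))

    # --- cardiac ---
    with _stage("ecg"):
        if hr_source == "hr_ref":
            if "hr_ref" not in rec.channels:
                raise ValueError("hr_source='hr_ref' but channel absent")
            ref = rec.channels["hr_ref"].samples
            hr = np.interp(np.arange(n), np.arange(len(ref)), ref)
        else:
            filtered = preprocess.filter_ecg(rec.channels["ecg"].samples)
            beats = detect_r_peaks(filtered, fs=rec.channels["ecg"].fs)
            hr = hr_series(beats, n)

    # --- respiratory ---
    with _stage("respiration"):
        if resp_source == "sum":
            src = None
            for name in ("resp_thoracic", "resp_abdominal"):
                if name in rec.channels:
                    s = rec.channels[name].samples
                    src = s if src is None else src + s
        else:
            name = f"resp_{resp_source}"
            if name not in rec.channels:
                raise ValueError(f"respiration source {resp_source!r} absent")
            src = rec.channels[name].samples
        resp = preprocess.filter_respiration(src)
        breaths = detect_breaths(resp, fs=25.0)
        rr_t, rr_v = rr_series(breaths)
        da_t, da_v = dapt_series(breaths)
        rr = resample_1hz(rr_t, rr_v, n)
        dapt = resample_1hz(da_t, da_v, n)

    # --- motion ---
    with _stage("acceleration"):
        ax = rec.channels["acc_x"].samples
        ay = rec.channels["acc_y"].samples
        az = rec.channels["acc_z"].samples
        if acc_lowpass == "svm":
            svm = svm_series(ax, ay, az)
            svm = preprocess.filter_acceleration(svm, svm, svm)[0]
        else:
            fx, fy, fz = preprocess.filter_acceleration(ax, ay, az)
            svm = svm_series(fx, fy, fz)
        mads = mads_series(svm, T=1.0, fs=25.0)
        if len(mads) < n:  # pad a trailing partial second with the edge value
            mads = np.concatenate([mads, np.full(n - len(mads), mads[-1])])
        mads = mads[:n]

    # --- target ---
    vo2 = None
    if "vo2_ref" in rec.channels:
        v = rec.channels["vo2_ref"].samples
        vo2 = np.interp(np.arange(n), np.arange(len(v)), v)

    with _stage("synchronize"):
        hr_s = smooth_ma(hr[:n], smooth_width)
        rr_s = smooth_ma(rr[:n], smooth_width)
        dapt_s = smooth_ma(dapt[:n], smooth_width)
        mads_s = smooth_ma(mads[:n], smooth_width)
        data = {
            "t": np.arange(n, dtype=float),
            "hr": hr_s,
            "hr_pct": hr_percent(np.maximum(hr_s, 1e-9), rec.subject.age),
            "rr": rr_s,
            "dapt": dapt_s,
            "mads": mads_s,
        }
        if vo2 is not None:
            data["vo2"] = smooth_ma(vo2, smooth_width)
        labels = np.full(n, "unlabeled", dtype=object)
        for iv in rec.activities:
            sel = (data["t"] >= iv.t_start) & (data["t"] < iv.t_end)
            labels[sel] = iv.label
        data["activity"] = labels

    frame = pd.DataFrame(data)
    frame.attrs["subject"] = rec.subject
    frame.attrs["prediction_only"] = vo2 is None
    if vo2 is None:
        warnings.warn(
            f"recording {rec.subject.subject_id}: no vo2_ref channel; "
            "frame is prediction-only",
            stacklevel=2,
        )
    return frame


def write_feature_frame(frame: pd.DataFrame, path) -> None:
    """Serialise a feature frame as delimited text with a fixed column order.

    Subject demographics travel in ``#``-prefixed header lines so the file
    is self-contained for the modelling stage.
    """
    s = frame.attrs.get("subject")
    cols = [c for c in FEATURE_COLUMNS if c in frame.columns]
    with open(path, "w") as fh:
        if s is not None:
            fh.write(f"# subject_id = {s.subject_id}\n")
            fh.write(f"# age = {s.age}\n# sex = {s.sex}\n")
            fh.write(f"# height_cm = {s.height_cm:g}\n# weight_kg = {s.weight_kg:g}\n")
        frame[cols].to_csv(fh, index=False, float_format="%.10g")


def read_feature_frame(path) -> pd.DataFrame:
    """Read a frame written by :func:`write_feature_frame`."""
    from .io import SubjectInfo

    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            k, _, v = line[1:].partition("=")
            meta[k.strip()] = v.strip()
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    if "subject_id" in meta:
        frame.attrs["subject"] = SubjectInfo(
            subject_id=meta["subject_id"],
            age=int(meta["age"]),
            sex=meta["sex"],
            height_cm=float(meta["height_cm"]),
            weight_kg=float(meta["weight_kg"]),
        )
    frame.attrs["prediction_only"] = "vo2" not in frame.columns
    return frame
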