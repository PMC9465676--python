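"""Signal conditioning ahead of feature extraction.

Three fixed chains, one per modality:

* **ECG (200 Hz)** — linear-phase FIR band-pass 3–45 Hz (201 taps, Hamming
  window), group delay compensated. The band suppresses baseline wander and
  ST-segment drift below 3 Hz and powerline/EMG content above 45 Hz while
  amplifying the R wave for QRS detection.
* **Respiration (25 Hz)** — wavelet baseline removal (db4, level 9: the
  retained approximation band lies below ~0.025 Hz and is subtracted as the
  offset/drift estimate), then a zero-phase order-4 Butterworth band-pass
  0.1–0.35 Hz (6–21 breaths/min) to strip residual high-frequency noise.
* **Acceleration (25 Hz)** — zero-phase order-4 Butterworth low-pass at
  0.32 Hz per axis, preserving the gravity (DC) component; motion-artifact
  oscillations above the cutoff are removed before the signal-vector-
  magnitude computation.

All chains are linear and phase-neutral by construction, so event timing
(R waves, breath peaks) is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal as sps

__all__ = [
    "FilterSpec",
    "ECG_FILTER",
    "RESP_FILTER",
    "ACC_FILTER",
    "filter_ecg",
    "filter_respiration",
    "filter_acceleration",
    "ecg_response",
    "respiration_response",
    "acceleration_response",
    "SignalTooShortError",
]


class SignalTooShortError(ValueError):
    """Input shorter than the filter's minimum length ("signal too short")."""


@dataclass(frozen=True)
class FilterSpec:
    """Auditable description of one filtering stage.

    ``band`` is a (low, high) pair in Hz for band-passes or a scalar cutoff
    for the low-pass; ``order`` is the IIR order or FIR tap count.
    """

    kind: str  # fir_bandpass | wavelet_detrend | butter_bandpass | lowpass
    band: tuple[float, float] | float
    order: int
    zero_phase: bool = True
    fs: float = 0.0
    wavelet: str = "db4"
    level: int = 0

    def validate(self) -> None:
        edges = self.band if isinstance(self.band, tuple) else (self.band,)
        for e in edges:
            if not (0.0 < e < self.fs / 2):
                raise ValueError(f"band edge {e} Hz outside (0, {self.fs / 2}) for {self.kind}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "band": list(self.band) if isinstance(self.band, tuple) else self.band,
            "order": self.order,
            "zero_phase": self.zero_phase,
            "fs": self.fs,
        }


ECG_FILTER = FilterSpec("fir_bandpass", (3.0, 45.0), 201, zero_phase=True, fs=200.0)
RESP_DETREND = FilterSpec("wavelet_detrend", 0.025, 0, fs=25.0, wavelet="db4", level=9)
RESP_FILTER = FilterSpec("butter_bandpass", (0.1, 0.35), 4, zero_phase=True, fs=25.0)
ACC_FILTER = FilterSpec("lowpass", 0.32, 4, zero_phase=True, fs=25.0)


def _fir_taps(spec: FilterSpec = ECG_FILTER) -> np.ndarray:
    taps = sps.firwin(
        spec.order, list(spec.band), pass_zero=False, window="hamming", fs=spec.fs
    )
    # null the residual DC leakage of the window design; perturbs the rest
    # of the response by < 2e-4
    return taps - taps.mean()


def filter_ecg(ecg: np.ndarray, spec: FilterSpec = ECG_FILTER) -> np.ndarray:
    """Band-pass a raw 200 Hz ECG trace for R-peak detection.

    Linear-phase FIR; the (order-1)/2-sample group delay is compensated so
    R-wave timing is preserved. Output length equals input length.
    """
    spec.validate()
    x = np.asarray(ecg, dtype=float)
    taps = _fir_taps(spec)
    if len(x) < len(taps):
        raise SignalTooShortError(
            f"signal too short: {len(x)} samples < {len(taps)} filter taps"
        )
    pad = len(taps)
    xp = np.pad(x, pad, mode="reflect")
    # 'same' centres the odd-length symmetric kernel -> group delay removed
    y = sps.fftconvolve(xp, taps, mode="same")
    return y[pad:-pad]


def _wavelet_baseline(x: np.ndarray, spec: FilterSpec = RESP_DETREND) -> np.ndarray:
    level = min(spec.level, pywt.dwt_max_level(len(x), spec.wavelet))
    coeffs = pywt.wavedec(x, spec.wavelet, level=level)
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    return pywt.waverec(coeffs, spec.wavelet)[: len(x)]


def filter_respiration(
    resp: np.ndarray,
    spec: FilterSpec = RESP_FILTER,
    detrend: FilterSpec = RESP_DETREND,
) -> np.ndarray:
    """Detrend and band-pass a raw 25 Hz respiration belt signal.

    The db4 approximation at the coarsest retained level is the baseline
    (belt offset + slow drift) and is subtracted; the residual is band-passed
    0.1–0.35 Hz with a zero-phase order-4 Butterworth filter.
    """
    spec.validate()
    x = np.asarray(resp, dtype=float)
    if len(x) < 2**detrend.level:
        raise SignalTooShortError(
            f"signal too short: {len(x)} samples < one level-{detrend.level} "
            "wavelet decomposition block"
        )
    x = x - _wavelet_baseline(x, detrend)
    sos = sps.butter(spec.order, list(spec.band), btype="bandpass", fs=spec.fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def filter_acceleration(
    acc_x: np.ndarray,
    acc_y: np.ndarray,
    acc_z: np.ndarray,
    spec: FilterSpec = ACC_FILTER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Low-pass the three 25 Hz acceleration axes at 0.32 Hz, zero phase.

    DC (gravity) is preserved exactly; gait-frequency oscillations are
    attenuated as motion artifact.
    """
    spec.validate()
    axes = [np.asarray(a, dtype=float) for a in (acc_x, acc_y, acc_z)]
    if len({len(a) for a in axes}) != 1:
        raise ValueError("channel mismatch: acceleration axes differ in length")
    sos = sps.butter(spec.order, spec.band, btype="lowpass", fs=spec.fs, output="sos")
    return tuple(sps.sosfiltfilt(sos, a) for a in axes)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Designed magnitude responses (for auditing the filter contracts)
# ---------------------------------------------------------------------------

def ecg_response(freqs: np.ndarray, spec: FilterSpec = ECG_FILTER) -> np.ndarray:
    """|H(f)| of the ECG FIR band-pass at the given frequencies (Hz)."""
    w, h = sps.freqz(_fir_taps(spec), worN=2 * np.pi * np.asarray(freqs) / spec.fs)
    return np.abs(h)


def respiration_response(freqs: np.ndarray, spec: FilterSpec = RESP_FILTER) -> np.ndarray:
    """|H(f)| of the zero-phase respiration Butterworth band-pass.

    Forward-backward application squares the single-pass magnitude. The
    wavelet detrend stage is excluded: it only affects content below
    ~0.025 Hz, outside this filter's band.
    """
    sos = sps.butter(spec.order, list(spec.band), btype="bandpass", fs=spec.fs, output="sos")
    w, h = sps.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs) / spec.fs)
    return np.abs(h) ** 2


def acceleration_response(freqs: np.ndarray, spec: FilterSpec = ACC_FILTER) -> np.ndarray:
    """|H(f)| of the zero-phase acceleration Butterworth low-pass."""
    sos = sps.butter(spec.order, spec.band, btype="lowpass", fs=spec.fs, output="sos")
    w, h = sps.sosfreqz(sos, worN=2 * np.pi * np.asarray(freqs) / spec.fs)
    return np.abs(h) ** 2
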