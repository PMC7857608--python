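"""Noise filtering, normalization, resampling and analysis-window extraction.

RF phase traces are band-passed (zero-phase Butterworth, default 0.1-8 Hz,
order 4) after mean removal, which strips the static-distance phase offset
and drift while keeping respiration, heartbeat and their harmonics. ECG
traces are resampled to 154 Hz and band-passed 0.5-45 Hz, removing baseline
drift. Zero-phase (forward-backward) filtering is used throughout so
downstream features and scaleograms are not phase-distorted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .simulate import Recording


class DegenerateInputError(ValueError):
    """Raised for inputs on which an operation is undefined (e.g. z-scoring
    a constant trace)."""


@dataclass(frozen=True)
class PreprocessConfig:
    rf_band: tuple[float, float] = (0.1, 8.0)
    rf_filter_order: int = 4
    normalization: str = "zscore"
    analysis_window: float = 120.0
    ecg_resample_rate: float = 154.0
    ecg_band: tuple[float, float] = (0.5, 45.0)
    ecg_filter_order: int = 4

    def __post_init__(self) -> None:
        for lo, hi in (self.rf_band, self.ecg_band):
            if not 0 < lo < hi:
                raise ValueError("band must satisfy 0 < low < high")
        if self.normalization not in ("zscore", "minmax"):
            raise ValueError("normalization must be 'zscore' or 'minmax'")


def _bandpass(trace: np.ndarray, band: tuple[float, float], order: int,
              sampling_rate: float) -> np.ndarray:
    lo, hi = band
    nyq = sampling_rate / 2.0
    if hi >= nyq:
        raise ValueError(f"band edge {hi} Hz must be below Nyquist {nyq} Hz")
    min_len = 3 * 3 * (order + 1)  # sosfiltfilt padlen for a cascaded design
    if trace.size < min_len:
        raise ValueError(f"trace too short to filter: {trace.size} < {min_len}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=sampling_rate,
                        output="sos")
    return signal.sosfiltfilt(sos, trace)


def filter_rf(trace: np.ndarray, sampling_rate: float,
              config: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase band-pass of a phase trace with the mean (C0 offset) removed."""
    config = config or PreprocessConfig()
    trace = np.asarray(trace, dtype=float)
    return _bandpass(trace - trace.mean(), config.rf_band,
                     config.rf_filter_order, sampling_rate)


def normalize(trace: np.ndarray, method: str = "zscore") -> np.ndarray:
    """Per-trace normalization: ``zscore`` -> mean 0 / sd 1, ``minmax`` -> [0, 1]."""
    trace = np.asarray(trace, dtype=float)
    if method == "zscore":
        sd = trace.std()
        if sd == 0:
            raise DegenerateInputError("cannot z-score a constant trace")
        return (trace - trace.mean()) / sd
    if method == "minmax":
        lo, hi = trace.min(), trace.max()
        if hi == lo:
            return np.zeros_like(trace)
        return (trace - lo) / (hi - lo)
    raise ValueError(f"unknown normalization {method!r}")


def extract_window(recording: Recording, window: float) -> Recording:
    """Final ``window`` seconds of all traces, time re-zeroed."""
    if window <= 0:
        raise ValueError("window must be positive")
    n_keep = int(round(window * recording.sampling_rate))
    if n_keep > recording.time.size:
        raise ValueError(
            f"recording ({recording.time.size} samples) shorter than window "
            f"({n_keep} samples)")
    phase = recording.phase_trace[-n_keep:]
    time = np.arange(n_keep) / recording.sampling_rate
    ecg = recording.ecg_trace
    if ecg is not None:
        n_ecg = int(round(window * recording.ecg_sampling_rate))
        ecg = ecg[-n_ecg:]
    return dataclasses.replace(recording, time=time, phase_trace=phase, ecg_trace=ecg)


def preprocess_ecg(trace: np.ndarray, sampling_rate: float,
                   config: PreprocessConfig | None = None) -> np.ndarray:
    """Resample to ``ecg_resample_rate`` (polyphase) then zero-phase Butterworth
    band-pass 0.5-45 Hz; the high-pass edge removes baseline drift."""
    config = config or PreprocessConfig()
    trace = np.asarray(trace, dtype=float)
    target = config.ecg_resample_rate
    if not np.isclose(sampling_rate, target):
        frac = Fraction(target / sampling_rate).limit_denominator(1000)
        trace = signal.resample_poly(trace, frac.numerator, frac.denominator)
    return _bandpass(trace - trace.mean(), config.ecg_band,
                     config.ecg_filter_order, target)


def preprocess_recording(recording: Recording,
                         config: PreprocessConfig | None = None) -> Recording:
    """Window extraction + RF filtering + normalization (+ ECG chain if present)."""
    config = config or PreprocessConfig()
    rec = extract_window(recording, config.analysis_window)
    phase = filter_rf(rec.phase_trace, rec.sampling_rate, config)
    phase = normalize(phase, config.normalization)
    ecg = rec.ecg_trace
    ecg_rate = rec.ecg_sampling_rate
    if ecg is not None:
        ecg = preprocess_ecg(ecg, rec.ecg_sampling_rate, config)
        ecg_rate = config.ecg_resample_rate
    return dataclasses.replace(rec, phase_trace=phase, ecg_trace=ecg,
                               ecg_sampling_rate=ecg_rate)
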