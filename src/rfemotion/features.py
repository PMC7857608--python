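"""The seven hand-crafted parameters feeding the classical ML baselines:
permutation entropy, band-limited PSD power in 0.15-2 / 2-4 / 4-8 Hz, and the
variance, skewness and kurtosis of the preprocessed trace.

Conventions (fixed so trained baselines are portable):

* permutation entropy: order m=3, delay 1, normalized by log(m!), ties broken
  by order of occurrence (stable sort), so the value lies in [0, 1] and is
  amplitude-scale-free;
* band powers: Welch PSD (Hann window, 30 s segments, 50% overlap)
  integrated over half-open bins [low, high);
* kurtosis: non-excess convention (a Gaussian scores 3); variance uses the
  population (1/n) normalisation.

Feature ordering is versioned in :data:`FEATURE_NAMES`.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import signal, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocessing import DegenerateInputError
from .simulate import Recording

FEATURE_NAMES = (
    "permutation_entropy",
    "psd_0.15_2Hz",
    "psd_2_4Hz",
    "psd_4_8Hz",
    "variance",
    "skewness",
    "kurtosis",
)
FEATURE_SET_VERSION = "rf-7param-v1"

PSD_BANDS = ((0.15, 2.0), (2.0, 4.0), (4.0, 8.0))


def permutation_entropy(trace: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized permutation entropy in [0, 1].

    Shannon entropy of the ordinal-pattern distribution of embedded vectors
    (x_t, x_{t+delay}, ..., x_{t+(m-1)delay}), divided by log(m!). Equal
    values are ranked by order of occurrence (stable argsort).
    """
    trace = np.asarray(trace, dtype=float)
    if not 3 <= order <= 7:
        raise ValueError("order must be in 3..7")
    if delay < 1:
        raise ValueError("delay must be >= 1")
    n_patterns = trace.size - (order - 1) * delay
    if n_patterns < 2:
        raise ValueError("trace too short for the requested order/delay")
    idx = np.arange(n_patterns)[:, None] + delay * np.arange(order)[None, :]
    patterns = np.argsort(trace[idx], axis=1, kind="stable")
    # encode each permutation as an integer key
    key = np.zeros(n_patterns, dtype=np.int64)
    for j in range(order):
        key = key * order + patterns[:, j]
    counts = np.bincount(key)
    p = counts[counts > 0] / n_patterns
    return float(-(p * np.log(p)).sum() / math.log(math.factorial(order)))


def band_powers(trace: np.ndarray, sampling_rate: float,
                bands: tuple = PSD_BANDS, segment_seconds: float = 30.0,
                ) -> np.ndarray:
    """Welch PSD integrated over half-open frequency bins [low, high) Hz."""
    if sampling_rate < 16.0:
        raise ValueError("sampling_rate must be >= 16 Hz so 8 Hz is resolvable")
    trace = np.asarray(trace, dtype=float)
    nperseg = min(int(segment_seconds * sampling_rate), trace.size)
    freqs, psd = signal.welch(trace, fs=sampling_rate, window="hann",
                              nperseg=nperseg, noverlap=nperseg // 2)
    df = freqs[1] - freqs[0]
    out = []
    for lo, hi in bands:
        mask = (freqs >= lo) & (freqs < hi)
        out.append(float(psd[mask].sum() * df))
    return np.asarray(out)


def moments(trace: np.ndarray) -> tuple[float, float, float]:
    """(population variance, skewness, non-excess kurtosis)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 4:
        raise ValueError("need at least 4 samples")
    var = float(np.var(trace))
    if var == 0:
        raise DegenerateInputError("skewness/kurtosis undefined for constant trace")
    skew = float(stats.skew(trace, bias=True))
    kurt = float(stats.kurtosis(trace, fisher=False, bias=True))
    return var, skew, kurt


def extract_features(recording: Recording, pe_order: int = 3,
                     pe_delay: int = 1) -> np.ndarray:
    """The 7-vector in :data:`FEATURE_NAMES` order for one preprocessed,
    windowed recording."""
    trace = recording.phase_trace
    pe = permutation_entropy(trace, pe_order, pe_delay)
    bands = band_powers(trace, recording.sampling_rate)
    var, skew, kurt = moments(trace)
    vec = np.array([pe, *bands, var, skew, kurt])
    assert vec.shape == (len(FEATURE_NAMES),)
    return vec


def feature_table(recordings: list[Recording]) -> pd.DataFrame:
    """Feature table with subject/label columns, CSV-export ready."""
    rows = []
    for rec in recordings:
        rows.append({"subject": rec.subject_id, "label": rec.label,
                     **dict(zip(FEATURE_NAMES, extract_features(rec)))})
    return pd.DataFrame(rows)


class FeatureExtractor(BaseEstimator, TransformerMixin):
    """scikit-learn transformer: list of preprocessed recordings -> (n, 7)."""

    def __init__(self, pe_order: int = 3, pe_delay: int = 1):
        self.pe_order = pe_order
        self.pe_delay = pe_delay

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X) -> np.ndarray:
        return np.stack([extract_features(rec, self.pe_order, self.pe_delay)
                         for rec in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
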