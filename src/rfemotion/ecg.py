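"""ECG branch machinery: R-peak detection, the inter-beat-interval (IBI)
feature family, and minimum-redundancy-maximum-relevance (mRmR) selection.

The detector follows the classical derivative - squaring - moving-window
integration scheme with an adaptive threshold and a 250 ms refractory
period. The feature catalogue applies a fixed set of 27 statistics to each
of the IBI series, its first difference and its second difference, giving
exactly 81 named features (catalogue version ``ibi-27x3-v1``); this mirrors
the shape of toolbox-style HRV feature extraction, where interval statistics
and their successive-difference statistics carry the variability signal.
mRmR uses the "difference" (MID) criterion with mutual information estimated
on 10-quantile discretized features, which keeps the selection fully
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import mutual_info_score

MIN_INTERVAL_S = 0.25
MAX_INTERVAL_S = 2.5
CATALOGUE_VERSION = "ibi-27x3-v1"


class NoPeaksError(ValueError):
    """No R peaks could be detected (e.g. flat-line input)."""


@dataclass
class IBISeries:
    """R-peak times (s) and the physiologically plausible intervals between
    them (0.25-2.5 s after range filtering)."""

    r_peak_times: np.ndarray
    intervals: np.ndarray
    source_rate: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.r_peak_times) <= 0):
            raise ValueError("r_peak_times must be strictly increasing")


def detect_r_peaks(ecg: np.ndarray, rate: float) -> IBISeries:
    """Detect R peaks in a band-passed ECG trace.

    Derivative -> squaring -> moving-window integration (150 ms), peak picking
    with an adaptive threshold (a fraction of the rolling 95th percentile) and
    a 250 ms refractory period, then refinement to the local ECG maximum
    within +-80 ms.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size < int(rate):
        raise ValueError("trace shorter than one second")
    deriv = np.gradient(ecg)
    squared = deriv ** 2
    win = max(1, int(0.150 * rate))
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")
    level = np.percentile(mwi, 95)
    if level <= 0 or np.ptp(ecg) < 1e-6:
        raise NoPeaksError("no QRS energy found (flat-line input?)")
    peaks, _ = signal.find_peaks(mwi, height=0.3 * level,
                                 distance=max(1, int(MIN_INTERVAL_S * rate)))
    if peaks.size == 0:
        raise NoPeaksError("no peaks above the adaptive threshold")
    # refine to the ECG local maximum around each integrator peak
    half = int(0.080 * rate)
    refined = []
    for p in peaks:
        lo, hi = max(0, p - half), min(ecg.size, p + half + 1)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    # enforce refractory period on the refined positions
    kept = [int(refined[0])]
    for p in refined[1:]:
        if (p - kept[-1]) / rate >= MIN_INTERVAL_S:
            kept.append(int(p))
        elif ecg[p] > ecg[kept[-1]]:
            kept[-1] = int(p)
    times = np.asarray(kept) / rate
    intervals = np.diff(times)
    intervals = intervals[(intervals > MIN_INTERVAL_S) & (intervals < MAX_INTERVAL_S)]
    return IBISeries(r_peak_times=times, intervals=intervals, source_rate=rate)


def _series_statistics(x: np.ndarray) -> dict[str, float]:
    """The 27 per-series statistics of the catalogue (order is fixed)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    mean = float(np.mean(x))
    sd = float(np.std(x))
    stats_out: dict[str, float] = {}
    stats_out["mean"] = mean
    stats_out["median"] = float(np.median(x))
    stats_out["std"] = sd
    stats_out["var"] = sd ** 2
    stats_out["min"] = float(np.min(x))
    stats_out["max"] = float(np.max(x))
    stats_out["range"] = float(np.ptp(x))
    stats_out["rms"] = float(np.sqrt(np.mean(x ** 2)))
    stats_out["energy"] = float(np.sum(x ** 2))
    q = np.percentile(x, [5, 10, 25, 75, 90, 95])
    stats_out["p5"], stats_out["p10"], stats_out["p25"] = map(float, q[:3])
    stats_out["p75"], stats_out["p90"], stats_out["p95"] = map(float, q[3:])
    stats_out["iqr"] = stats_out["p75"] - stats_out["p25"]
    stats_out["mad_median"] = float(np.median(np.abs(x - np.median(x))))
    stats_out["mad_mean"] = float(np.mean(np.abs(x - mean)))
    stats_out["skewness"] = float(stats.skew(x, bias=True)) if sd > 0 else 0.0
    stats_out["kurtosis"] = float(stats.kurtosis(x, fisher=False, bias=True)) if sd > 0 else 0.0
    stats_out["cv"] = sd / abs(mean) if abs(mean) > 1e-12 else 0.0
    stats_out["sem"] = sd / np.sqrt(n) if n > 0 else 0.0
    stats_out["trimmed_mean_10"] = float(stats.trim_mean(x, 0.1)) if n >= 3 else mean
    if sd > 0 and n >= 10:
        hist, _ = np.histogram(x, bins=10)
        p = hist[hist > 0] / n
        stats_out["hist_entropy"] = float(-(p * np.log(p)).sum())
    else:
        stats_out["hist_entropy"] = 0.0
    crossings = np.sum(np.diff(np.sign(x - mean)) != 0) if sd > 0 else 0
    stats_out["mean_crossing_rate"] = float(crossings) / max(n - 1, 1)
    if n >= 2 and sd > 0:
        t = np.arange(n)
        stats_out["trend_slope"] = float(np.polyfit(t, x, 1)[0])
        x0 = x - mean
        stats_out["autocorr_lag1"] = float(np.dot(x0[:-1], x0[1:]) / (n * sd ** 2))
    else:
        stats_out["trend_slope"] = 0.0
        stats_out["autocorr_lag1"] = 0.0
    assert len(stats_out) == 27
    return stats_out


_SERIES_PREFIXES = ("ibi", "dibi", "ddibi")

IBI_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{prefix}_{name}" for prefix in _SERIES_PREFIXES
    for name in _series_statistics(np.arange(12.0)))


def ibi_features(series: IBISeries, ecg: np.ndarray | None = None) -> np.ndarray:
    """The 81 IBI features: 27 statistics on each of {IBI, dIBI, ddIBI}.

    Degenerate statistics (e.g. skewness of a constant interval series) are
    mapped to 0 rather than NaN, with a warning. Interval-derived features
    are invariant to ECG amplitude scaling by construction.
    """
    iv = np.asarray(series.intervals, dtype=float)
    if iv.size < 10:
        raise ValueError(f"need at least 10 intervals, got {iv.size}")
    out: list[float] = []
    for x in (iv, np.diff(iv), np.diff(iv, n=2)):
        out.extend(_series_statistics(x).values())
    vec = np.asarray(out)
    if not np.all(np.isfinite(vec)):
        warnings.warn("degenerate IBI statistics mapped to 0", RuntimeWarning)
        vec = np.nan_to_num(vec, nan=0.0, posinf=0.0, neginf=0.0)
    assert vec.shape == (81,)
    return vec


@dataclass
class SelectedFeatures:
    """Result of mRmR selection: retained indices/names plus the per-step
    relevance and mean-redundancy scores."""

    indices: list[int]
    names: list[str]
    relevance: list[float] = field(default_factory=list)
    redundancy: list[float] = field(default_factory=list)


def _discretize(X: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile discretization per column (deterministic)."""
    out = np.empty_like(X, dtype=np.int32)
    for j in range(X.shape[1]):
        edges = np.unique(np.quantile(X[:, j], np.linspace(0, 1, n_bins + 1)[1:-1]))
        out[:, j] = np.searchsorted(edges, X[:, j], side="right")
    return out


def mrmr_select(features: np.ndarray, labels: np.ndarray, k: int = 30,
                feature_names: list[str] | None = None,
                n_bins: int = 10) -> SelectedFeatures:
    """Greedy forward mRmR (MID form): at each step pick the feature
    maximizing relevance MI(f; y) minus mean MI(f; already-selected), on
    10-quantile discretized features; ties break toward the lower index.
    Constant columns are skipped with a warning.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    n, p = X.shape
    if k > p:
        raise ValueError(f"cannot select {k} of {p} features")
    if n <= k:
        raise ValueError("need more samples than selected features")
    names = list(feature_names) if feature_names is not None else [
        f"f{j}" for j in range(p)]
    Xd = _discretize(X, n_bins)
    constant = np.array([np.unique(Xd[:, j]).size <= 1 for j in range(p)])
    if constant.any():
        warnings.warn(f"skipping {int(constant.sum())} constant feature columns",
                      RuntimeWarning)
    relevance = np.array([
        0.0 if constant[j] else mutual_info_score(y, Xd[:, j]) for j in range(p)])
    candidates = [j for j in range(p) if not constant[j]]
    if len(candidates) < k:
        raise ValueError("too few non-constant features")
    selected: list[int] = []
    rel_log: list[float] = []
    red_log: list[float] = []
    mi_cache: dict[tuple[int, int], float] = {}

    def pair_mi(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in mi_cache:
            mi_cache[key] = mutual_info_score(Xd[:, a], Xd[:, b])
        return mi_cache[key]

    for _ in range(k):
        best_j, best_score, best_red = -1, -np.inf, 0.0
        for j in candidates:
            if j in selected:
                continue
            red = (np.mean([pair_mi(j, s) for s in selected]) if selected else 0.0)
            score = relevance[j] - red
            if score > best_score + 1e-15:
                best_j, best_score, best_red = j, score, red
        selected.append(best_j)
        rel_log.append(float(relevance[best_j]))
        red_log.append(float(best_red))
    return SelectedFeatures(indices=selected,
                            names=[names[j] for j in selected],
                            relevance=rel_log, redundancy=red_log)


class MrmrSelector(SelectorMixin, BaseEstimator):
    """scikit-learn selector wrapping :func:`mrmr_select` (default k=30)."""

    def __init__(self, k: int = 30, n_bins: int = 10):
        self.k = k
        self.n_bins = n_bins

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        sel = mrmr_select(X, np.asarray(y), k=self.k, n_bins=self.n_bins)
        self.selected_ = sel
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[sel.indices] = True
        self.support_mask_ = mask
        return self

    def _get_support_mask(self):
        return self.support_mask_
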