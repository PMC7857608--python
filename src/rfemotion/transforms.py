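"""Time-frequency and spectral representations feeding the fusion network.

The 2-D branch input is a continuous-wavelet-transform (complex Morlet)
magnitude scaleogram on 64 logarithmic scales spanning 0.1-8 Hz, resized to a
fixed square image and min-max scaled to [0, 1]. The 1-D branch input stacks
the normalized time series with its Fourier-magnitude sequence as two
channels of a fixed-length sequence. Rows of the scaleogram are ordered by
descending frequency (high frequencies at the top), as conventional for
scaleogram images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.linalg import solve_toeplitz
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

from .preprocessing import normalize
from .simulate import Recording

DEFAULT_WAVELET = "cmor1.5-1.0"
DEFAULT_FREQ_RANGE = (0.1, 8.0)
DEFAULT_N_SCALES = 64
DEFAULT_IMAGE_SIZE = (64, 64)
DEFAULT_SEQUENCE_LENGTH = 256


@dataclass
class Scaleogram:
    """|CWT| image with axis metadata.

    ``magnitude`` is the native-resolution non-negative array (frequency x
    time, frequencies descending top-to-bottom); ``image`` is the resized,
    per-image min-max scaled copy fed to the 2-D convolutional branch.
    """

    magnitude: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    wavelet_name: str
    image: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.magnitude < 0):
            raise ValueError("scaleogram magnitude must be non-negative")
        if not np.all(np.diff(self.frequencies) < 0):
            raise ValueError("frequencies must be strictly decreasing")

    @property
    def image_size(self) -> tuple[int, int]:
        return self.image.shape


@dataclass
class SequenceInput:
    """1-D branch input: (length, 2) array; channel 0 is the normalized time
    series resampled to a fixed length, channel 1 the unit-norm Fourier
    magnitude sequence interpolated onto the same grid."""

    values: np.ndarray
    layout: str = "channels: [normalized_time_series, fft_magnitude]"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("sequence input must be finite")


def scale_grid(freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
               n_scales: int = DEFAULT_N_SCALES,
               wavelet: str = DEFAULT_WAVELET,
               sampling_rate: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    """Geometric frequency grid (descending) and matching CWT scales."""
    lo, hi = freq_range
    freqs = np.geomspace(hi, lo, n_scales)
    fc = pywt.central_frequency(wavelet)
    scales = fc * sampling_rate / freqs
    return freqs, scales


def _ar_extend(x: np.ndarray, n_pad: int, order: int = 64,
               fit_len: int = 256) -> np.ndarray:
    """Forward linear-prediction extension of a trace.

    Yule-Walker AR coefficients are fitted on the trailing ``fit_len``
    samples (a local fit, so the extension continues the instantaneous
    rhythm at the boundary rather than the global spectrum) and iterated
    forward; the biased autocorrelation estimate keeps the model stable.
    """
    seg = x[-min(fit_len, x.size):]
    order = min(order, seg.size // 2)
    xm = seg - seg.mean()
    n = xm.size
    r = np.correlate(xm, xm, "full")[n - 1:n + order] / n
    if order < 1 or r[0] <= 0:
        return np.full(n_pad, float(seg.mean()))
    a = solve_toeplitz((r[:-1], r[:-1]), r[1:])
    buf = list(x[-order:])
    out = np.empty(n_pad)
    for i in range(n_pad):
        v = float(np.dot(a, buf[-1:-order - 1:-1]))
        out[i] = v
        buf.append(v)
    return out


def cwt_scaleogram(trace: np.ndarray, sampling_rate: float,
                   freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
                   n_scales: int = DEFAULT_N_SCALES,
                   wavelet: str = DEFAULT_WAVELET,
                   image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE) -> Scaleogram:
    """Continuous-wavelet-transform magnitude image of a 1-D trace.

    Before the transform the trace is extended on both sides by a locally
    fitted linear-prediction (AR) continuation covering the longest wavelet
    support, then trimmed after; this keeps ridge estimates accurate up to
    the very first and last time columns, where zero- or reflection-padding
    would bend them toward low frequencies.
    """
    trace = np.asarray(trace, dtype=float)
    lo, hi = freq_range
    if hi > sampling_rate / 2:
        raise ValueError(f"freq_range upper edge {hi} Hz exceeds Nyquist")
    freqs, scales = scale_grid(freq_range, n_scales, wavelet, sampling_rate)
    if trace.size < 2 * n_scales:
        raise ValueError("trace too short for the requested scale grid")
    pad = min(int(np.ceil(scales.max() * 4)), trace.size - 1)
    padded = np.concatenate([
        _ar_extend(trace[::-1], pad)[::-1], trace, _ar_extend(trace, pad)])
    coef, _ = pywt.cwt(padded, scales, wavelet,
                       sampling_period=1.0 / sampling_rate, method="fft")
    mag = np.abs(coef[:, pad:pad + trace.size])
    img = resize(mag, image_size, order=1, mode="reflect", anti_aliasing=True)
    span = img.max() - img.min()
    img = (img - img.min()) / span if span > 0 else np.zeros_like(img)
    times = np.arange(trace.size) / sampling_rate
    return Scaleogram(magnitude=mag, frequencies=freqs, times=times,
                      wavelet_name=wavelet, image=img)


def fft_sequence(trace: np.ndarray) -> np.ndarray:
    """One-sided Fourier magnitude sequence, unit Euclidean norm.

    Length is floor(n/2)+1; for real input the one-sided spectrum is a
    lossless summary of the symmetric full spectrum.
    """
    trace = np.asarray(trace, dtype=float)
    mag = np.abs(np.fft.rfft(trace))
    nrm = np.linalg.norm(mag)
    return mag / nrm if nrm > 0 else mag


def ridge_frequencies(scaleogram: Scaleogram) -> np.ndarray:
    """Frequency of maximal magnitude at each time column (ridge trace)."""
    return scaleogram.frequencies[np.argmax(scaleogram.magnitude, axis=0)]


def _resample_to_length(x: np.ndarray, length: int) -> np.ndarray:
    """Linear interpolation onto a uniform grid of ``length`` points."""
    src = np.linspace(0.0, 1.0, x.size)
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, x)


def build_network_inputs(recording: Recording,
                         sequence_length: int = DEFAULT_SEQUENCE_LENGTH,
                         freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
                         n_scales: int = DEFAULT_N_SCALES,
                         wavelet: str = DEFAULT_WAVELET,
                         image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE,
                         ) -> tuple[SequenceInput, Scaleogram]:
    """Deterministic pair of branch inputs for one preprocessed recording."""
    trace = recording.phase_trace
    ts = _resample_to_length(normalize(trace, "zscore"), sequence_length)
    spec = _resample_to_length(fft_sequence(trace), sequence_length)
    seq = SequenceInput(values=np.stack([ts, spec], axis=-1))
    scal = cwt_scaleogram(trace, recording.sampling_rate, freq_range,
                          n_scales, wavelet, image_size)
    return seq, scal


def save_png(scaleogram: Scaleogram, path) -> None:
    """Write the min-max-scaled scaleogram image as an 8-bit grayscale PNG
    (top row = highest frequency)."""
    from PIL import Image
    img = (np.clip(scaleogram.image, 0, 1) * 255).astype(np.uint8)
    Image.fromarray(img, mode="L").save(path)


class NetworkInputTransformer(BaseEstimator, TransformerMixin):
    """Turn a list of preprocessed recordings into fusion-network inputs.

    ``transform`` returns ``(X_seq, X_img)`` with shapes
    (n, sequence_length, 2) and (n, height, width). Stateless; ``fit`` only
    validates parameters, following the scikit-learn transformer contract.
    """

    def __init__(self, sequence_length: int = DEFAULT_SEQUENCE_LENGTH,
                 n_scales: int = DEFAULT_N_SCALES,
                 freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
                 wavelet: str = DEFAULT_WAVELET,
                 image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE):
        self.sequence_length = sequence_length
        self.n_scales = n_scales
        self.freq_range = freq_range
        self.wavelet = wavelet
        self.image_size = image_size

    def fit(self, X, y=None):
        self.n_features_in_ = len(X)
        return self

    def transform(self, X) -> tuple[np.ndarray, np.ndarray]:
        seqs, imgs = [], []
        for rec in X:
            seq, scal = build_network_inputs(
                rec, self.sequence_length, self.freq_range, self.n_scales,
                self.wavelet, self.image_size)
            if seq.values.shape != (self.sequence_length, 2):
                raise ValueError("sequence input shape mismatch")
            if scal.image.shape != tuple(self.image_size):
                raise ValueError("scaleogram image shape mismatch")
            seqs.append(seq.values)
            imgs.append(scal.image)
        return np.stack(seqs), np.stack(imgs)
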