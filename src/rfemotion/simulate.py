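"""Forward model of a continuous-wave (CW) radar observing a breathing, beating
chest, plus a class-conditioned synthetic dataset generator with paired ECG.

The physical chain is: a 5.8 GHz tone is transmitted at a subject sitting at a
static distance ``d``; chest displacement ``f(t)`` (respiration + heartbeat,
each a harmonic series with cycle-to-cycle rate jitter) modulates the
round-trip delay, so the phase difference between transmitted and received
signals is

    Phi(t) = C0 - (2 omega0 / c) * f(t),        C0 = (2 d / c) * omega0.

Emotion classes are emulated as shifts of the generative parameters
(heart rate, rate jitter, respiration rate/amplitude); subjects carry a
persistent multiplicative offset so that recordings share a subject-identity
signal, which is what subject-independent evaluation must generalise over.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import fftconvolve

SPEED_OF_LIGHT = 299_792_458.0  # m/s

EMOTION_LABELS = ("relax", "scary", "disgust", "joy")

# sub-stream indices for per-recording seed splitting
_STREAM_RESP = 0
_STREAM_HEART = 1
_STREAM_NOISE = 2
_STREAM_ARTIFACT = 3
_STREAM_ECG = 4


class NyquistError(ValueError):
    """Sampling rate too low for the highest requested harmonic."""


@dataclass(frozen=True)
class RadarConfig:
    """CW radar front-end parameters.

    ``carrier_frequency`` is the transmitted tone in Hz (default 5.8 GHz),
    ``static_distance`` the subject-antenna distance in metres,
    ``reflection_magnitude`` |Gamma0| in (0, 1], ``sampling_rate`` the rate of
    the demodulated phase trace.
    """

    carrier_frequency: float = 5.8e9
    initial_phase: float = 0.0
    static_distance: float = 0.30
    reflection_magnitude: float = 0.8
    sampling_rate: float = 50.0
    speed_of_light: float = SPEED_OF_LIGHT

    def __post_init__(self) -> None:
        if self.carrier_frequency <= 0:
            raise ValueError("carrier_frequency must be positive")
        if self.static_distance <= 0:
            raise ValueError("static_distance must be positive")
        if not 0 < self.reflection_magnitude <= 1:
            raise ValueError("reflection_magnitude must be in (0, 1]")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def omega0(self) -> float:
        """Angular carrier frequency, rad/s."""
        return 2.0 * np.pi * self.carrier_frequency

    @property
    def phase_offset(self) -> float:
        """Constant phase offset C0 = (2 d / c) * omega0, rad."""
        return 2.0 * self.static_distance / self.speed_of_light * self.omega0


@dataclass(frozen=True)
class VitalSignProfile:
    """Generative parameters of one recording.

    Rates in Hz, amplitudes in metres, phases in radians. ``rate_jitter_sd``
    is the relative cycle-to-cycle standard deviation of the instantaneous
    rate of both rhythms (an HRV-like quantity). ``noise_sd`` is additive
    phase noise on the demodulated trace, in radians.
    """

    respiration_rate: float = 0.25
    respiration_amplitude: float = 4.0e-3
    respiration_harmonics: int = 2
    heart_rate: float = 1.2
    heart_amplitude: float = 0.5e-3
    heart_harmonics: int = 3
    harmonic_decay: float = 0.4
    rate_jitter_sd: float = 0.03
    respiration_phase: float = 0.0
    heart_phase: float = 0.0
    artifact_rate: float = 0.0
    artifact_amplitude: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.respiration_amplitude < 0 or self.heart_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.respiration_amplitude > 0 and self.heart_amplitude >= self.respiration_amplitude:
            raise ValueError("heart_amplitude must be smaller than respiration_amplitude")
        if self.rate_jitter_sd < 0:
            raise ValueError("rate_jitter_sd must be non-negative")
        if self.respiration_harmonics < 0 or self.heart_harmonics < 0:
            raise ValueError("harmonic counts must be non-negative")

    @property
    def max_harmonic_frequency(self) -> float:
        freqs = [0.0]
        if self.respiration_amplitude > 0 and self.respiration_harmonics > 0:
            freqs.append(self.respiration_rate * self.respiration_harmonics)
        if self.heart_amplitude > 0 and self.heart_harmonics > 0:
            freqs.append(self.heart_rate * self.heart_harmonics)
        return max(freqs)


@dataclass(frozen=True)
class EmotionProfile:
    """Distribution over :class:`VitalSignProfile` for one emotion class.

    ``means``/``sds`` map VitalSignProfile field names to the class-level
    mean and between-recording standard deviation. ``subject_offset_sd`` is
    the relative sd of the persistent per-subject multiplicative offset
    applied to rates and amplitudes.
    """

    label: str
    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    subject_offset_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.label not in EMOTION_LABELS:
            raise ValueError(f"label must be one of {EMOTION_LABELS}, got {self.label!r}")

    def sample(self, rng: np.random.Generator, subject_offset: float = 0.0) -> VitalSignProfile:
        """Draw one VitalSignProfile; the subject offset multiplies rates and
        amplitudes by (1 + offset)."""
        base = dataclasses.asdict(VitalSignProfile())
        for name, mu in self.means.items():
            sd = self.sds.get(name, 0.0)
            val = mu + sd * rng.standard_normal() if sd > 0 else mu
            base[name] = val
        for name in ("respiration_rate", "heart_rate",
                     "respiration_amplitude", "heart_amplitude"):
            base[name] = base[name] * (1.0 + subject_offset)
        # clamp to physiologically sensible supports
        base["respiration_rate"] = float(np.clip(base["respiration_rate"], 0.1, 0.5))
        base["heart_rate"] = float(np.clip(base["heart_rate"], 0.8, 2.5))
        base["rate_jitter_sd"] = max(0.0, base["rate_jitter_sd"])
        base["respiration_harmonics"] = int(base["respiration_harmonics"])
        base["heart_harmonics"] = int(base["heart_harmonics"])
        if base["heart_amplitude"] >= base["respiration_amplitude"]:
            base["heart_amplitude"] = 0.5 * base["respiration_amplitude"]
        return VitalSignProfile(**base)


@dataclass
class Recording:
    """One labelled session: demodulated phase trace, optional paired ECG."""

    subject_id: str
    label: str
    time: np.ndarray
    phase_trace: np.ndarray
    sampling_rate: float
    ecg_trace: Optional[np.ndarray] = None
    ecg_sampling_rate: Optional[float] = None
    ground_truth: Optional[VitalSignProfile] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.phase_trace = np.asarray(self.phase_trace, dtype=float)
        if self.label not in EMOTION_LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.time.shape != self.phase_trace.shape:
            raise ValueError("time and phase_trace must have equal length")
        dt = np.diff(self.time)
        if self.time.size > 1 and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6)):
            raise ValueError("time must be strictly increasing and uniform")

    @property
    def duration(self) -> float:
        return self.time.size / self.sampling_rate


def _recording_seed(master_seed: int, subject_index: int, class_index: int) -> int:
    """Stable per-recording sub-seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(subject_index), int(class_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _stream_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _jittered_phase(rate: float, jitter_sd: float, duration: float,
                    sampling_rate: float, rng: np.random.Generator,
                    initial_phase: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Phase theta(t) of a quasi-periodic oscillator with per-cycle rate jitter.

    Each nominal cycle k gets an instantaneous rate rate*(1 + eps_k),
    eps_k ~ N(0, jitter_sd); theta grows by 2 pi per cycle. Returns
    (theta over the uniform sample grid, cycle-start times). The cycle starts
    double as beat times so the paired ECG shares the identical beat process.
    """
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    if rate <= 0:
        return np.full(n, initial_phase), np.empty(0)
    n_cycles = int(np.ceil(duration * rate * (1 + 5 * max(jitter_sd, 0.05)))) + 4
    eps = jitter_sd * rng.standard_normal(n_cycles) if jitter_sd > 0 else np.zeros(n_cycles)
    rates = rate * np.clip(1.0 + eps, 0.3, 3.0)
    periods = 1.0 / rates
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    # piecewise-linear phase: 2 pi per completed cycle
    k = np.searchsorted(starts, t, side="right") - 1
    theta = 2.0 * np.pi * (k + (t - starts[k]) / periods[k]) + initial_phase
    beat_times = starts[starts < duration]
    return theta, beat_times


def _harmonic_series(theta: np.ndarray, amplitude: float, n_harmonics: int,
                     decay: float, phase: float) -> np.ndarray:
    out = np.zeros_like(theta)
    for h in range(1, n_harmonics + 1):
        out += amplitude * decay ** (h - 1) * np.sin(h * theta + phase)
    return out


def _artifact_bumps(duration: float, sampling_rate: float, rate_per_min: float,
                    amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Poisson-timed raised-cosine bumps (0.5-2 s) emulating body motion."""
    n = int(round(duration * sampling_rate))
    out = np.zeros(n)
    if rate_per_min <= 0 or amplitude <= 0:
        return out
    n_events = rng.poisson(rate_per_min * duration / 60.0)
    t = np.arange(n) / sampling_rate
    for _ in range(n_events):
        centre = rng.uniform(0, duration)
        width = rng.uniform(0.5, 2.0)
        sign = rng.choice([-1.0, 1.0])
        mask = np.abs(t - centre) < width / 2
        out[mask] += sign * amplitude * 0.5 * (
            1 + np.cos(2 * np.pi * (t[mask] - centre) / width))
    return out


def simulate_displacement(profile: VitalSignProfile, duration: float,
                          sampling_rate: float, seed: int) -> np.ndarray:
    """Chest displacement f(t) in metres over a uniform grid.

    Sum of respiration and heartbeat harmonic series with per-cycle rate
    jitter, plus sporadic motion-artifact bumps. Reproducible for fixed seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    f_max = profile.max_harmonic_frequency
    if sampling_rate <= 2.0 * f_max:
        raise NyquistError(
            f"sampling_rate {sampling_rate} Hz must exceed twice the highest "
            f"harmonic frequency ({f_max} Hz)")
    theta_r, _ = _jittered_phase(profile.respiration_rate, profile.rate_jitter_sd,
                                 duration, sampling_rate,
                                 _stream_rng(seed, _STREAM_RESP))
    theta_h, _ = _jittered_phase(profile.heart_rate, profile.rate_jitter_sd,
                                 duration, sampling_rate,
                                 _stream_rng(seed, _STREAM_HEART))
    disp = np.zeros(int(round(duration * sampling_rate)))
    if profile.respiration_amplitude > 0:
        disp += _harmonic_series(theta_r, profile.respiration_amplitude,
                                 profile.respiration_harmonics,
                                 profile.harmonic_decay, profile.respiration_phase)
    if profile.heart_amplitude > 0:
        disp += _harmonic_series(theta_h, profile.heart_amplitude,
                                 profile.heart_harmonics,
                                 profile.harmonic_decay, profile.heart_phase)
    disp += _artifact_bumps(duration, sampling_rate, profile.artifact_rate,
                            profile.artifact_amplitude,
                            _stream_rng(seed, _STREAM_ARTIFACT))
    return disp


def heart_beat_times(profile: VitalSignProfile, duration: float, seed: int) -> np.ndarray:
    """Beat times implied by the radar heart component for this seed.

    Uses the same jittered-phase stream as :func:`simulate_displacement`, so
    the ECG synthesised from the same seed shares the identical beat process.
    """
    _, beats = _jittered_phase(profile.heart_rate, profile.rate_jitter_sd,
                               duration, 100.0, _stream_rng(seed, _STREAM_HEART))
    return beats


def forward_and_demodulate(displacement: np.ndarray, config: RadarConfig,
                           wrap: bool = False) -> np.ndarray:
    """Phase difference Phi(t) = C0 - (2 omega0 / c) * f(t), in radians.

    The output is continuous (the constant C0 generally exceeds 2 pi). With
    ``wrap=True`` the trace is first wrapped to (-pi, pi] and then unwrapped
    with the standard 2 pi jump correction, as a real arctangent demodulator
    would require; this recovers the waveform up to a 2 pi multiple.
    """
    displacement = np.asarray(displacement, dtype=float)
    if not np.all(np.isfinite(displacement)):
        raise ValueError("displacement must be finite")
    phi = config.phase_offset - (2.0 * config.omega0 / config.speed_of_light) * displacement
    if wrap:
        wrapped = np.angle(np.exp(1j * phi))
        phi = np.unwrap(wrapped)
    return phi


_QRS_COMPONENTS = (
    # (delay s, sigma s, amplitude mV): P, Q, R, S, T
    (-0.20, 0.040, 0.15),
    (-0.025, 0.012, -0.12),
    (0.0, 0.011, 1.0),
    (0.028, 0.013, -0.25),
    (0.25, 0.055, 0.30),
)


def _ecg_kernel(sampling_rate: float) -> tuple[np.ndarray, int]:
    """PQRST-like template; returns (kernel, index of the R peak)."""
    t = np.arange(-0.35, 0.50, 1.0 / sampling_rate)
    k = np.zeros_like(t)
    for delay, sigma, amp in _QRS_COMPONENTS:
        k += amp * np.exp(-0.5 * ((t - delay) / sigma) ** 2)
    return k, int(np.argmin(np.abs(t)))


def synthesize_ecg(profile: VitalSignProfile, duration: float,
                   sampling_rate: float, seed: int,
                   noise_mv: float = 0.02, wander_mv: float = 0.05) -> np.ndarray:
    """Synthetic single-lead ECG (mV) sharing the radar beat process.

    QRS-like template kernels are placed at RR intervals drawn from the same
    heart-rate + jitter stream as the radar displacement; baseline wander and
    white noise are added (set both to 0 for an exact kernel superposition).
    """
    if profile.heart_rate <= 0:
        raise ValueError("heart_rate must be positive")
    beats = heart_beat_times(profile, duration, seed)
    n = int(round(duration * sampling_rate))
    impulses = np.zeros(n)
    idx = np.round(beats * sampling_rate).astype(int)
    idx = idx[idx < n]
    impulses[idx] = 1.0
    kernel, r_idx = _ecg_kernel(sampling_rate)
    ecg = fftconvolve(impulses, kernel, mode="full")[r_idx:r_idx + n]
    rng = _stream_rng(seed, _STREAM_ECG)
    if wander_mv > 0:
        t = np.arange(n) / sampling_rate
        f1, f2 = rng.uniform(0.15, 0.35, size=2)
        ph = rng.uniform(0, 2 * np.pi, size=2)
        ecg = ecg + wander_mv * (np.sin(2 * np.pi * f1 * t + ph[0])
                                 + 0.5 * np.sin(2 * np.pi * f2 * t + ph[1]))
    if noise_mv > 0:
        ecg = ecg + noise_mv * rng.standard_normal(n)
    return ecg


def default_emotion_profiles(separation: float = 1.0) -> list[EmotionProfile]:
    """The four class-conditional parameter distributions.

    A synthetic convention, not a physiological claim: relax = low heart rate
    and low rate jitter; scary = high rate and jitter; disgust = mid rate,
    irregular (fast, jittery) respiration; joy = elevated respiration
    amplitude with mid-high rate. ``separation`` scales the gap between the
    class mean heart rates about their grand mean (1.0 reproduces the
    defaults; 0 collapses all heart-rate means).
    """
    hr = {"relax": 1.00, "scary": 2.00, "disgust": 1.40, "joy": 1.70}
    grand = float(np.mean(list(hr.values())))
    hr = {k: grand + separation * (v - grand) for k, v in hr.items()}
    common = dict(respiration_amplitude=4.0e-3, heart_amplitude=0.5e-3,
                  noise_sd=0.02, artifact_rate=0.5, artifact_amplitude=1.0e-3)
    spec = {
        "relax": dict(heart_rate=hr["relax"], rate_jitter_sd=0.02,
                      respiration_rate=0.25, **common),
        "scary": dict(heart_rate=hr["scary"], rate_jitter_sd=0.10,
                      respiration_rate=0.30, **common),
        "disgust": dict(heart_rate=hr["disgust"], rate_jitter_sd=0.14,
                        respiration_rate=0.45, **common),
        "joy": {**dict(heart_rate=hr["joy"], rate_jitter_sd=0.05,
                       respiration_rate=0.30, **common),
                "respiration_amplitude": 6.0e-3},
    }
    sds = dict(heart_rate=0.05, respiration_rate=0.02, rate_jitter_sd=0.008,
               respiration_amplitude=0.3e-3, heart_amplitude=0.05e-3)
    return [EmotionProfile(label=lab, means=spec[lab], sds=sds) for lab in EMOTION_LABELS]


def generate_dataset(profiles: Sequence[EmotionProfile], n_subjects: int,
                     duration: float, config: RadarConfig, seed: int,
                     with_ecg: bool = True,
                     ecg_sampling_rate: float = 250.0) -> list[Recording]:
    """Generate n_subjects x 4 labelled recordings.

    Each subject receives one persistent random offset applied across all its
    four recordings (the subject-identity signal); the ground-truth profile of
    every recording is stored. Per-recording sub-seeds are derived from the
    master seed via ``SeedSequence([seed, subject, class])`` so any recording
    is independently reproducible.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be at least 2")
    if duration < 125.0:
        raise ValueError("duration must be at least 125 s (120 s window + margin)")
    labels = {p.label for p in profiles}
    missing = set(EMOTION_LABELS) - labels
    if missing:
        raise ValueError(f"missing class profiles: {sorted(missing)}")
    by_label = {p.label: p for p in profiles}
    recordings: list[Recording] = []
    for s in range(n_subjects):
        offset_rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(s), 999]))
        subject_draw = float(offset_rng.standard_normal())
        for c, label in enumerate(EMOTION_LABELS):
            prof_dist = by_label[label]
            subject_offset = prof_dist.subject_offset_sd * subject_draw
            rec_seed = _recording_seed(seed, s, c)
            draw_rng = np.random.default_rng(np.random.SeedSequence([rec_seed, 7]))
            gt = prof_dist.sample(draw_rng, subject_offset)
            disp = simulate_displacement(gt, duration, config.sampling_rate, rec_seed)
            phi = forward_and_demodulate(disp, config)
            if gt.noise_sd > 0:
                phi = phi + gt.noise_sd * _stream_rng(
                    rec_seed, _STREAM_NOISE).standard_normal(phi.size)
            n = phi.size
            time = np.arange(n) / config.sampling_rate
            ecg = None
            if with_ecg:
                ecg = synthesize_ecg(gt, duration, ecg_sampling_rate, rec_seed)
            recordings.append(Recording(
                subject_id=f"S{s:02d}", label=label, time=time, phase_trace=phi,
                sampling_rate=config.sampling_rate, ecg_trace=ecg,
                ecg_sampling_rate=ecg_sampling_rate if with_ecg else None,
                ground_truth=gt))
    return recordings
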