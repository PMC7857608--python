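"""Radar forward model and synthetic dataset generator."""

import numpy as np
import pytest

from rfemotion import (RadarConfig, Recording, VitalSignProfile,
                       default_emotion_profiles, forward_and_demodulate,
                       generate_dataset, simulate_displacement, synthesize_ecg)
from rfemotion.simulate import NyquistError, heart_beat_times


def fft_peaks(trace, fs, n_peaks):
    """Independent oracle: strongest spectral peaks of a trace by FFT."""
    spec = np.abs(np.fft.rfft(trace * np.hanning(trace.size)))
    freqs = np.fft.rfftfreq(trace.size, 1 / fs)
    idx = np.argsort(spec)[::-1]
    found = []
    for i in idx:
        f = freqs[i]
        if all(abs(f - g) > 0.2 for g in found):
            found.append(f)
        if len(found) == n_peaks:
            break
    return sorted(found)


class TestSimulateDisplacement:
    def test_pure_respiration_tone(self):
        p = VitalSignProfile(respiration_rate=0.25, respiration_amplitude=5e-3,
                             respiration_harmonics=1, heart_amplitude=0.0,
                             heart_harmonics=0, rate_jitter_sd=0.0)
        d = simulate_displacement(p, 40.0, 50.0, seed=0)
        t = np.arange(d.size) / 50.0
        np.testing.assert_allclose(d, 5e-3 * np.sin(2 * np.pi * 0.25 * t),
                                   atol=1e-12)
        assert abs(d.max() - 5e-3) < 1e-5

    def test_zero_amplitudes_give_zero_trace(self):
        p = VitalSignProfile(respiration_amplitude=0.0, heart_amplitude=0.0)
        d = simulate_displacement(p, 10.0, 50.0, seed=0)
        assert np.all(d == 0.0)

    def test_heart_harmonics_in_spectrum(self):
        p = VitalSignProfile(respiration_amplitude=0.0, heart_rate=1.2,
                             heart_amplitude=1e-3, heart_harmonics=3,
                             harmonic_decay=0.6, rate_jitter_sd=0.0)
        d = simulate_displacement(p, 120.0, 50.0, seed=0)
        peaks = fft_peaks(d, 50.0, 3)
        np.testing.assert_allclose(peaks, [1.2, 2.4, 3.6], atol=0.05)

    def test_spectral_fidelity_both_rhythms(self, clean_profile):
        d = simulate_displacement(clean_profile, 240.0, 50.0, seed=0)
        df = 1 / 240.0
        spec = np.abs(np.fft.rfft(d * np.hanning(d.size)))
        freqs = np.fft.rfftfreq(d.size, 1 / 50.0)
        resp_band = (freqs > 0.1) & (freqs < 0.35)
        heart_band = (freqs > 0.8) & (freqs < 2.5)
        f_resp = freqs[resp_band][np.argmax(spec[resp_band])]
        f_heart = freqs[heart_band][np.argmax(spec[heart_band])]
        assert abs(f_resp - clean_profile.respiration_rate) <= 2 * df + 1e-9
        assert abs(f_heart - clean_profile.heart_rate) <= 2 * df + 1e-9

    def test_nyquist_rejection(self):
        p = VitalSignProfile(heart_rate=2.0, heart_harmonics=3)
        with pytest.raises(NyquistError):
            simulate_displacement(p, 10.0, 10.0, seed=0)

    def test_reproducible_for_fixed_seed(self):
        p = VitalSignProfile(rate_jitter_sd=0.05, artifact_rate=2.0,
                             artifact_amplitude=1e-3)
        d1 = simulate_displacement(p, 30.0, 50.0, seed=42)
        d2 = simulate_displacement(p, 30.0, 50.0, seed=42)
        np.testing.assert_array_equal(d1, d2)


class TestDemodulation:
    def test_closed_form_amplitude(self, radar_config):
        t = np.arange(0, 40, 1 / 50.0)
        disp = 5e-3 * np.sin(2 * np.pi * 0.25 * t)
        phi = forward_and_demodulate(disp, radar_config)
        expected = 2 * radar_config.omega0 * 5e-3 / radar_config.speed_of_light
        measured = (phi.max() - phi.min()) / 2
        assert measured == pytest.approx(expected, rel=1e-3)

    def test_zero_displacement_constant_offset(self, radar_config):
        phi = forward_and_demodulate(np.zeros(100), radar_config)
        np.testing.assert_allclose(phi, radar_config.phase_offset)
        assert radar_config.phase_offset > 2 * np.pi  # C0 exceeds one turn

    @pytest.mark.parametrize("alpha", [0.5, 2.0, 10.0])
    def test_linearity_in_displacement(self, radar_config, alpha):
        rng = np.random.default_rng(0)
        disp = 1e-3 * rng.standard_normal(500)
        c0 = radar_config.phase_offset
        base = forward_and_demodulate(disp, radar_config) - c0
        scaled = forward_and_demodulate(alpha * disp, radar_config) - c0
        # C0 ~ 73 rad dominates the ~0.1 rad fluctuation, so the comparison
        # is absolute at the cancellation floor of double precision
        np.testing.assert_allclose(scaled, alpha * base, atol=1e-9)

    def test_unwrapping_restores_continuity(self, radar_config):
        t = np.arange(0, 20, 1 / 50.0)
        disp = 40e-3 * np.sin(2 * np.pi * 0.25 * t)  # swings phase past 2 pi
        phi = forward_and_demodulate(disp, radar_config, wrap=True)
        assert np.all(np.abs(np.diff(phi)) < np.pi)
        direct = forward_and_demodulate(disp, radar_config)
        offset = phi[0] - direct[0]
        np.testing.assert_allclose(phi - offset, direct, atol=1e-9)

    def test_rejects_nonfinite(self, radar_config):
        with pytest.raises(ValueError):
            forward_and_demodulate(np.array([0.0, np.nan]), radar_config)


class TestGenerateDataset:
    def test_balanced_sixty_recordings(self, radar_config):
        recs = generate_dataset(default_emotion_profiles(), 15, 150.0,
                                radar_config, seed=5, with_ecg=False)
        assert len(recs) == 60
        labels = [r.label for r in recs]
        assert all(labels.count(lab) == 15 for lab in set(labels))

    def test_deterministic_regeneration(self, radar_config):
        a = generate_dataset(default_emotion_profiles(), 2, 130.0,
                             radar_config, seed=9, with_ecg=True)
        b = generate_dataset(default_emotion_profiles(), 2, 130.0,
                             radar_config, seed=9, with_ecg=True)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.phase_trace, rb.phase_trace)
            np.testing.assert_array_equal(ra.ecg_trace, rb.ecg_trace)

    def test_class_mean_heart_rate_matches_profile(self, radar_config):
        profiles = default_emotion_profiles()
        recs = generate_dataset(profiles, 12, 130.0, radar_config, seed=3,
                                with_ecg=False)
        by_label = {p.label: p for p in profiles}
        for lab in by_label:
            rates = [r.ground_truth.heart_rate for r in recs if r.label == lab]
            mu = by_label[lab].means["heart_rate"]
            # sd combines within-class draw and subject offset
            sd = np.sqrt(0.05 ** 2 + (0.03 * mu) ** 2)
            se = sd / np.sqrt(len(rates))
            assert abs(np.mean(rates) - mu) < 3 * se + 1e-3

    def test_missing_class_profile_rejected(self, radar_config):
        with pytest.raises(ValueError, match="missing"):
            generate_dataset(default_emotion_profiles()[:3], 3, 130.0,
                             radar_config, seed=0)

    def test_ground_truth_stored_and_subject_ids(self, small_dataset):
        assert all(r.ground_truth is not None for r in small_dataset)
        assert len({r.subject_id for r in small_dataset}) == 4


class TestSynthesizeEcg:
    def test_beat_count_no_jitter(self):
        p = VitalSignProfile(heart_rate=1.0, rate_jitter_sd=0.0)
        ecg = synthesize_ecg(p, 60.0, 250.0, seed=0, noise_mv=0.0, wander_mv=0.0)
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(ecg, height=0.5, distance=int(0.25 * 250))
        assert abs(peaks.size - 60) <= 1

    def test_rr_mean_matches_rate(self):
        p = VitalSignProfile(heart_rate=1.25, rate_jitter_sd=0.03)
        ecg = synthesize_ecg(p, 120.0, 250.0, seed=2, noise_mv=0.0, wander_mv=0.0)
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(ecg, height=0.5, distance=int(0.25 * 250))
        rr = np.diff(peaks) / 250.0
        assert np.mean(rr) == pytest.approx(1 / 1.25, rel=0.02)

    def test_exact_kernel_superposition_without_noise(self):
        p = VitalSignProfile(heart_rate=1.0, rate_jitter_sd=0.0)
        a = synthesize_ecg(p, 30.0, 250.0, seed=0, noise_mv=0.0, wander_mv=0.0)
        b = synthesize_ecg(p, 30.0, 250.0, seed=1, noise_mv=0.0, wander_mv=0.0)
        np.testing.assert_array_equal(a, b)  # rng only enters via noise/wander

    def test_paired_modality_beat_count(self):
        """ECG and the radar heart component share the same beat process."""
        p = VitalSignProfile(heart_rate=1.4, rate_jitter_sd=0.08)
        beats = heart_beat_times(p, 90.0, seed=17)
        ecg = synthesize_ecg(p, 90.0, 250.0, seed=17, noise_mv=0.0, wander_mv=0.0)
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(ecg, height=0.5, distance=int(0.25 * 250))
        # peak picking cannot see a beat flush against the trace edge,
        # so compare on the interior
        interior = beats[(beats > 0.3) & (beats < 90.0 - 0.3)]
        detected = peaks[(peaks > 0.3 * 250) & (peaks < (90.0 - 0.3) * 250)] / 250.0
        assert detected.size == interior.size
        np.testing.assert_allclose(detected, interior, atol=0.01)


class TestValidation:
    def test_heart_amplitude_must_be_smaller(self):
        with pytest.raises(ValueError):
            VitalSignProfile(respiration_amplitude=1e-3, heart_amplitude=2e-3)

    def test_radar_config_invariants(self):
        with pytest.raises(ValueError):
            RadarConfig(reflection_magnitude=1.5)
        with pytest.raises(ValueError):
            RadarConfig(static_distance=-1.0)

    def test_recording_requires_uniform_time(self):
        with pytest.raises(ValueError):
            Recording(subject_id="S00", label="relax",
                      time=np.array([0.0, 0.1, 0.3]),
                      phase_trace=np.zeros(3), sampling_rate=10.0)
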