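"""Temporal and spectral feature extraction from gated RF segments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vgn.rf_features import (
    DEFAULT_BAND,
    compute_envelope,
    estimate_noise_floor,
    rise_times,
    spectral_features,
)
from vgn.types import RFGate

from conftest import gabor_gate

FS = 250e6


class TestEnvelope:
    def test_sinusoid_envelope_is_constant_amplitude(self):
        t = np.arange(500) / FS  # integer number of cycles: no leakage
        gate = RFGate(3.5 * np.sin(2 * np.pi * 25e6 * t), fs=FS)
        env = compute_envelope(gate)
        interior = env[32:-32]
        assert np.allclose(interior, 3.5, rtol=1e-3)

    def test_zero_gate_gives_zero_envelope(self):
        env = compute_envelope(RFGate(np.zeros(64), fs=FS))
        assert np.all(env == 0)

    def test_envelope_bounds_rf_pointwise(self):
        gate = gabor_gate()
        env = compute_envelope(gate)
        assert np.all(env >= np.abs(gate.samples) - 1e-9)

    def test_gabor_envelope_peak_within_one_sample_of_gaussian_center(self):
        # Closed form: the envelope of a Gabor pulse is its Gaussian window,
        # so the argmax must land on the modulation center.
        center = 0.4e-6
        k_true = int(round(center * FS))
        env = compute_envelope(gabor_gate(center=center))
        assert abs(int(np.argmax(env)) - k_true) <= 1

    def test_short_gate_rejected(self):
        with pytest.raises(ValueError, match="16"):
            RFGate(np.zeros(8), fs=FS)


def brute_force_rise_times(samples: np.ndarray, fs: float, threshold: float):
    """Exhaustive scan oracle: first local |RF| extremum above threshold."""
    a = np.abs(np.asarray(samples, dtype=float))
    n = a.size
    for i in range(n):
        left = a[i - 1] if i > 0 else -np.inf
        right = a[i + 1] if i < n - 1 else -np.inf
        if a[i] >= left and a[i] >= right and (a[i] > left or a[i] > right):
            if a[i] > threshold:
                return i / fs
    return None


class TestRiseTimes:
    def test_single_impulse_t1_equals_t2(self):
        samples = np.zeros(64)
        samples[17] = 1.0
        feats = rise_times(RFGate(samples, fs=FS), noise_floor=0.01)
        assert feats.valid
        assert feats.t1 == pytest.approx(17 / FS)
        assert feats.t2 == pytest.approx(17 / FS)

    def test_gabor_pulse_extrema_match_brute_force(self):
        gate = gabor_gate(center=0.5e-6)
        noise_floor = 0.01
        feats = rise_times(gate, noise_floor=noise_floor)
        t1_oracle = brute_force_rise_times(gate.samples, FS, 3 * noise_floor)
        assert feats.t1 == pytest.approx(t1_oracle)
        # envelope peak sits at the Gaussian center, before which several
        # RF extrema already exceed the threshold
        assert feats.t1 < feats.t2
        assert feats.t2 == pytest.approx(0.5e-6, abs=1.5 / FS)

    def test_noise_only_gate_marks_features_missing(self):
        rng = np.random.default_rng(0)
        gate = RFGate(0.001 * rng.normal(size=128), fs=FS)
        feats = rise_times(gate, noise_floor=1.0)
        assert not feats.valid
        assert np.isnan(feats.t1) and np.isnan(feats.t2)

    @given(shift=st.integers(min_value=0, max_value=40))
    @settings(max_examples=20, deadline=None)
    def test_time_shift_covariance(self, shift):
        base = gabor_gate(n=192, center=0.3e-6)
        shifted = RFGate(np.concatenate([np.zeros(shift), base.samples]), fs=FS)
        f0 = rise_times(base, noise_floor=0.01)
        f1 = rise_times(shifted, noise_floor=0.01)
        assert f1.t1 - f0.t1 == pytest.approx(shift / FS, abs=1e-12)
        assert f1.t2 - f0.t2 == pytest.approx(shift / FS, abs=1e-12)

    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_amplitude_invariance(self, scale):
        base = gabor_gate()
        scaled = RFGate(scale * base.samples, fs=FS)
        f0 = rise_times(base, noise_floor=1e-4)
        f1 = rise_times(scaled, noise_floor=1e-4 * scale)
        assert f1.t1 == f0.t1 and f1.t2 == f0.t2

    @given(seed=st.integers(min_value=0, max_value=500))
    @settings(max_examples=30, deadline=None)
    def test_oracle_equivalence_on_short_gates(self, seed):
        rng = np.random.default_rng(seed)
        samples = rng.normal(size=64)
        noise_floor = 0.1
        feats = rise_times(RFGate(samples, fs=FS), noise_floor=noise_floor)
        oracle = brute_force_rise_times(samples, FS, 3 * noise_floor)
        if oracle is None:
            assert not feats.valid
        else:
            assert feats.t1 == pytest.approx(oracle)


class TestSpectralFeatures:
    def test_white_spectrum_flat_slope_and_centered_centroid(self):
        # an impulse has an exactly flat spectrum under a boxcar window
        samples = np.zeros(512)
        samples[256] = 1.0
        feats = spectral_features(RFGate(samples, fs=FS), window="boxcar")
        lo, hi = DEFAULT_BAND
        assert feats.slope == pytest.approx(0.0, abs=1e-12)
        assert feats.f_c == pytest.approx((lo + hi) / 2, rel=0.02)

    def test_linear_db_spectrum_slope_recovered_exactly(self):
        # Build a time signal whose boxcar spectrum is exactly linear in dB
        # over the band, by inverse transform of the constructed spectrum.
        n = 512
        freqs = np.fft.rfftfreq(n, d=1.0 / FS)
        slope_true = -1.5e-6  # dB per Hz
        intercept_true = 10.0
        power_db = intercept_true + slope_true * freqs
        spectrum = 10 ** (power_db / 20.0)  # amplitude whose power in dB is linear
        samples = np.fft.irfft(spectrum, n=n)
        feats = spectral_features(RFGate(samples, fs=FS), window="boxcar")
        assert feats.slope == pytest.approx(slope_true, rel=1e-6)
        assert feats.intercept == pytest.approx(intercept_true, rel=1e-6)

    def test_gabor_centroid_at_transducer_center_frequency(self):
        feats = spectral_features(gabor_gate(n=512), band=(15e6, 35e6))
        bin_width = FS / 512
        assert feats.f_c == pytest.approx(25e6, abs=bin_width)

    def test_zero_power_gate_rejected(self):
        with pytest.raises(ValueError, match="zero-power"):
            spectral_features(RFGate(np.zeros(64), fs=FS))

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band"):
            spectral_features(gabor_gate(), band=(15e6, 200e6))

    def test_narrow_band_rejected(self):
        gate = gabor_gate(n=32)  # 32 samples -> bins ~7.8 MHz apart
        with pytest.raises(ValueError, match="bins"):
            spectral_features(gate, band=(20e6, 30e6))

    @given(scale=st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=20, deadline=None)
    def test_amplitude_scaling_shifts_intercept_only(self, scale):
        base = gabor_gate(n=512)
        scaled = RFGate(scale * base.samples, fs=FS)
        f0 = spectral_features(base)
        f1 = spectral_features(scaled)
        assert f1.f_c == pytest.approx(f0.f_c, rel=1e-9)
        assert f1.slope == pytest.approx(f0.slope, rel=1e-6)
        assert f1.intercept - f0.intercept == pytest.approx(
            20 * np.log10(scale), abs=1e-6
        )


def test_noise_floor_estimate_tracks_noise_sd():
    rng = np.random.default_rng(3)
    noise = rng.normal(0, 0.05, size=4096)
    est = estimate_noise_floor(noise)
    assert est == pytest.approx(0.05, rel=0.1)
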