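"""Temporal and spectral features of gated vessel echoes.

Each segmented vessel contributes a gated RF A-line segment.  Its temporal
response is summarized by two rise times (delay of the first RF peak and of
the envelope peak) and its spectral response by three quantities standard in
quantitative ultrasound: the band-limited spectral centroid, and the slope
and 0-Hz intercept of a straight line fitted to the power spectrum in dB
over the analysis band.

Reference zero for the rise times is the gate start (first sample of the
vessel's depth gate).  Spectra are used uncalibrated: no reference-phantom
normalization is applied, which is acceptable as long as features are only
compared within one acquisition system.
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

import numpy as np
from scipy.signal import hilbert, get_window

from .types import RFGate, SpectralFeatures, TemporalFeatures

#: Default analysis band: the transducer's -6 dB band around 25 MHz.
DEFAULT_BAND = (15e6, 35e6)

#: Detection multiple applied to the noise floor for the first-peak search.
PEAK_THRESHOLD_FACTOR = 3.0

MIN_BAND_BINS = 5


def compute_envelope(gate: RFGate) -> np.ndarray:
    """Magnitude of the analytic signal of the gated RF.

    Non-negative, and an upper bound of ``|samples|`` pointwise up to
    numerical tolerance at the gate boundaries.
    """
    return np.abs(hilbert(gate.samples))


def estimate_noise_floor(samples: np.ndarray) -> float:
    """Robust noise-floor estimate: scaled median absolute deviation.

    Intended as a fallback when no signal-free region is available; the
    MAD is insensitive to the sparse high-amplitude vessel echoes.  Large
    frames are subsampled on a fixed stride: the estimate is statistical,
    and ~64k samples pin the MAD far more tightly than it matters.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size > 65536:
        samples = samples[:: samples.size // 65536]
    return float(1.4826 * np.median(np.abs(samples - np.median(samples))))


def _local_extrema(absval: np.ndarray) -> np.ndarray:
    """Indices of local maxima of ``absval``, endpoints included.

    A sample is an extremum if it is >= both neighbors and > at least one
    (so flat plateaus contribute their leading edge); endpoints use the
    single available neighbor.
    """
    a = np.asarray(absval, dtype=float)
    n = a.size
    left = np.empty(n)
    right = np.empty(n)
    left[0], left[1:] = -np.inf, a[:-1]
    right[-1], right[:-1] = -np.inf, a[1:]
    is_ext = (a >= left) & (a >= right) & ((a > left) | (a > right))
    return np.flatnonzero(is_ext)


def rise_times(gate: RFGate, noise_floor: Optional[float] = None) -> TemporalFeatures:
    """Rise times t1 (first RF peak) and t2 (envelope peak) in seconds.

    t1 is the delay from the gate start to the first local extremum of the
    absolute RF exceeding ``PEAK_THRESHOLD_FACTOR * noise_floor``; t2 the
    delay to the global envelope maximum.  If no sample exceeds the
    threshold the features are missing: NaNs with ``valid=False``.
    """
    if noise_floor is None:
        noise_floor = estimate_noise_floor(gate.samples)
    if noise_floor < 0:
        raise ValueError(f"noise floor must be non-negative, got {noise_floor}")

    absval = np.abs(gate.samples)
    threshold = PEAK_THRESHOLD_FACTOR * noise_floor
    ext = _local_extrema(absval)
    ext = ext[absval[ext] > threshold]
    if ext.size == 0:
        return TemporalFeatures(math.nan, math.nan, valid=False)

    envelope = compute_envelope(gate)
    t1 = float(ext[0]) / gate.fs
    t2 = float(np.argmax(envelope)) / gate.fs
    return TemporalFeatures(t1, t2, valid=True)


def spectral_features(
    gate: RFGate,
    band: Tuple[float, float] = DEFAULT_BAND,
    window: str = "hann",
) -> SpectralFeatures:
    """Centroid frequency and midband dB-line fit over ``band``.

    The gate is windowed (Hann by default), its one-sided power spectrum
    computed, and within the band:

    * ``f_c``  — power-weighted spectral centroid (linear power);
    * ``slope``, ``intercept`` — ordinary least squares fit of the
      spectrum in dB against frequency, the intercept evaluated at 0 Hz.
    """
    lo, hi = band
    nyquist = gate.fs / 2
    if not (0 < lo < hi < nyquist):
        raise ValueError(f"band {band} must lie strictly inside (0, {nyquist:g})")

    w = get_window(window, gate.samples.size, fftbins=True)
    spectrum = np.fft.rfft(gate.samples * w)
    power = np.abs(spectrum) ** 2
    freqs = np.fft.rfftfreq(gate.samples.size, d=1.0 / gate.fs)

    in_band = (freqs >= lo) & (freqs <= hi)
    if int(in_band.sum()) < MIN_BAND_BINS:
        raise ValueError(
            f"analysis band {band} spans {int(in_band.sum())} frequency bins; "
            f"need >= {MIN_BAND_BINS}"
        )
    p = power[in_band]
    f = freqs[in_band]
    total = p.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("zero-power gate: spectral features undefined")

    f_c = float((f * p).sum() / total)
    p_db = 10.0 * np.log10(np.maximum(p, np.finfo(float).tiny))
    slope, intercept = np.polyfit(f, p_db, 1)
    return SpectralFeatures(f_c=f_c, slope=float(slope), intercept=float(intercept))
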