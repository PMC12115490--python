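"""Per-window step-frequency estimation from the FFT magnitude spectrum.

The estimator takes the highest spectral peak inside the physiologic cadence
band (0.3-4.6 Hz); if no in-band peak clears the magnitude floor the window's
step frequency is 0.  A harmonic-disambiguation rule handles gaits whose
second harmonic dominates the spectrum (e.g. running or Trendelenburg-style
walking with a strong lateral component): when a lower-frequency peak sits
below 60% of the dominant peak's frequency but carries at least 60% of its
magnitude, the lower peak is taken as the step frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from fftgait.preprocessing import TimeWindow


@dataclass(frozen=True)
class SpectralConfig:
    """Band limits and peak-selection rule constants.

    freq_ratio / mag_ratio are the two 60% constants of the harmonic rule.
    ``target_resolution`` caps the FFT bin spacing (Hz): a raw 5 s window
    gives 0.2 Hz bins, too coarse for cadence, so windows are zero-padded to
    at least ``zero_pad_factor`` times their length and further until the bin
    spacing is at or below the target.  ``magnitude_floor`` is the fraction
    of the spectrum maximum below which local maxima are not treated as
    peaks.
    """

    band_low: float = 0.3
    band_high: float = 4.6
    freq_ratio: float = 0.6
    mag_ratio: float = 0.6
    zero_pad_factor: int = 4
    target_resolution: float = 0.05
    magnitude_floor: float = 0.05
    taper: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("need 0 < band_low < band_high")
        if not (0 < self.freq_ratio < 1 and 0 < self.mag_ratio < 1):
            raise ValueError("rule ratios must lie in (0, 1)")
        if self.zero_pad_factor < 1:
            raise ValueError("zero_pad_factor must be >= 1")


DEFAULT_CONFIG = SpectralConfig()


@dataclass(frozen=True)
class Spectrum:
    """One-sided FFT magnitude spectrum on a uniform frequency grid."""

    freqs: np.ndarray
    mags: np.ndarray

    @property
    def resolution(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def window_spectrum(tw: TimeWindow, cfg: SpectralConfig = DEFAULT_CONFIG) -> Spectrum:
    """Magnitude spectrum of the mean-removed window, zero-padded for cadence
    resolution."""
    x = np.asarray(tw.samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("window contains non-finite samples")
    if len(x) < tw.sample_rate:
        raise ValueError("window must contain at least 1 s of samples")
    x = x - np.mean(x)
    if cfg.taper:
        x = x * np.hanning(len(x))
    nfft = max(
        cfg.zero_pad_factor * len(x),
        int(np.ceil(tw.sample_rate / cfg.target_resolution)),
    )
    mags = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / tw.sample_rate)
    return Spectrum(freqs=freqs, mags=mags)


def _candidate_peaks(spec: Spectrum, cfg: SpectralConfig):
    """In-band local maxima clearing the magnitude floor, as (freq, mag) arrays."""
    global_max = float(np.max(spec.mags)) if len(spec.mags) else 0.0
    if global_max <= 0.0:
        return np.empty(0), np.empty(0)
    idx, _ = sps.find_peaks(spec.mags, height=cfg.magnitude_floor * global_max)
    f = spec.freqs[idx]
    in_band = (f >= cfg.band_low) & (f <= cfg.band_high)
    return f[in_band], spec.mags[idx][in_band]


def select_step_frequency(spec: Spectrum, cfg: SpectralConfig = DEFAULT_CONFIG) -> float:
    """Step frequency (Hz) for one window; 0 when no in-band peak exists.

    P is the highest-magnitude in-band candidate (ties broken toward the
    lower frequency, favoring the fundamental over a harmonic).  If a
    lower-frequency candidate Q satisfies freq(Q) < freq_ratio * freq(P) and
    mag(Q) >= mag_ratio * mag(P), Q's frequency is returned instead — the
    harmonic rule, applied once.
    """
    freqs, mags = _candidate_peaks(spec, cfg)
    if len(freqs) == 0:
        return 0.0
    order = np.lexsort((freqs, -mags))  # by magnitude desc, then frequency asc
    p = order[0]
    lower = np.flatnonzero(freqs < freqs[p])
    if len(lower):
        q = lower[np.lexsort((freqs[lower], -mags[lower]))[0]]
        if freqs[q] < cfg.freq_ratio * freqs[p] and mags[q] >= cfg.mag_ratio * mags[p]:
            return float(freqs[q])
    return float(freqs[p])


def window_step_frequency(tw: TimeWindow, cfg: SpectralConfig = DEFAULT_CONFIG) -> float:
    """Convenience: spectrum + peak selection in one call."""
    return select_step_frequency(window_spectrum(tw, cfg), cfg)
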