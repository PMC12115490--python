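"""Detrending, bandpass filtering and fixed 5 s windowing of the signal.

The anteroposterior axis is bandpass-filtered to the physiologic cadence band
(0.3-4.6 Hz by default) with a 4th-order Butterworth applied forward-backward
(zero phase, so step peaks are not shifted relative to second boundaries),
then cut into non-overlapping 5 s time windows starting at t = 0.  A trailing
partial window is kept if it is at least 1 s long and flagged as partial; its
true duration is carried through all per-window formulas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from fftgait.core_io import AccelRecording

DEFAULT_BAND = (0.3, 4.6)  # Hz
WINDOW_SECONDS = 5.0
MIN_PARTIAL_SECONDS = 1.0


class NyquistError(ValueError):
    """Sample rate too low for the requested passband."""


@dataclass(frozen=True)
class TimeWindow:
    """A fixed-duration segment of the preprocessed anteroposterior signal."""

    index: int
    start: float
    end: float
    samples: np.ndarray
    sample_rate: float
    partial: bool = False

    @property
    def duration(self) -> float:
        return self.end - self.start


def preprocess_signal(
    rec: AccelRecording,
    band_low: float = DEFAULT_BAND[0],
    band_high: float = DEFAULT_BAND[1],
    order: int = 4,
) -> AccelRecording:
    """Detrend and bandpass the anteroposterior axis; other axes untouched.

    Zero-phase (forward-backward) Butterworth filtering keeps the output the
    same length as the input and preserves peak timing.  The global mean is
    removed first; the passband excludes DC so baseline drift is suppressed
    twice over.
    """
    if band_low <= 0 or band_low >= band_high:
        raise ValueError(f"need 0 < band_low < band_high, got ({band_low}, {band_high})")
    if rec.sample_rate <= 2 * band_high:
        raise NyquistError(
            f"sample rate {rec.sample_rate} Hz must exceed twice the upper band edge "
            f"({band_high} Hz)"
        )
    x = rec.anteroposterior - np.mean(rec.anteroposterior)
    sos = sps.butter(order, [band_low, band_high], btype="bandpass", fs=rec.sample_rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return rec.with_anteroposterior(y)


def segment_windows(rec: AccelRecording, window_s: float = WINDOW_SECONDS):
    """Cut the recording into contiguous non-overlapping windows from t = 0.

    Returns ``floor(duration / window_s)`` full windows plus one trailing
    partial window when at least ``MIN_PARTIAL_SECONDS`` remain.  A recording
    shorter than 1 s yields no windows.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    fs = rec.sample_rate
    x = rec.anteroposterior
    n_per = int(round(window_s * fs))
    windows = []
    idx = 0
    pos = 0
    while pos + n_per <= len(x):
        windows.append(
            TimeWindow(
                index=idx,
                start=pos / fs,
                end=(pos + n_per) / fs,
                samples=x[pos : pos + n_per],
                sample_rate=fs,
            )
        )
        idx += 1
        pos += n_per
    remaining = len(x) - pos
    if remaining >= MIN_PARTIAL_SECONDS * fs:
        windows.append(
            TimeWindow(
                index=idx,
                start=pos / fs,
                end=len(x) / fs,
                samples=x[pos:],
                sample_rate=fs,
                partial=True,
            )
        )
    return windows
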