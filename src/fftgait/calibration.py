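"""Activity threshold from the slow-walk calibration and per-second classification.

The slowest-walk trial (SC-L1) provides one acceleration peak per step; the
activity threshold is the mean plus one standard deviation of those peaks
(population-form sigma, divisor m).  A 1 s slice of a window is classified
active when the maximum absolute preprocessed acceleration in the slice
reaches the threshold; inactive seconds contribute no steps downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from fftgait.core_io import AccelRecording
from fftgait.preprocessing import TimeWindow

logger = logging.getLogger(__name__)

#: shortest physiologic step period (s) — the inverse of the 4.6 Hz band edge
MIN_STEP_PERIOD = 1.0 / 4.6

#: fallback threshold (G) for exploratory runs without an SC-L1 recording
DEFAULT_FALLBACK_THRESHOLD = 0.05

MIN_PEAKS = 3


class CalibrationError(ValueError):
    """SC-L1 trace unusable for threshold derivation."""


@dataclass(frozen=True)
class CalibrationProfile:
    """Per-step peak statistics and the derived activity threshold (G)."""

    peaks: np.ndarray
    mu: float
    sigma: float
    threshold: float

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "peaks": [float(p) for p in self.peaks],
                    "mu": self.mu,
                    "sigma": self.sigma,
                    "threshold": self.threshold,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "CalibrationProfile":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            peaks=np.asarray(d["peaks"], dtype=float),
            mu=float(d["mu"]),
            sigma=float(d["sigma"]),
            threshold=float(d["threshold"]),
        )


def detect_calibration_peaks(scl1: AccelRecording) -> np.ndarray:
    """Per-step maximum accelerations from a preprocessed SC-L1 trace.

    Local maxima separated by at least the minimum physiologic step period
    (1/4.6 s) with prominence >= 10% of the trace's maximum absolute value;
    the separation constraint yields one peak per step.
    """
    x = scl1.anteroposterior
    if scl1.duration < 5.0:
        raise CalibrationError("SC-L1 trace shorter than 5 s")
    scale = float(np.max(np.abs(x))) if len(x) else 0.0
    if scale == 0.0:
        raise CalibrationError("SC-L1 trace is identically zero")
    distance = max(1, int(round(MIN_STEP_PERIOD * scl1.sample_rate)))
    idx, _ = sps.find_peaks(x, distance=distance, prominence=0.1 * scale)
    peaks = x[idx]
    peaks = peaks[peaks > 0]
    if len(peaks) < MIN_PEAKS:
        raise CalibrationError(f"only {len(peaks)} usable peaks found (need >= {MIN_PEAKS})")
    return peaks


def compute_threshold(peaks) -> CalibrationProfile:
    """Activity threshold = mu + sigma of the per-step peaks.

    sigma uses the population divisor m, mirroring the defining formula.
    """
    peaks = np.asarray(peaks, dtype=float)
    if len(peaks) < MIN_PEAKS:
        raise CalibrationError(f"need at least {MIN_PEAKS} peaks, got {len(peaks)}")
    if np.any(peaks <= 0):
        raise CalibrationError("all peaks must be positive")
    mu = float(np.mean(peaks))
    sigma = float(np.sqrt(np.mean((peaks - mu) ** 2)))
    return CalibrationProfile(peaks=peaks, mu=mu, sigma=sigma, threshold=mu + sigma)


def fallback_profile(threshold: float = DEFAULT_FALLBACK_THRESHOLD) -> CalibrationProfile:
    """Profile around a directly supplied threshold (no SC-L1 available)."""
    logger.warning(
        "no SC-L1 calibration: using supplied activity threshold %.3f G; "
        "active/inactive classification is uncalibrated",
        threshold,
    )
    return CalibrationProfile(peaks=np.empty(0), mu=threshold, sigma=0.0, threshold=threshold)


def classify_active_seconds(tw: TimeWindow, threshold: float):
    """Classify each 1 s slice of a window as active or inactive.

    A slice is active iff the maximum absolute signal over the slice reaches
    ``threshold`` (the absolute value accommodates device orientations where
    step impacts present as negative excursions after detrending).  The last
    slice of a partial window may be shorter than 1 s.

    Returns
    -------
    (active_seconds, mask) : active time in seconds (the final short slice
    contributes its true duration), and the per-slice boolean mask.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fs = tw.sample_rate
    n_per = int(round(fs))
    x = tw.samples
    mask = []
    active = 0.0
    pos = 0
    while pos < len(x):
        sl = x[pos : pos + n_per]
        is_active = bool(np.max(np.abs(sl)) >= threshold)
        mask.append(is_active)
        if is_active:
            active += len(sl) / fs
        pos += n_per
    return active, np.asarray(mask, dtype=bool)
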