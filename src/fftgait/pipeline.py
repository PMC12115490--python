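"""End-to-end orchestration: calibrate -> preprocess -> estimate -> summarize.

The library entry point is :func:`estimate_bout`, which takes an in-memory
recording; :func:`run_pipeline` wraps it with file I/O, calibration handling,
optional ground-truth comparison, and a run manifest echoing every configured
constant so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fftgait import agreement, calibration, core_io, gait_metrics, preprocessing, spectral
from fftgait.core_io import AccelRecording, RecordingSchema, SubjectProfile
from fftgait.step_length import EQ1_COEFFICIENTS, StepLengthCoefficients

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, defaulting to the published constants."""

    bout_path: str | None = None
    scl1_path: str | None = None
    ground_truth_path: str | None = None
    subject: SubjectProfile | None = None
    schema: RecordingSchema = field(default_factory=RecordingSchema)
    band_low: float = 0.3
    band_high: float = 4.6
    window_s: float = 5.0
    spectral: spectral.SpectralConfig = field(default_factory=spectral.SpectralConfig)
    coefficients: StepLengthCoefficients = EQ1_COEFFICIENTS
    threshold: float | None = None  # direct override when no SC-L1 exists
    averaging: str = "total"
    output_dir: str = "."

    def manifest(self) -> dict:
        return {
            "bout_path": self.bout_path,
            "scl1_path": self.scl1_path,
            "ground_truth_path": self.ground_truth_path,
            "subject": None
            if self.subject is None
            else {"subject_id": self.subject.subject_id, "height": self.subject.height, "dmd": self.subject.dmd},
            "band_low": self.band_low,
            "band_high": self.band_high,
            "window_s": self.window_s,
            "spectral": {
                "band_low": self.spectral.band_low,
                "band_high": self.spectral.band_high,
                "freq_ratio": self.spectral.freq_ratio,
                "mag_ratio": self.spectral.mag_ratio,
                "zero_pad_factor": self.spectral.zero_pad_factor,
                "target_resolution": self.spectral.target_resolution,
                "magnitude_floor": self.spectral.magnitude_floor,
                "taper": self.spectral.taper,
            },
            "coefficients": {k: getattr(self.coefficients, k) for k in
                             ("b_sf", "b_h", "b_sf_h", "b_0", "d_0", "d_sf", "d_h", "d_sf_h")},
            "threshold": self.threshold,
            "averaging": self.averaging,
        }


def calibrate_threshold(scl1: AccelRecording, band_low: float = 0.3, band_high: float = 4.6):
    """Preprocess an SC-L1 trace and derive the activity threshold."""
    filtered = preprocessing.preprocess_signal(scl1, band_low, band_high)
    peaks = calibration.detect_calibration_peaks(filtered)
    return calibration.compute_threshold(peaks)


def estimate_bout(
    rec: AccelRecording,
    subject: SubjectProfile,
    threshold: float,
    band_low: float = 0.3,
    band_high: float = 4.6,
    window_s: float = 5.0,
    spectral_cfg: spectral.SpectralConfig | None = None,
    coefficients: StepLengthCoefficients = EQ1_COEFFICIENTS,
    averaging: str = "total",
):
    """Run preprocessing, windowing, cadence, and metrics on one recording.

    Returns
    -------
    (window_estimates, bout_summary)
    """
    cfg = spectral_cfg or spectral.SpectralConfig(band_low=band_low, band_high=band_high)
    filtered = preprocessing.preprocess_signal(rec, band_low, band_high)
    windows = preprocessing.segment_windows(filtered, window_s)
    if not windows:
        raise PipelineError("segment", "recording too short to form any window")
    estimates = []
    for tw in windows:
        active_s, _ = calibration.classify_active_seconds(tw, threshold)
        sf = spectral.window_step_frequency(tw, cfg)
        est = gait_metrics.window_metrics(tw, active_s, sf, subject, coefficients)
        logger.debug(
            "window %d: sf=%.3f Hz active=%.1f s steps=%.2f", tw.index, sf, active_s, est.steps
        )
        estimates.append(est)
    summary = gait_metrics.summarize_bout(estimates, averaging=averaging)
    return estimates, summary


def run_pipeline(cfg: PipelineConfig):
    """File-level pipeline: read inputs, estimate, write outputs + manifest.

    Returns a dict with keys ``estimates``, ``summary``, ``profile`` and
    (when ground truth is supplied) ``agreement``.
    """
    if cfg.bout_path is None or cfg.subject is None:
        raise PipelineError("config", "bout_path and subject are required")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        rec = core_io.read_recording(cfg.bout_path, cfg.schema)
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        raise PipelineError("read", str(exc)) from exc

    if cfg.scl1_path is not None:
        try:
            scl1 = core_io.read_recording(cfg.scl1_path, cfg.schema)
            profile = calibrate_threshold(scl1, cfg.band_low, cfg.band_high)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("calibrate", str(exc)) from exc
    elif cfg.threshold is not None:
        profile = calibration.fallback_profile(cfg.threshold)
    else:
        profile = calibration.fallback_profile()

    try:
        estimates, summary = estimate_bout(
            rec,
            cfg.subject,
            profile.threshold,
            cfg.band_low,
            cfg.band_high,
            cfg.window_s,
            cfg.spectral,
            cfg.coefficients,
            cfg.averaging,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("estimate", str(exc)) from exc

    core_io.write_window_table(estimates, out / "windows.csv")
    gait_metrics.export_timeline(estimates, out / "timeline.csv")
    profile.to_json(out / "calibration.json")
    summary_dict = {k: getattr(summary, k) for k in summary.__dataclass_fields__}
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_dict, fh, indent=2)
    with open(out / "manifest.json", "w") as fh:
        json.dump(cfg.manifest(), fh, indent=2)

    result = {"estimates": estimates, "summary": summary, "profile": profile}

    if cfg.ground_truth_path is not None:
        try:
            import pandas as pd

            gt = pd.read_csv(cfg.ground_truth_path)
            reports = {}
            pairs = {
                "total_steps": ("total_steps", summary.total_steps),
                "avg_step_frequency": ("avg_step_frequency", summary.avg_step_frequency),
                "avg_step_length": ("avg_step_length", summary.avg_step_length),
                "avg_step_velocity": ("avg_step_velocity", summary.avg_step_velocity),
                "total_distance": ("total_distance", summary.total_distance),
            }
            # single-bout ground truth: report signed percent error per metric
            errors = {}
            for name, (col, est) in pairs.items():
                if col in gt.columns:
                    ref = float(gt[col].iloc[0])
                    errors[name] = {
                        "reference": ref,
                        "estimate": est,
                        "pct_error": 100.0 * (est - ref) / ref if ref else float("nan"),
                    }
            with open(out / "comparison.json", "w") as fh:
                json.dump(errors, fh, indent=2)
            result["agreement"] = errors
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("compare", str(exc)) from exc

    return result
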