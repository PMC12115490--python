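"""Per-window and bout-level gait metrics.

Per window: steps = step frequency x active seconds; step length from the
cadence/height regression; distance = steps x step length; velocity =
distance / ACTIVE seconds.  Bout level: totals are sums over windows, while
average step frequency and average step velocity divide by TOTAL duration
(active plus inactive), reflecting overall mobility density rather than pure
gait performance; an ``averaging="active"`` option divides by active time
instead.  The 95th-percentile step velocity is computed over per-window
velocities of active windows — a window-level approximation of the
stride-velocity-95 concept (no per-step timing exists in this method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from fftgait.core_io import SubjectProfile
from fftgait.preprocessing import TimeWindow
from fftgait.step_length import EQ1_COEFFICIENTS, StepLengthCoefficients, predict_step_length


@dataclass(frozen=True)
class WindowEstimate:
    """Gait metrics for a single time window."""

    index: int
    start: float
    duration: float
    active_s: float
    step_frequency: float
    steps: float
    step_length: float
    distance: float
    velocity: float


@dataclass(frozen=True)
class BoutSummary:
    """Bout-level totals and averages over all windows."""

    total_duration: float
    active_duration: float
    total_steps: float
    total_steps_rounded: int
    avg_step_frequency: float
    avg_step_length: float
    avg_step_velocity: float
    total_distance: float
    p95_step_velocity: float
    n_windows: int


def window_metrics(
    tw: TimeWindow,
    active_s: float,
    step_frequency: float,
    subject: SubjectProfile,
    coefficients: StepLengthCoefficients = EQ1_COEFFICIENTS,
) -> WindowEstimate:
    """Combine a window's cadence and active time into step/distance/velocity."""
    if step_frequency < 0:
        raise ValueError("step frequency must be nonnegative")
    if not (0 <= active_s <= tw.duration + 1e-9):
        raise ValueError(f"active_s {active_s} outside [0, {tw.duration}]")
    if step_frequency == 0.0:
        return WindowEstimate(tw.index, tw.start, tw.duration, active_s, 0.0, 0.0, 0.0, 0.0, 0.0)
    steps = step_frequency * active_s
    sl = predict_step_length(step_frequency, subject.height, subject.dmd, coefficients)
    distance = steps * sl
    velocity = distance / active_s if active_s > 0 else 0.0
    return WindowEstimate(
        index=tw.index,
        start=tw.start,
        duration=tw.duration,
        active_s=active_s,
        step_frequency=step_frequency,
        steps=steps,
        step_length=sl,
        distance=distance,
        velocity=velocity,
    )


def summarize_bout(estimates, averaging: str = "total") -> BoutSummary:
    """Aggregate window estimates into bout totals and averages.

    ``averaging="total"`` divides average step frequency and velocity by the
    total bout duration (the default convention); ``"active"`` divides by
    active time only.
    """
    est = list(estimates)
    if not est:
        raise ValueError("cannot summarize an empty bout")
    if averaging not in ("total", "active"):
        raise ValueError("averaging must be 'total' or 'active'")
    total_duration = float(sum(e.duration for e in est))
    active_duration = float(sum(e.active_s for e in est))
    total_steps = float(sum(e.steps for e in est))
    total_distance = float(sum(e.distance for e in est))
    denom = total_duration if averaging == "total" else active_duration
    avg_sf = total_steps / denom if denom > 0 else 0.0
    avg_vel = total_distance / denom if denom > 0 else 0.0
    avg_sl = total_distance / total_steps if total_steps > 0 else 0.0
    active_vels = [e.velocity for e in est if e.active_s > 0 and e.steps > 0]
    p95 = float(np.percentile(active_vels, 95)) if active_vels else 0.0
    return BoutSummary(
        total_duration=total_duration,
        active_duration=active_duration,
        total_steps=total_steps,
        total_steps_rounded=int(round(total_steps)),
        avg_step_frequency=avg_sf,
        avg_step_length=avg_sl,
        avg_step_velocity=avg_vel,
        total_distance=total_distance,
        p95_step_velocity=p95,
        n_windows=len(est),
    )


def timeline_frame(estimates) -> pd.DataFrame:
    """Long-format per-window table with a nondecreasing cumulative distance."""
    est = list(estimates)
    if not est:
        raise ValueError("cannot export an empty timeline")
    df = pd.DataFrame(
        {
            "start_s": [e.start for e in est],
            "step_frequency_hz": [e.step_frequency for e in est],
            "steps": [e.steps for e in est],
            "step_length_m": [e.step_length for e in est],
            "velocity_mps": [e.velocity for e in est],
        }
    )
    df["cumulative_distance_m"] = np.cumsum([e.distance for e in est])
    return df


def export_timeline(estimates, path) -> None:
    """Write the timeline table as CSV (floats at 6 decimals)."""
    timeline_frame(estimates).to_csv(path, index=False, float_format="%.6f")
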