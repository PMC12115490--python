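"""Data model for accelerometer recordings and subjects, plus CSV readers/writers.

The canonical internal acceleration unit is G; inputs declared in m/s^2 are
converted at the boundary.  Timestamps are seconds from bout start.  Irregular
sampling is resampled to a uniform grid at the median observed rate by linear
interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STANDARD_GRAVITY = 9.80665  # m/s^2 per G

#: relative jitter in sample spacing tolerated before resampling kicks in
_UNIFORMITY_RTOL = 1e-3


class SchemaError(ValueError):
    """Input file does not match the declared column schema."""


class DataError(ValueError):
    """Input file contains invalid values (non-finite, non-monotonic...)."""


@dataclass(frozen=True)
class SubjectProfile:
    """Participant covariates entering the step-length model.

    Parameters
    ----------
    subject_id : opaque identifier.
    height : standing height in meters.
    dmd : 1 for Duchenne muscular dystrophy, 0 for typically developing.
    """

    subject_id: str
    height: float
    dmd: int

    def __post_init__(self) -> None:
        if not (0.5 <= self.height <= 2.5):
            raise ValueError(f"height {self.height} m outside plausible range [0.5, 2.5]")
        if self.dmd not in (0, 1):
            raise ValueError(f"dmd indicator must be 0 or 1, got {self.dmd!r}")


@dataclass(frozen=True)
class AccelRecording:
    """Uniformly sampled triaxial acceleration trace in G.

    ``t`` is strictly increasing, seconds from bout start.  ``axis_map``
    names which column carries the anteroposterior axis consumed by the
    pipeline (default ``"az"``).
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    sample_rate: float
    axis_map: str = "az"

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise DataError("recording needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise DataError("timestamps must be strictly increasing")
        if self.sample_rate < 10.0:
            raise DataError(
                f"sample_rate {self.sample_rate:.3g} Hz is below the 10 Hz minimum "
                "(Nyquist margin above the 4.6 Hz band edge)"
            )
        for name in ("ax", "ay", "az"):
            a = getattr(self, name)
            if len(a) != len(t):
                raise DataError(f"axis {name} length {len(a)} != time length {len(t)}")
        if self.axis_map not in ("ax", "ay", "az"):
            raise SchemaError(f"axis_map must be one of ax/ay/az, got {self.axis_map!r}")
        object.__setattr__(self, "t", t)
        for name in ("ax", "ay", "az"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    @property
    def duration(self) -> float:
        """Recording span in seconds including the final sample period."""
        return float(self.t[-1] - self.t[0]) + 1.0 / self.sample_rate

    @property
    def anteroposterior(self) -> np.ndarray:
        """The single axis the pipeline consumes."""
        return getattr(self, self.axis_map)

    def with_anteroposterior(self, values: np.ndarray) -> "AccelRecording":
        """Return a copy with the anteroposterior axis replaced (e.g. filtered)."""
        return replace(self, **{self.axis_map: np.asarray(values, dtype=float)})


@dataclass(frozen=True)
class RecordingSchema:
    """Column mapping for :func:`read_recording`.

    ``units`` is ``"G"`` or ``"m/s2"``; m/s^2 values are divided by 9.80665.
    """

    time: str = "t"
    ax: str = "ax"
    ay: str = "ay"
    az: str = "az"
    units: str = "G"
    anteroposterior: str = "az"


def read_recording(path, schema: RecordingSchema | None = None) -> AccelRecording:
    """Read a timestamped triaxial CSV into an :class:`AccelRecording`.

    Non-monotonic timestamps are rejected; irregular sampling is resampled to
    a uniform grid at the median observed rate by linear interpolation, and
    the applied rate is recorded in ``sample_rate``.
    """
    schema = schema or RecordingSchema()
    df = pd.read_csv(path)
    needed = [schema.time, schema.ax, schema.ay, schema.az]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing} in {path} (have {list(df.columns)})")
    if len(df) < 2:
        raise DataError(f"{path}: fewer than 2 samples")
    vals = df[needed].to_numpy(dtype=float)
    bad = ~np.isfinite(vals)
    if bad.any():
        row = int(np.argwhere(bad.any(axis=1))[0][0])
        raise DataError(f"{path}: non-finite value at data row {row}")
    t = vals[:, 0]
    if np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: timestamps not strictly increasing")
    t = t - t[0]
    axes = vals[:, 1:4].T
    if schema.units.lower() in ("m/s2", "m/s^2", "ms2"):
        axes = axes / STANDARD_GRAVITY
    elif schema.units.upper() != "G":
        raise SchemaError(f"unknown units {schema.units!r}; expected 'G' or 'm/s2'")

    dt = np.diff(t)
    if np.max(np.abs(dt - dt.mean())) > _UNIFORMITY_RTOL * dt.mean():
        rate = 1.0 / float(np.median(dt))
        grid = np.arange(int(round(t[-1] * rate)) + 1) / rate
        axes = np.vstack([np.interp(grid, t, a) for a in axes])
        t = grid
    else:
        rate = 1.0 / float(dt.mean())

    ap = {"ax": "ax", "ay": "ay", "az": "az"}[schema.anteroposterior]
    return AccelRecording(t=t, ax=axes[0], ay=axes[1], az=axes[2], sample_rate=rate, axis_map=ap)


_WINDOW_COLUMNS = [
    "window",
    "start_s",
    "duration_s",
    "active_s",
    "step_frequency_hz",
    "steps",
    "step_length_m",
    "distance_m",
    "velocity_mps",
]


def write_window_table(estimates, path) -> None:
    """Write per-window estimates as CSV, floats at 6 decimals.

    Round-trips losslessly through :func:`read_window_table`.
    """
    rows = list(estimates)
    if not rows:
        raise ValueError("no window estimates to write")
    df = pd.DataFrame(
        [
            {
                "window": e.index,
                "start_s": e.start,
                "duration_s": e.duration,
                "active_s": e.active_s,
                "step_frequency_hz": e.step_frequency,
                "steps": e.steps,
                "step_length_m": e.step_length,
                "distance_m": e.distance,
                "velocity_mps": e.velocity,
            }
            for e in rows
        ],
        columns=_WINDOW_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.6f")


def read_window_table(path) -> pd.DataFrame:
    """Read a window table written by :func:`write_window_table`."""
    df = pd.read_csv(path)
    missing = [c for c in _WINDOW_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"window table {path} missing columns {missing}")
    return df
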