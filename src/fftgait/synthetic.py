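"""Synthetic accelerometer bouts with known ground truth.

Walking is emulated as a quasi-periodic anteroposterior acceleration: a
fundamental sinusoid at the step frequency plus an optional second harmonic
(which may dominate, emulating the harmonic spectra of lateral-component
gaits), additive Gaussian noise, and slow sinusoidal baseline drift.  Rest
segments carry drift and noise only.  Ground truth (step times, per-step
lengths from the published step-length equation, travel distance, per-second
activity mask) is constructed analytically from the generating parameters, so
every downstream stage of the pipeline is testable without real recordings.

The generator uses NumPy's PCG64 generator throughout, so traces are
bit-reproducible for a given (spec, seed) on any platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fftgait.core_io import AccelRecording, SubjectProfile
from fftgait.step_length import EQ1_COEFFICIENTS, StepLengthCoefficients, predict_step_length

CADENCE_BAND = (0.3, 4.6)  # physiologic step-frequency band, Hz


class SimSpecError(ValueError):
    """Simulation spec violates its contract (e.g. out-of-band cadence)."""


@dataclass(frozen=True)
class SimSegment:
    """One homogeneous stretch of a simulated bout.

    kind : ``"walk"`` or ``"rest"``.
    duration : seconds (> 0).
    step_frequency : steps/s for walk segments (ignored for rest).
    amp_fundamental : amplitude of the step-frequency sinusoid, G.
    amp_harmonic : amplitude of the second harmonic (2f), G.
    """

    kind: str
    duration: float
    step_frequency: float = 0.0
    amp_fundamental: float = 0.0
    amp_harmonic: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("walk", "rest"):
            raise SimSpecError(f"segment kind must be walk/rest, got {self.kind!r}")
        if self.duration <= 0:
            raise SimSpecError("segment duration must be positive")
        if self.amp_fundamental < 0 or self.amp_harmonic < 0:
            raise SimSpecError("amplitudes must be nonnegative")
        if self.kind == "walk" and not (CADENCE_BAND[0] <= self.step_frequency <= CADENCE_BAND[1]):
            raise SimSpecError(
                f"walk step frequency {self.step_frequency} Hz outside "
                f"[{CADENCE_BAND[0]}, {CADENCE_BAND[1]}]"
            )


@dataclass(frozen=True)
class GaitSimSpec:
    """Full description of a simulated bout."""

    segments: tuple
    sample_rate: float = 100.0
    noise_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_period: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise SimSpecError("spec needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.sample_rate < 10:
            raise SimSpecError("sample_rate must be at least 10 Hz")
        if self.noise_sd < 0 or self.drift_amplitude < 0 or self.drift_period <= 0:
            raise SimSpecError("noise_sd/drift_amplitude must be >= 0 and drift_period > 0")

    @property
    def duration(self) -> float:
        return float(sum(s.duration for s in self.segments))


@dataclass(frozen=True)
class GroundTruthBout:
    """Analytic ground truth accompanying a simulated recording."""

    step_times: np.ndarray          # s, one entry per true step
    step_lengths: np.ndarray        # m, one entry per true step
    segment_frequencies: tuple      # true step frequency per segment (0 for rest)
    active_mask: np.ndarray         # bool per whole second of the bout
    total_duration: float           # s

    @property
    def total_steps(self) -> int:
        return int(len(self.step_times))

    @property
    def total_distance(self) -> float:
        return float(np.sum(self.step_lengths))

    @property
    def avg_step_frequency(self) -> float:
        """Steps per second over the total duration (rest time included)."""
        return self.total_steps / self.total_duration if self.total_duration else 0.0

    @property
    def avg_step_length(self) -> float:
        return self.total_distance / self.total_steps if self.total_steps else 0.0

    @property
    def avg_step_velocity(self) -> float:
        """m/s over the total duration (rest time included)."""
        return self.total_distance / self.total_duration if self.total_duration else 0.0


def _segment_signal(seg: SimSegment, t_local: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if seg.kind == "rest":
        return np.zeros_like(t_local)
    phase1 = rng.uniform(0, 2 * np.pi)
    phase2 = rng.uniform(0, 2 * np.pi)
    f = seg.step_frequency
    return seg.amp_fundamental * np.sin(2 * np.pi * f * t_local + phase1) + seg.amp_harmonic * np.sin(
        4 * np.pi * f * t_local + phase2
    )


def simulate_bout(
    spec: GaitSimSpec,
    subject: SubjectProfile,
    coefficients: StepLengthCoefficients = EQ1_COEFFICIENTS,
    step_lengths=None,
):
    """Generate a recording and its ground truth.

    Ground-truth step lengths default to the published step-length equation
    evaluated at each segment's true cadence for ``subject``; a per-step array
    may be supplied instead via ``step_lengths``.

    Returns
    -------
    (AccelRecording, GroundTruthBout)
    """
    rng = np.random.default_rng(spec.seed)
    fs = spec.sample_rate
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs

    z = np.zeros(n)
    step_times = []
    step_sl = []
    seg_freqs = []
    start = 0.0
    for seg in spec.segments:
        i0 = int(round(start * fs))
        i1 = int(round((start + seg.duration) * fs))
        t_local = t[i0:i1] - start
        z[i0:i1] = _segment_signal(seg, t_local, rng)
        if seg.kind == "walk":
            seg_freqs.append(seg.step_frequency)
            # one step per 1/f of walk time; the k-th step completes at (k+1)/f
            k = np.arange(int(np.floor(seg.duration * seg.step_frequency + 1e-9)))
            times = start + (k + 1) / seg.step_frequency
            step_times.append(times)
            sl = predict_step_length(
                seg.step_frequency, subject.height, subject.dmd, coefficients
            )
            step_sl.append(np.full(len(times), sl))
        else:
            seg_freqs.append(0.0)
        start += seg.duration

    drift = spec.drift_amplitude * np.sin(2 * np.pi * t / spec.drift_period)
    noise = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else 0.0
    z = z + drift + noise

    step_times = np.concatenate(step_times) if step_times else np.empty(0)
    step_sl = np.concatenate(step_sl) if step_sl else np.empty(0)
    if step_lengths is not None:
        step_lengths = np.asarray(step_lengths, dtype=float)
        if len(step_lengths) != len(step_times):
            raise SimSpecError("step_lengths must have one entry per ground-truth step")
        step_sl = step_lengths

    # a whole second is active iff the majority of it lies in a walk segment
    n_sec = int(np.ceil(spec.duration - 1e-9))
    mask = np.zeros(n_sec, dtype=bool)
    start = 0.0
    for seg in spec.segments:
        if seg.kind == "walk":
            lo, hi = start, start + seg.duration
            for s in range(int(np.floor(lo)), min(n_sec, int(np.ceil(hi)))):
                overlap = min(hi, s + 1) - max(lo, s)
                if overlap > 0.5:
                    mask[s] = True
        start += seg.duration

    rec = AccelRecording(t=t, ax=np.zeros(n), ay=np.zeros(n), az=z, sample_rate=fs, axis_map="az")
    truth = GroundTruthBout(
        step_times=step_times,
        step_lengths=step_sl,
        segment_frequencies=tuple(seg_freqs),
        active_mask=mask,
        total_duration=spec.duration,
    )
    return rec, truth


def scl1_spec(
    step_frequency: float = 1.0,
    duration: float = 30.0,
    amp_fundamental: float = 0.25,
    amp_harmonic: float = 0.05,
    noise_sd: float = 0.01,
    sample_rate: float = 100.0,
    seed: int = 0,
) -> GaitSimSpec:
    """Default calibration-walk spec: a single very slow walk segment."""
    return GaitSimSpec(
        segments=(
            SimSegment("walk", duration, step_frequency, amp_fundamental, amp_harmonic),
        ),
        sample_rate=sample_rate,
        noise_sd=noise_sd,
        seed=seed,
    )


def simulate_scl1(spec: GaitSimSpec) -> AccelRecording:
    """Generate a slow-walk calibration (SC-L1) trace.

    The spec must contain a single walk segment at a slow cadence (<= 1.5 Hz);
    per-step peak amplitudes vary only by the configured noise, which makes
    the trace suitable for deriving the activity threshold.
    """
    if len(spec.segments) != 1 or spec.segments[0].kind != "walk":
        raise SimSpecError("SC-L1 spec must contain exactly one walk segment")
    if spec.segments[0].step_frequency > 1.5:
        raise SimSpecError("SC-L1 must be a very slow walk (step frequency <= 1.5 Hz)")
    dummy = SubjectProfile("scl1", 1.3, 0)
    rec, _ = simulate_bout(spec, dummy)
    return rec


def random_bout_spec(
    rng: np.random.Generator,
    cadence_range=(1.2, 3.0),
    duration_range=(20.0, 180.0),
    walk_seconds=(10, 40),
    rest_seconds=(3, 10),
    amp_range=(0.3, 0.6),
    harmonic_ratio: float = 0.3,
    noise_fraction: float = 0.2,
    sample_rate: float = 100.0,
) -> GaitSimSpec:
    """Draw a mixed walk/rest bout spec emulating intermittent community walking.

    Walk and rest segments alternate (walk first) with integer-second
    durations until the total reaches a duration drawn from
    ``duration_range``.  Each walk segment gets its own cadence from
    ``cadence_range`` and fundamental amplitude from ``amp_range``, a
    fundamental-dominant second harmonic (``harmonic_ratio`` of the
    fundamental), and the bout-level noise SD is ``noise_fraction`` of the
    mean fundamental amplitude.
    """
    total = float(rng.uniform(*duration_range))
    segments = []
    amps = []
    elapsed = 0.0
    walking = True
    while elapsed < total:
        if walking:
            dur = int(rng.integers(walk_seconds[0], walk_seconds[1] + 1))
            dur = min(dur, max(5, int(round(total - elapsed))))
            f = float(rng.uniform(*cadence_range))
            a1 = float(rng.uniform(*amp_range))
            segments.append(SimSegment("walk", dur, f, a1, harmonic_ratio * a1))
            amps.append(a1)
        else:
            dur = int(rng.integers(rest_seconds[0], rest_seconds[1] + 1))
            if elapsed + dur >= total:
                break
            segments.append(SimSegment("rest", dur))
        elapsed += dur
        walking = not walking
    noise_sd = noise_fraction * float(np.mean(amps))
    return GaitSimSpec(
        segments=tuple(segments),
        sample_rate=sample_rate,
        noise_sd=noise_sd,
        drift_amplitude=0.05,
        drift_period=60.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
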