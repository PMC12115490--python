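# Methods

## Signal model and pipeline assumptions

The pipeline assumes a single waist-worn (lumbosacral) accelerometer whose
anteroposterior axis carries a quasi-periodic signal during gait, with the
dominant spectral component at the *step* frequency (not the stride
frequency). All processing operates in G; readers convert m/s² inputs at the
boundary. Timestamps are seconds from bout start; irregular input sampling
is linearly resampled to the median observed rate before any filtering —
the simplest scheme that preserves total duration to within one sample
period.

### Preprocessing

The band 0.3–4.6 Hz brackets physiologic cadence: below 0.3 Hz lie postural
adjustments and drift, above 4.6 Hz only the fastest running cadences.
The filter realization is a 4th-order Butterworth bandpass applied
forward–backward (`scipy.signal.sosfiltfilt`). Zero-phase filtering was
chosen so that step peaks are not displaced relative to the 1 s
classification grid; the effective attenuation one octave outside the band
exceeds 20 dB. The window mean is additionally removed before each FFT —
redundant with the passband's DC rejection but a cheap guarantee.

Windows are fixed at 5 s, non-overlapping, aligned to t = 0. A trailing
partial window is kept when ≥ 1 s remains (discarding up to 5 s of a short
clinical test would bias totals); its true duration propagates through all
per-window formulas.

### Calibration (activity threshold)

The threshold is μ + σ of per-step acceleration peaks in the slowest-walk
trial, with σ in population form (divisor m), matching the defining formula
rather than the sample convention. Peak detection uses local maxima
separated by at least the minimum physiologic step period (1/4.6 s) with
prominence ≥ 10 % of the trace maximum; the separation constraint yields one
peak per step without gait-event segmentation. Classification compares the
*absolute* preprocessed signal against the threshold (after detrending,
step impacts can present as negative excursions depending on device
orientation) and uses ≥ at the boundary. The threshold is applied to the
preprocessed signal for consistency with the spectral stage. When no
calibration trial exists a threshold may be supplied directly; the fallback
(0.05 G) is logged loudly as uncalibrated.

### Spectral cadence estimation

Each 5 s window gives 0.2 Hz native bins — too coarse for cadence — so
windows are zero-padded (default factor 4, and always enough to reach
≤ 0.05 Hz bins). No taper is applied by default (a Hann option exists): on
quasi-sinusoidal gait signals leakage is modest and an untapered spectrum
keeps two-tone magnitude comparisons interpretable for the harmonic rule.

A *peak* is a local maximum of the magnitude spectrum; candidates below 5 %
of the spectrum maximum are ignored (without such a floor, numerical noise
in silent windows would yield spurious cadence — harmless for steps, since
inactive windows contribute none, but confusing in exports). Selection:
take the highest-magnitude in-band candidate P (ties break toward lower
frequency, favoring the fundamental); if a lower-frequency candidate Q has
freq(Q) < 0.6·freq(P) and mag(Q) ≥ 0.6·mag(P), return Q. The two
60 % constants mirror the harmonic phenomenon the rule targets: a spurious
dominant peak near 2× the true cadence. The rule is applied once — no
recursive sub-harmonic descent — and the frequency condition is read as a
*ratio of frequencies*, consistent with the ≈2× harmonic geometry it must
disambiguate. Output is always 0 or within the band.

### Step-length model

Covariate transforms are u = √sf and v = 1/√h; the untransformed reading of
the published coefficients would predict ≈ 1.3 m steps for a 1.3 m child,
which is physiologically impossible, while the transformed reading gives
≈ 0.55 m and a step-length/height ratio of 0.35–0.40 at self-selected
cadence — the expected range. Predictions at sf = 0 are 0 by convention
(inactive window); negative extrapolations (possible at near-zero cadence)
are clamped to 0 with a logged warning.

Refitting uses pooled fixed-effects OLS on the eight-term design
{u, v, uv, 1, dmd, dmd·u, dmd·v, dmd·uv} via statsmodels. The original
calibration used mixed-effects regression with within-subject random
effects; participant-level data are not available to reproduce that
structure, and the fit report carries an explicit note to that effect.
Reported RMSE is √(SSR/(n−8)) (degrees-of-freedom corrected) and R² is
adjusted.

### Aggregation conventions

Per-window velocity divides by *active* time; bout-average step frequency
and velocity divide by *total* time (rest included). Both conventions are
deliberate and never mixed: the former measures gait performance, the
latter mobility density over a community bout. An `averaging="active"`
switch exposes the alternative bout convention. Fractional steps are kept
per window; the bout total is also reported rounded for comparison with
observed counts. The 95th-percentile step velocity is computed over
per-window velocities of active windows (linear-interpolation percentile) —
a window-weighted approximation of stride-velocity-95, since this method
has no per-step timing.

### Agreement statistics

Bland–Altman differences are estimate − reference (positive = overestimate)
normalized by the pair mean — the standard percentage-BA form. The
Passing–Bablok slope is the shifted median of pairwise slopes (equal-x/y
pairs excluded, slopes of −1 dropped, offset K = #slopes < −1), with
rank-based normal-approximation CIs; exact small-sample tables are out of
scope. Lin's concordance uses population (1/n) moments. All medians and
IQRs use linear-interpolation (type-7) quantiles so values are reproducible
bit-for-bit. Every statistic is cross-checked in the test suite against
independent brute-force implementations on random small instances.

## Synthetic-data generator

Walk segments produce A₁·sin(2πft+φ) + A₂·sin(4πft+φ₂); rest segments are
zero; noise is white Gaussian and drift a slow sinusoid (period ≥ 30 s by
default, exercising the detrend/bandpass stage). Ground truth places one
step per 1/f of walk time, takes step lengths from the step-length equation
at the true cadence, and marks a second active when the majority of it
overlaps a walk segment. Phases are drawn per segment from a seeded PCG64
generator, making traces bit-reproducible across platforms.

The validation batch (`fftgait.validation.run_simulation_batch`) emulates
intermittent community walking: alternating walk (10–40 s) and rest
(3–10 s) segments with integer durations, bout lengths 20–180 s, per-segment
cadences uniform on 1.2–3.0 steps/s, fundamental amplitudes 0.3–0.6 G with a
second harmonic at 30 % of the fundamental, noise at 20 % of the mean
fundamental amplitude, drift of 0.05 G at 60 s period, subject heights
1.0–1.7 m, and a per-bout slow-walk calibration trace (1.0 Hz, 0.25 G).
Fifty bouts run in seconds on one CPU.

What the generator does *not* emulate: triaxial coupling, stride-to-stride
cadence variability, asymmetry, turning, flight-phase running dynamics, or
soft-tissue artifacts. Passing the simulation twins therefore demonstrates
correctness of the *algorithmic chain* (filtering, thresholding, spectral
peak logic, arithmetic aggregation) under controlled signal phenomena — not
clinical accuracy on real recordings, which requires the original study's
data or new collections.

## Numerical choices and degenerate inputs

- FFT bin spacing ≤ 0.05 Hz via zero-padding; spectral tie-breaks go to the
  lower frequency.
- All-zero or out-of-band windows yield cadence 0, hence zero steps,
  distance and velocity; all-inactive bouts summarize to zeros rather than
  NaNs.
- Recordings must be strictly monotonic in time and ≥ 10 Hz; sub-1 s
  recordings produce zero windows.
- Window-table and summary CSVs round floats to 6 decimals and round-trip
  losslessly at that precision.

## Known limitations

- Cadence resolution is bounded by the 5 s window and the ≤ 0.05 Hz bins;
  very short activity bursts inside a window are averaged over.
- Step length inherits the calibration cohort's range (children 3–16,
  heights ≈ 1.0–1.75 m, walking speeds); extrapolation beyond it is clamped
  but not validated.
- The refit is fixed-effects only (see above).
- Per-step event timing, left/right asymmetry and ankle-worn
  stride-velocity-95 semantics are out of scope.
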