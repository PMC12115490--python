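# fftgait

FFT-based estimation of step frequency, step count, step length, step
velocity and travel distance from a single waist-worn accelerometer, aimed
at mobility monitoring in children with Duchenne muscular dystrophy (DMD)
and typically developing (TD) peers. A companion agreement-statistics
toolkit (percentage Bland–Altman, Passing–Bablok, Lin's concordance, median
absolute error metrics) supports method-comparison studies against reference
measurements.

## Method

The anteroposterior (z-axis) acceleration is bandpass-filtered to the
physiologic cadence band (0.3–4.6 Hz) and cut into fixed, non-overlapping
5 s time windows. Per window:

1. **Active time.** A threshold is derived from a very-slow-walk calibration
   trial (SC-L1) as `threshold = μ + σ` of the per-step acceleration peaks.
   Each 1 s slice whose maximum |acceleration| reaches the threshold is an
   *active* second.
2. **Step frequency.** The highest peak of the FFT magnitude spectrum inside
   0.3–4.6 Hz gives the cadence `sf` (0 if no in-band peak). When a
   lower-frequency peak sits below 60 % of the dominant peak's frequency but
   carries at least 60 % of its magnitude, the lower peak wins — this
   demotes second-harmonic peaks produced by running or Trendelenburg-style
   gaits.
3. **Steps, length, distance, velocity.**
   `steps = sf × active_s`; step length comes from the regression

   ```
   SL(sf, h) = 3.33758·√sf + 2.442582/√h − 3.072612·√sf/√h − 2.505019
             + DMD·(1.87948 − 1.689478·√sf − 1.865428/√h + 1.664073·√sf/√h)
   ```

   with `h` the standing height in meters and `DMD` an indicator;
   `distance = steps × SL`; window velocity divides by *active* time.

Bout totals sum the windows; average step frequency and velocity divide by
the *total* duration (rest included), reflecting community mobility density.
The 95th-percentile of per-window velocities approximates the
stride-velocity-95 endpoint at window resolution.

Because real recordings of this kind are rarely shareable, the package ships
a synthetic-gait generator (`fftgait.synthetic`) producing bouts with known
ground truth — harmonic walking segments, rest periods, noise and baseline
drift — on which the whole pipeline is validated.

## Worked example

Simulate a 100 s bout (60 s at 2.0 steps/s, 10 s rest, 30 s at 1.5 steps/s)
for a 1.30 m TD child, calibrate from a slow-walk trial, and estimate:

```bash
fftgait simulate --config sim.yaml --out-dir bout
fftgait simulate --config scl1.yaml --out-dir cal
fftgait calibrate --scl1 cal/recording.csv --out threshold.json
fftgait estimate --bout bout/recording.csv --scl1 cal/recording.csv \
    --height 1.30 --out-dir out
```

prints

```
threshold 0.2671 G from 29 peaks (mu 0.2549, sigma 0.0123)
20 windows | 165 steps | 84.65 m | avg sf 1.650 Hz | avg velocity 0.846 m/s
```

against simulator ground truth of 165 steps, 84.645 m, 1.650 Hz and
0.846 m/s: the step count is exact and distance agrees to <0.01 %. The
`out/` directory holds the per-window table, a Fig-style timeline with
cumulative distance, the bout summary, the calibration profile, and a run
manifest echoing every configured constant.

The same pipeline is available as a library:

```python
from fftgait import SubjectProfile, estimate_bout
estimates, summary = estimate_bout(recording, SubjectProfile("p1", 1.30, 0),
                                   threshold=0.27)
```

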