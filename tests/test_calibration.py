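import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fftgait.calibration import (
    CalibrationError,
    CalibrationProfile,
    classify_active_seconds,
    compute_threshold,
    detect_calibration_peaks,
    fallback_profile,
)
from fftgait.core_io import AccelRecording
from fftgait.preprocessing import TimeWindow, preprocess_signal
from fftgait.synthetic import scl1_spec, simulate_scl1


def _rec(z, fs=100.0):
    n = len(z)
    return AccelRecording(
        t=np.arange(n) / fs, ax=np.zeros(n), ay=np.zeros(n), az=np.asarray(z, float), sample_rate=fs
    )


def _brute_force_peaks(x, min_sep, min_height):
    """Oracle: leftmost-of-plateau local maxima, greedily separated."""
    cand = [
        i
        for i in range(1, len(x) - 1)
        if x[i] > x[i - 1] and x[i] >= x[i + 1] and x[i] >= min_height
    ]
    cand.sort(key=lambda i: -x[i])
    kept = []
    for i in cand:
        if all(abs(i - j) >= min_sep for j in kept):
            kept.append(i)
    return sorted(kept)


def test_peak_count_on_noiseless_slow_walk():
    rec = simulate_scl1(scl1_spec(step_frequency=1.0, duration=20.0, amp_fundamental=0.3,
                                  amp_harmonic=0.0, noise_sd=0.0, seed=4))
    filtered = preprocess_signal(rec)
    peaks = detect_calibration_peaks(filtered)
    oracle = _brute_force_peaks(filtered.az, int(100 / 4.6), 0.5 * filtered.az.max())
    assert len(peaks) == len(oracle) == 20


def test_small_ripple_rejected_by_prominence():
    t = np.arange(2000) / 100.0
    z = np.sin(2 * np.pi * 1.0 * t) + 0.05 * np.sin(2 * np.pi * 4.0 * t)
    peaks = detect_calibration_peaks(_rec(z))
    assert len(peaks) == 20


def test_flat_trace_is_calibration_error():
    with pytest.raises(CalibrationError):
        detect_calibration_peaks(_rec(np.zeros(1000)))


def test_threshold_hand_value():
    prof = compute_threshold([0.8, 1.0, 1.2])
    assert prof.mu == pytest.approx(1.0)
    assert prof.threshold == pytest.approx(1.1633, abs=1e-4)
    assert prof.threshold == prof.mu + prof.sigma


def test_threshold_zero_variance():
    prof = compute_threshold([1.0, 1.0, 1.0])
    assert prof.sigma == 0.0
    assert prof.threshold == 1.0


def test_threshold_needs_three_peaks():
    with pytest.raises(CalibrationError):
        compute_threshold([1.0, 1.1])


@given(
    peaks=st.lists(st.floats(0.05, 5.0), min_size=3, max_size=40),
    scale=st.floats(0.1, 10.0),
)
def test_threshold_homogeneity_and_order_invariance(peaks, scale):
    p = np.asarray(peaks)
    base = compute_threshold(p).threshold
    assert compute_threshold(scale * p).threshold == pytest.approx(scale * base, rel=1e-9)
    assert compute_threshold(p[::-1]).threshold == pytest.approx(base, rel=1e-12)


def _tw(x, fs=100.0):
    return TimeWindow(0, 0.0, len(x) / fs, np.asarray(x, float), fs)


def test_fully_active_window():
    t = np.arange(500) / 100.0
    active, mask = classify_active_seconds(_tw(0.4 * np.sin(2 * np.pi * 2 * t)), 0.3)
    assert active == 5.0
    assert mask.tolist() == [True] * 5


def test_partially_active_window():
    t = np.arange(200) / 100.0
    walk = 0.4 * np.sin(2 * np.pi * 2 * t)
    x = np.concatenate([walk, np.full(300, 0.01)])
    active, mask = classify_active_seconds(_tw(x), 0.3)
    assert active == 2.0
    assert mask.tolist() == [True, True, False, False, False]


def test_all_zero_window_inactive():
    active, mask = classify_active_seconds(_tw(np.zeros(500)), 0.3)
    assert active == 0.0
    assert not mask.any()


def test_negative_excursions_count_via_absolute_value():
    x = np.zeros(500)
    x[120] = -0.5  # impact presenting as a negative spike
    active, mask = classify_active_seconds(_tw(x), 0.3)
    assert active == 1.0 and mask[1]


def test_partial_window_short_last_slice():
    x = np.concatenate([0.4 * np.ones(100), 0.4 * np.ones(50)])  # 1.5 s window
    active, mask = classify_active_seconds(_tw(x), 0.3)
    assert len(mask) == 2
    assert active == pytest.approx(1.5)


@given(st.floats(0.01, 2.0), st.floats(0.01, 2.0))
def test_raising_threshold_never_increases_active_count(th1, th2):
    t = np.arange(500) / 100.0
    tw = _tw(0.5 * np.sin(2 * np.pi * 1.3 * t) + 0.1 * np.sin(2 * np.pi * 3.1 * t))
    lo, hi = sorted((th1, th2))
    a_lo, _ = classify_active_seconds(tw, lo)
    a_hi, _ = classify_active_seconds(tw, hi)
    assert a_hi <= a_lo


def test_profile_json_round_trip(tmp_path):
    prof = compute_threshold([0.8, 1.0, 1.2])
    path = tmp_path / "cal.json"
    prof.to_json(path)
    back = CalibrationProfile.from_json(path)
    assert back.threshold == pytest.approx(prof.threshold)
    np.testing.assert_allclose(back.peaks, prof.peaks)


def test_fallback_profile_logs_and_sets_threshold(caplog):
    with caplog.at_level("WARNING"):
        prof = fallback_profile(0.07)
    assert prof.threshold == 0.07
    assert any("uncalibrated" in r.message for r in caplog.records)
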