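import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fftgait.agreement import (
    AgreementReport,
    PairedSeries,
    acceptance_flags,
    agreement_report,
    bland_altman_percent,
    lins_ccc,
    median_errors,
    passing_bablok,
)

# ---------------------------------------------------------------- brute-force oracles


def bf_passing_bablok_slope(x, y):
    """Naive double-loop enumeration of pairwise slopes with shifted median."""
    slopes = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[j] - x[i], y[j] - y[i]
            if dx == 0 and dy == 0:
                continue
            s = math.inf * (1 if dy > 0 else -1) if dx == 0 else dy / dx
            if s != -1.0:
                slopes.append(s)
    slopes.sort()
    big_n = len(slopes)
    k = sum(1 for s in slopes if s < -1.0)
    if big_n % 2:
        return slopes[(big_n + 1) // 2 + k - 1]
    return 0.5 * (slopes[big_n // 2 + k - 1] + slopes[big_n // 2 + k])


def bf_ccc(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sx2 = sum((v - mx) ** 2 for v in x) / n
    sy2 = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return 2 * sxy / (sx2 + sy2 + (mx - my) ** 2)


def bf_percentile(values, q):
    """Linear-interpolation (type 7) percentile."""
    v = sorted(values)
    pos = (len(v) - 1) * q / 100.0
    lo = int(math.floor(pos))
    frac = pos - lo
    return v[lo] if lo + 1 >= len(v) else v[lo] * (1 - frac) + v[lo + 1] * frac


# ---------------------------------------------------------------- Bland-Altman


def test_ba_perfect_agreement():
    p = PairedSeries(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 4]))
    r = bland_altman_percent(p)
    assert r.mean_pct_diff == 0.0
    assert r.loa == (0.0, 0.0)


def test_ba_replicated_pair_hand_value():
    p = PairedSeries(np.full(5, 100.0), np.full(5, 102.0))
    r = bland_altman_percent(p)
    assert r.mean_pct_diff == pytest.approx(1.9802, abs=1e-4)
    assert r.sd_pct_diff == 0.0


def test_ba_antisymmetry():
    ref = np.array([10.0, 12, 9, 14])
    est = np.array([11.0, 11.5, 9.8, 13.2])
    fwd = bland_altman_percent(PairedSeries(ref, est))
    rev = bland_altman_percent(PairedSeries(est, ref))
    assert fwd.mean_pct_diff == pytest.approx(-rev.mean_pct_diff)


def test_ba_zero_pair_mean_rejected():
    p = PairedSeries(np.array([1.0, -1.0, 2.0]), np.array([1.0, 1.0, 2.0]))
    with pytest.raises(ValueError, match="index 1"):
        bland_altman_percent(p)


def test_ba_loa_bracket_mean():
    rng = np.random.default_rng(0)
    ref = rng.uniform(50, 150, 30)
    est = ref * rng.normal(1.02, 0.05, 30)
    r = bland_altman_percent(PairedSeries(ref, est))
    assert r.loa[0] <= r.mean_pct_diff <= r.loa[1]


# ---------------------------------------------------------------- Passing-Bablok


def test_pb_identity():
    x = np.arange(1.0, 11.0)
    r = passing_bablok(PairedSeries(x, x))
    assert r.slope == pytest.approx(1.0)
    assert r.intercept == pytest.approx(0.0)


def test_pb_hand_enumerated_example():
    r = passing_bablok(PairedSeries(np.array([1.0, 2, 3, 4]), np.array([1.0, 2.1, 2.9, 4.2])))
    assert r.slope == pytest.approx(1.05833, abs=1e-4)
    assert r.intercept == pytest.approx(-0.04583, abs=1e-4)


def test_pb_exact_scaling():
    x = np.arange(1.0, 9.0)
    r = passing_bablok(PairedSeries(x, 2 * x))
    assert r.slope == pytest.approx(2.0)
    assert r.intercept == pytest.approx(0.0)


def test_pb_degenerate_x_rejected():
    with pytest.raises(ValueError):
        passing_bablok(PairedSeries(np.full(5, 3.0), np.arange(5.0)))


def test_pb_scaling_equivariance():
    rng = np.random.default_rng(3)
    x = rng.uniform(1, 10, 12)
    y = 1.1 * x + rng.normal(0, 0.1, 12)
    base = passing_bablok(PairedSeries(x, y))
    scaled = passing_bablok(PairedSeries(3 * x, 3 * y))
    assert scaled.slope == pytest.approx(base.slope)
    assert scaled.intercept == pytest.approx(3 * base.intercept)


def test_pb_axis_exchange_inverts_slope():
    rng = np.random.default_rng(4)
    x = rng.uniform(1, 10, 15)
    y = 2.0 * x + rng.normal(0, 0.05, 15)
    fwd = passing_bablok(PairedSeries(x, y))
    rev = passing_bablok(PairedSeries(y, x))
    assert rev.slope == pytest.approx(1.0 / fwd.slope, rel=0.02)


# ---------------------------------------------------------------- Lin's CCC


def test_ccc_identity_and_hand_value():
    x = np.array([1.0, 2, 3])
    assert lins_ccc(PairedSeries(x, x)) == 1.0
    assert lins_ccc(PairedSeries(x, x + 1)) == pytest.approx(0.571429, abs=1e-6)


def test_ccc_negative_for_reversed_series():
    x = np.array([1.0, 2, 3, 4])
    assert lins_ccc(PairedSeries(x, -x + 5)) < 0


def test_ccc_bounded_by_pearson():
    rng = np.random.default_rng(6)
    for _ in range(50):
        x = rng.uniform(0, 10, 10)
        y = 0.8 * x + rng.normal(0, 1, 10)
        ccc = lins_ccc(PairedSeries(x, y))
        r = np.corrcoef(x, y)[0, 1]
        assert abs(ccc) <= abs(r) + 1e-12


# ---------------------------------------------------------------- median errors


def test_mdae_mdape_hand_values():
    # errors 1,1,4; APEs 10,5,10 (%)
    p = PairedSeries(np.array([10.0, 20, 40]), np.array([11.0, 19, 44]))
    r = median_errors(p)
    assert r.mdae == 1.0
    assert r.mdape == 10.0


def test_mdae_zero_on_perfect_estimates():
    x = np.array([5.0, 6, 7])
    r = median_errors(PairedSeries(x, x))
    assert r.mdae == r.mdape == 0.0


def test_constant_errors_collapse_iqr():
    x = np.array([10.0, 20, 30, 40])
    r = median_errors(PairedSeries(x, x + 2.0))
    assert r.mdae == 2.0
    assert r.mdae_iqr == (2.0, 2.0)


def test_zero_references_excluded_from_mdape(caplog):
    p = PairedSeries(np.array([0.0, 10, 20]), np.array([1.0, 11, 22]))
    with caplog.at_level("WARNING"):
        r = median_errors(p)
    assert r.n_excluded == 1
    assert r.mdape == pytest.approx(10.0)


# ---------------------------------------------------------------- randomized cross-checks


def test_agreement_stats_match_brute_force_on_random_instances():
    """PB slope, CCC and MdAPE equal independent brute-force oracles."""
    rng = np.random.default_rng(99)
    for _ in range(300):
        n = int(rng.integers(4, 13))
        x = rng.uniform(1, 20, n)
        y = rng.uniform(0.5, 1.5) * x + rng.normal(0, 1, n)
        p = PairedSeries(x, y)
        assert passing_bablok(p).slope == pytest.approx(bf_passing_bablok_slope(list(x), list(y)), rel=1e-12)
        assert lins_ccc(p) == pytest.approx(bf_ccc(list(x), list(y)), rel=1e-10)
        me = median_errors(p)
        ape = list(100 * np.abs(y - x) / np.abs(x))
        assert me.mdape == pytest.approx(bf_percentile(ape, 50), rel=1e-12)
        assert me.mdape_iqr[0] == pytest.approx(bf_percentile(ape, 25), rel=1e-12)
        assert me.mdape_iqr[1] == pytest.approx(bf_percentile(ape, 75), rel=1e-12)


@given(st.integers(0, 2**32 - 1))
def test_pb_matches_brute_force_property(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    x = rng.uniform(1, 20, n)
    y = rng.uniform(0.5, 2.0) * x + rng.normal(0, 0.5, n)
    got = passing_bablok(PairedSeries(x, y)).slope
    assert got == pytest.approx(bf_passing_bablok_slope(list(x), list(y)), rel=1e-12)


# ---------------------------------------------------------------- acceptance flags


def _report_with(slope, slope_ci, intercept, ccc):
    from fftgait.agreement import BlandAltmanResult, MedianErrorResult, PassingBablokResult

    return AgreementReport(
        label="t",
        n=10,
        bland_altman=BlandAltmanResult(0.0, (0.0, 0.0), (0.0, 0.0), 0.0, 10),
        passing_bablok=PassingBablokResult(slope, slope_ci, intercept, (0.0, 0.0), 10),
        ccc=ccc,
        median_error=MedianErrorResult(0.0, (0.0, 0.0), 0.0, (0.0, 0.0), 0),
    )


def test_flags_all_strong():
    f = acceptance_flags(_report_with(1.0, (0.99, 1.01), 0.0, 0.999), max_reference=100.0)
    assert all(f.values())


def test_flags_acceptable_not_strong():
    f = acceptance_flags(_report_with(1.05, (1.02, 1.08), 1.0, 0.93), max_reference=100.0)
    assert f["slope_acceptable"] and not f["slope_strong"]
    assert f["ccc_acceptable"] and not f["ccc_strong"]
    assert f["intercept_acceptable"]


def test_flags_fail_out_of_band_slope():
    f = acceptance_flags(_report_with(1.2, (1.15, 1.25), 5.0, 0.85), max_reference=100.0)
    assert not any(f.values())


def test_full_report_assembles(rng):
    x = rng.uniform(10, 100, 20)
    y = x * rng.normal(1.0, 0.03, 20)
    rep = agreement_report(PairedSeries(x, y, label="steps"))
    assert rep.n == 20
    assert rep.label == "steps"
    assert -1 <= rep.ccc <= 1
    assert rep.bland_altman.loa[0] <= rep.bland_altman.mean_pct_diff <= rep.bland_altman.loa[1]
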