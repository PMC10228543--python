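import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tailspin import relaxation
from tailspin.relaxation import (
    AnalysisError,
    EmptyRegionError,
    RelaxationSeries,
    compute_hnnoe,
    compute_r2_over_r1,
    fit_exponential,
    jackknife_rate_error,
    noe_profile,
    r2r1_profile,
    rate_profile,
    region_average,
)
from tailspin.simulate import R1_DELAYS, R2_DELAYS


def _series(delays, intensities, noise=1.0, residue=3, peak=1):
    return RelaxationSeries(residue, peak, np.asarray(delays, float), np.asarray(intensities, float), noise)


def _loglinear_oracle(t, y):
    """Closed-form fit on noiseless data: linear regression of log I on t."""
    slope, intercept = np.polyfit(t, np.log(y), 1)
    return math.exp(intercept), -slope


@pytest.mark.parametrize(
    "delays, i0, rate",
    [(R1_DELAYS, 100.0, 1.0), (R2_DELAYS, 50.0, 22.0), (R1_DELAYS, 7.5, 0.3)],
)
def test_noiseless_fit_matches_loglinear_oracle(delays, i0, rate):
    t = np.asarray(delays)
    y = i0 * np.exp(-rate * t)
    fit = fit_exponential(_series(t, y))
    oi0, orate = _loglinear_oracle(t, y)
    assert fit.ok
    assert fit.rate == pytest.approx(rate, rel=1e-6)
    assert fit.amplitude == pytest.approx(i0, rel=1e-6)
    assert fit.rate == pytest.approx(orate, rel=1e-6)
    assert fit.amplitude == pytest.approx(oi0, rel=1e-6)


def test_monte_carlo_recovery_and_error_calibration():
    """2% noise: fitted rates are unbiased and the reported 1-sigma interval
    covers the truth at roughly the Gaussian frequency."""
    rng = np.random.default_rng(2024)
    truth, t = 1.25, np.asarray(R1_DELAYS)
    rates, errors, covered = [], [], 0
    for _ in range(500):
        y = 100 * np.exp(-truth * t) + rng.normal(0, 2.0, t.size)
        fit = fit_exponential(_series(t, y, noise=2.0))
        rates.append(fit.rate)
        errors.append(fit.rate_error)
        covered += abs(fit.rate - truth) < fit.rate_error
    rates = np.asarray(rates)
    assert abs(rates.mean() - truth) / truth < 0.01
    assert 0.58 < covered / 500 < 0.78
    # reported errors track the empirical scatter
    assert np.median(errors) == pytest.approx(rates.std(), rel=0.25)


def test_fit_failure_is_flagged_not_raised():
    t = np.asarray(R1_DELAYS)
    rising = 10.0 * np.exp(0.9 * t)  # growing signal: no positive decay rate
    fit = fit_exponential(_series(t, rising))
    assert not fit.ok and fit.reason
    with pytest.raises(AnalysisError):
        fit_exponential(_series([0.1, 0.2], [5.0, 4.0]))


def test_fit_is_permutation_and_scale_invariant():
    rng = np.random.default_rng(5)
    t = np.asarray(R2_DELAYS)
    y = 80 * np.exp(-20.0 * t) + rng.normal(0, 1.6, t.size)
    base = fit_exponential(_series(t, y, noise=1.6))
    perm = rng.permutation(t.size)
    shuffled = fit_exponential(_series(t[perm], y[perm], noise=1.6))
    assert shuffled.rate == pytest.approx(base.rate, rel=1e-6)
    assert shuffled.rate_error == pytest.approx(base.rate_error, rel=1e-6)
    scaled = fit_exponential(_series(t, 1e3 * y, noise=1.6e3))
    assert scaled.rate == pytest.approx(base.rate, rel=1e-6)
    assert scaled.rate_error == pytest.approx(base.rate_error, rel=1e-6)
    assert scaled.amplitude == pytest.approx(1e3 * base.amplitude, rel=1e-6)


def test_jackknife_error():
    t = np.asarray(R2_DELAYS)
    clean = 50 * np.exp(-22.0 * t)
    assert jackknife_rate_error(_series(t, clean)) == pytest.approx(0.0, abs=1e-5)
    rng = np.random.default_rng(7)
    noisy = clean + rng.normal(0, 1.0, t.size)
    s = _series(t, noisy, noise=1.0)
    jk = jackknife_rate_error(s)
    cov = fit_exponential(s).rate_error
    assert 0.5 < jk / cov < 2.0
    with pytest.raises(AnalysisError):
        jackknife_rate_error(_series([0.1, 0.2, 0.3], [3, 2, 1]))


def test_hnnoe_value_and_propagated_error():
    noe = compute_hnnoe(30.0, 100.0, 2.0, 2.0)
    assert noe.value == pytest.approx(0.300)
    assert noe.error == pytest.approx(0.0209, abs=5e-5)
    assert compute_hnnoe(100.0, 100.0, 2.0, 2.0).value == 1.0
    assert compute_hnnoe(-5.0, 100.0, 2.0, 2.0).value == -0.05
    # zero saturated peak: limit form
    assert compute_hnnoe(0.0, 100.0, 2.0, 2.0).error == pytest.approx(0.02)
    with pytest.raises(AnalysisError):
        compute_hnnoe(1.0, 0.0, 2.0, 2.0)


def test_hnnoe_error_matches_brute_force_monte_carlo():
    rng = np.random.default_rng(123)
    draws = rng.normal(30, 2, 100_000) / rng.normal(100, 2, 100_000)
    assert compute_hnnoe(30.0, 100.0, 2.0, 2.0).error == pytest.approx(
        draws.std(), rel=0.05
    )


def test_r2_over_r1_propagation():
    r1 = relaxation.RateFit(1.07, 0.02, 100, 1, 8, 0.0)
    r2 = relaxation.RateFit(22.0, 0.5, 100, 1, 8, 0.0)
    value, error = compute_r2_over_r1(r1, r2)
    assert value == pytest.approx(20.56, abs=0.005)
    expected = value * math.sqrt((0.5 / 22) ** 2 + (0.02 / 1.07) ** 2)
    assert error == pytest.approx(expected)
    # Monte-Carlo cross-check of the quadrature formula
    rng = np.random.default_rng(9)
    draws = rng.normal(22, 0.5, 100_000) / rng.normal(1.07, 0.02, 100_000)
    assert error == pytest.approx(draws.std(), rel=0.05)
    # symmetric case and zero-error case
    equal = relaxation.RateFit(2.0, 0.1, 1, 0, 8, 0.0)
    v, e = compute_r2_over_r1(equal, equal)
    assert v == 1.0 and e == pytest.approx(math.sqrt(2) * 0.05)
    exact = relaxation.RateFit(2.0, 0.0, 1, 0, 8, 0.0)
    assert compute_r2_over_r1(exact, exact) == (1.0, 0.0)


@given(
    sat=st.floats(-100, 100).filter(lambda x: abs(x) > 1e-3),
    ref=st.floats(1.0, 500.0),
    scale=st.floats(0.1, 1e4),
)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_hnnoe_scale_equivariance(sat, ref, scale):
    base = compute_hnnoe(sat, ref, 2.0, 2.0)
    scaled = compute_hnnoe(scale * sat, scale * ref, scale * 2.0, scale * 2.0)
    assert scaled.value == pytest.approx(base.value, rel=1e-9)
    assert scaled.error == pytest.approx(base.error, rel=1e-9)


def test_profiles_from_table_account_for_every_residue(wt_table):
    r1 = rate_profile(wt_table, "R1")
    r2 = rate_profile(wt_table, "R2")
    noe = noe_profile(wt_table)
    for prof in (r1, r2, noe):
        assert set(prof.values) | set(prof.missing) == set(range(1, 37))
        assert prof.missing[16] == "invisible" and prof.missing[20] == "omitted"
    ratio = r2r1_profile(r1, r2)
    for pos in ratio.values:
        assert ratio.values[pos][0].value > 0
    with pytest.raises(AnalysisError):
        r2r1_profile(r2, r1)


def test_doublet_residues_carry_two_values(tables_0mm):
    noe = noe_profile(tables_0mm["R8Q"])
    assert len(noe.values[3]) == 2 and len(noe.values[5]) == 2
    assert len(noe.values[10]) == 1


def test_region_average_basics(wt_table):
    noe = noe_profile(wt_table)
    mean_body, _, n_body = region_average(noe, 3, 27)
    mean_hinge, _, n_hinge = region_average(noe, 28, 36)
    assert mean_hinge < mean_body
    assert n_body == 23  # T3-K27 minus P16 and omitted L20
    assert n_hinge == 8  # S28-K36 minus P30
    with pytest.raises(EmptyRegionError):
        region_average(noe, 16, 16)


def test_region_average_constant_profile():
    from tailspin.relaxation import PeakValue, ResidueProfile

    prof = ResidueProfile(
        "WT", 0, "hnNOE", {p: [PeakValue(1, 0.4, 0.01)] for p in (3, 4, 5)}
    )
    mean, sd, n = region_average(prof, 3, 5)
    assert (mean, sd, n) == (pytest.approx(0.4), pytest.approx(0.0, abs=1e-12), 3)
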