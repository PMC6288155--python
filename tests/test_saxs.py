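"""Unit and property tests for SAXS profile computation and analysis."""

import io
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saxsguide.errors import GridMismatchError, GuinierFitError, SaxsGuideError
from saxsguide.saxs import (
    SAXSProfile,
    add_gaussian_noise,
    aggregate_profiles,
    cormap_test,
    debye_profile,
    guinier_rg,
    log_chi2_fit,
    longest_run_pvalue,
    read_crysol_int,
    read_dat,
    reduced_chi2,
    shannon_channels,
    write_dat,
)
from saxsguide.structures import Structure


def make_profile(q, i, s=None):
    return SAXSProfile(np.asarray(q, float), np.asarray(i, float), s)


# ---------------------------------------------------------------------------
# SAXSProfile contract


@pytest.mark.parametrize(
    "q,i,s",
    [
        ([0.2, 0.1], [1, 1], None),  # decreasing q
        ([-0.1, 0.1], [1, 1], None),  # negative q
        ([0.1, 0.2], [1, np.inf], None),  # nonfinite I
        ([0.1, 0.2], [1, 1], [1, -1]),  # negative sigma
        ([0.1, 0.2], [1, 1, 1], None),  # length mismatch
    ],
)
def test_profile_invariants_rejected(q, i, s):
    with pytest.raises(SaxsGuideError):
        make_profile(q, i, s)


# ---------------------------------------------------------------------------
# Debye calculator


def test_debye_single_scatterer_is_flat():
    s = Structure(np.zeros((1, 3)))
    p = debye_profile(s, [0.0, 0.1, 0.5], weights=[2.5])
    assert np.allclose(p.intensity, 2.5**2)


def test_debye_two_point_closed_form():
    # two unit scatterers 10 A apart at q = 0.1: I = 2(1 + sin(1)/1)
    s = Structure(np.array([[0.0, 0, 0], [10.0, 0, 0]]))
    p = debye_profile(s, [0.1])
    assert p.intensity[0] == pytest.approx(2 * (1 + math.sin(1.0) / 1.0), rel=1e-12)
    assert p.intensity[0] == pytest.approx(3.6829, abs=1e-4)


def test_debye_matches_naive_double_loop(rng):
    coords = rng.uniform(-20, 20, (20, 3))
    w = rng.uniform(0.5, 2.0, 20)
    q = np.linspace(0.0, 0.5, 23)
    p = debye_profile(Structure(coords), q, weights=w)
    # independent O(n^2) oracle
    expected = np.zeros_like(q)
    for i in range(20):
        for j in range(20):
            r = np.linalg.norm(coords[i] - coords[j])
            x = q * r
            sinc = np.where(x == 0, 1.0, np.sin(x) / np.where(x == 0, 1.0, x))
            expected += w[i] * w[j] * sinc
    assert np.allclose(p.intensity, expected, rtol=1e-10)


def test_debye_forward_intensity_and_bound(rng):
    coords = rng.uniform(-15, 15, (12, 3))
    w = rng.uniform(0.1, 3.0, 12)
    q = np.linspace(0.0, 1.0, 41)
    p = debye_profile(Structure(coords), q, weights=w)
    assert p.intensity[0] == pytest.approx(w.sum() ** 2, rel=1e-12)
    # |sinc| <= 1 implies |I(q)| <= I(0) for nonnegative weights
    assert np.all(np.abs(p.intensity) <= p.intensity[0] + 1e-9)


def test_debye_rejects_empty_and_negative_q():
    with pytest.raises(SaxsGuideError):
        debye_profile(Structure(np.zeros((0, 3))), [0.1])
    with pytest.raises(SaxsGuideError):
        debye_profile(Structure(np.zeros((2, 3))), [-0.1, 0.1])


# ---------------------------------------------------------------------------
# Reduced chi-square


def test_chi2_identity_fixed_mu():
    q = np.linspace(0.0, 0.5, 51)
    a = make_profile(q, np.exp(-q), np.full(51, 0.1))
    res = reduced_chi2(a, a, scale_mode=1.0)
    assert res.chi2 == 0.0
    assert res.n_points == 51


def test_chi2_exact_scaling_recovers_mu():
    q = [0.0, 0.1, 0.2]
    res = reduced_chi2(
        make_profile(q, [1, 2, 3]), make_profile(q, [2, 4, 6], [1, 1, 1])
    )
    assert res.scale == pytest.approx(2.0)
    assert res.chi2 == pytest.approx(0.0, abs=1e-24)


def test_chi2_optimal_mu_matches_grid_scan(rng):
    q = np.linspace(0.01, 0.5, 51)
    state = make_profile(q, rng.uniform(1, 5, 51))
    target = make_profile(q, rng.uniform(1, 5, 51), rng.uniform(0.1, 0.5, 51))
    res = reduced_chi2(state, target)
    mus = np.linspace(0.01, 10, 20001)
    grid = [
        reduced_chi2(state, target, scale_mode=float(mu)).chi2 for mu in mus
    ]
    assert res.chi2 <= min(grid) + 1e-6


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**32 - 1), st.floats(0.01, 100.0))
def test_chi2_invariant_to_state_scale(seed, const):
    r = np.random.default_rng(seed)
    q = np.linspace(0.0, 0.5, 21)
    state = make_profile(q, r.uniform(0.5, 5, 21))
    target = make_profile(q, r.uniform(0.5, 5, 21), r.uniform(0.05, 0.5, 21))
    scaled = make_profile(q, const * state.intensity)
    a = reduced_chi2(state, target).chi2
    b = reduced_chi2(scaled, target).chi2
    assert a == pytest.approx(b, rel=1e-9, abs=1e-12)


def test_chi2_interpolates_onto_target_grid():
    state = make_profile(np.linspace(0.0, 0.6, 61), np.linspace(1, 2, 61))
    target = make_profile(np.linspace(0.05, 0.5, 10), np.linspace(1.1, 1.8, 10),
                          np.full(10, 0.1))
    res = reduced_chi2(state, target)
    assert res.n_points == 10
    with pytest.raises(GridMismatchError):
        reduced_chi2(state, target, interpolate=False)


def test_chi2_rejects_zero_state_in_optimal_mode():
    q = [0.0, 0.1, 0.2]
    with pytest.raises(SaxsGuideError):
        reduced_chi2(make_profile(q, [0, 0, 0]), make_profile(q, [1, 2, 3]))


def test_chi2_sigma_floor_keeps_result_finite():
    q = np.linspace(0.0, 0.5, 11)
    a = make_profile(q, np.linspace(2, 1, 11))
    b = make_profile(q, np.linspace(1.9, 1.1, 11))  # sigma absent -> zeros
    res = reduced_chi2(a, b)
    assert np.isfinite(res.chi2)


# ---------------------------------------------------------------------------
# Log-scale fit


def test_log_fit_identity():
    q = np.linspace(0.01, 0.5, 30)
    p = make_profile(q, np.exp(-3 * q) + 0.5)
    res = log_chi2_fit(p, p)
    f, c = res.scale
    assert f == pytest.approx(1.0, abs=1e-6)
    assert c == pytest.approx(0.0, abs=1e-6)
    assert res.chi2 == pytest.approx(0.0, abs=1e-8)


def test_log_fit_pure_scale():
    q = np.linspace(0.01, 0.5, 30)
    base = np.exp(-3 * q) + 0.5
    res = log_chi2_fit(make_profile(q, base), make_profile(q, 2 * base))
    f, c = res.scale
    assert f == pytest.approx(0.5, abs=1e-6)
    assert c == pytest.approx(0.0, abs=1e-6)


def test_log_fit_offset_matches_grid_scan(rng):
    q = np.linspace(0.01, 0.5, 40)
    base = 3 * np.exp(-4 * q) + 1.0
    calc = make_profile(q, base + 0.1)
    exp = make_profile(q, base)
    res = log_chi2_fit(calc, exp)
    f, c = res.scale
    # brute-force 2-D scan oracle
    fs = np.linspace(0.8, 1.2, 81)
    cs = np.linspace(-0.1, 0.3, 81)
    best = min(
        (np.mean((np.log(calc.intensity) - np.log(fv * exp.intensity + cv)) ** 2),
         fv, cv)
        for fv, cv in itertools.product(fs, cs)
        if np.all(fv * exp.intensity + cv > 0)
    )
    assert res.chi2 <= best[0] + 1e-12
    assert f == pytest.approx(1.0, abs=0.005)
    assert c == pytest.approx(0.1, abs=0.005)


def test_log_fit_rejects_nonpositive_calc():
    q = [0.0, 0.1, 0.2]
    with pytest.raises(SaxsGuideError):
        log_chi2_fit(make_profile(q, [1.0, 0.0, 1.0]), make_profile(q, [1, 1, 1]))


# ---------------------------------------------------------------------------
# Guinier analysis


def test_guinier_ideal_curve_exact():
    q = np.linspace(0.001, 0.12, 60)
    rg_true = 10.0
    p = make_profile(q, 5.0 * np.exp(-(q**2) * rg_true**2 / 3))
    res = guinier_rg(p)
    assert res.rg == pytest.approx(rg_true, rel=1e-9)
    assert res.i0 == pytest.approx(5.0, rel=1e-9)


def test_guinier_sphere_form_factor():
    R = 30.0
    q = np.linspace(0.005, 0.2, 120)
    x = q * R
    ff = (3 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
    res = guinier_rg(make_profile(q, ff))
    assert res.rg == pytest.approx(math.sqrt(3.0 / 5.0) * R, rel=0.02)


def test_guinier_constant_profile_gives_zero_rg():
    q = np.linspace(0.001, 0.1, 20)
    res = guinier_rg(make_profile(q, np.ones(20)))
    assert res.rg == 0.0


def test_guinier_failures():
    q = np.linspace(0.001, 0.1, 20)
    with pytest.raises(GuinierFitError):
        guinier_rg(make_profile(q, np.exp(+(q**2) * 50)))  # rising intensity
    with pytest.raises(GuinierFitError):
        guinier_rg(make_profile(q[:2], np.ones(2)))  # too few points


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.floats(2.0, 80.0))
def test_guinier_recovers_any_generating_rg(rg_true):
    q = np.linspace(1e-4, min(1.2 / rg_true, 0.5), 50)
    p = make_profile(q, np.exp(-(q**2) * rg_true**2 / 3))
    assert guinier_rg(p).rg == pytest.approx(rg_true, rel=1e-6)


# ---------------------------------------------------------------------------
# Shannon channels


@pytest.mark.parametrize(
    "qmax,dmax,expected",
    [(1.0, 68.46, 22), (math.pi, 1.0, 1), (0.5, 62.8, 10)],
)
def test_shannon_channel_counts(qmax, dmax, expected):
    assert shannon_channels(qmax, dmax) == expected


def test_shannon_rejects_nonpositive():
    with pytest.raises(SaxsGuideError):
        shannon_channels(0.0, 10.0)


# ---------------------------------------------------------------------------
# Aggregation and noise


def test_aggregate_identical_copies():
    q = np.linspace(0, 0.5, 11)
    p = make_profile(q, np.exp(-q))
    agg = aggregate_profiles([p] * 5)
    assert np.allclose(agg.intensity, p.intensity)
    assert np.allclose(agg.sigma, 0.0)


def test_aggregate_two_point_formula():
    q = [0.0, 0.1]
    agg = aggregate_profiles([make_profile(q, [1, 1]), make_profile(q, [3, 1])])
    assert agg.intensity[0] == pytest.approx(2.0)
    assert agg.sigma[0] == pytest.approx(math.sqrt(2.0))  # sample convention


def test_aggregate_matches_two_pass_oracle(rng):
    q = np.linspace(0, 0.5, 17)
    profs = [make_profile(q, rng.uniform(1, 5, 17)) for _ in range(100)]
    agg = aggregate_profiles(profs)
    stack = np.array([p.intensity for p in profs])
    mean = stack.sum(axis=0) / 100
    var = ((stack - mean) ** 2).sum(axis=0) / 99
    assert np.allclose(agg.intensity, mean, rtol=1e-10)
    assert np.allclose(agg.sigma, np.sqrt(var), rtol=1e-10)


def test_aggregate_rejects_single_and_mismatched():
    q = np.linspace(0, 0.5, 5)
    p = make_profile(q, np.ones(5))
    with pytest.raises(SaxsGuideError):
        aggregate_profiles([p])
    with pytest.raises(GridMismatchError):
        aggregate_profiles([p, make_profile(q + 0.01, np.ones(5))])


def test_noise_zero_sigma_passthrough():
    q = np.linspace(0, 0.5, 9)
    p = make_profile(q, np.exp(-q))
    assert np.array_equal(add_gaussian_noise(p, 0).intensity, p.intensity)


def test_noise_moments_recovered():
    n = 100_000
    sigma = 0.37
    p = SAXSProfile(np.arange(n) * 1e-5, np.zeros(n), np.full(n, sigma))
    eps = add_gaussian_noise(p, 42).intensity
    assert abs(eps.mean()) < 4 * sigma / math.sqrt(n)
    assert eps.std() == pytest.approx(sigma, rel=0.02)


def test_noise_reproducible_under_seed():
    q = np.linspace(0, 0.5, 9)
    p = make_profile(q, np.ones(9), np.full(9, 0.1))
    assert np.array_equal(
        add_gaussian_noise(p, 5).intensity, add_gaussian_noise(p, 5).intensity
    )


# ---------------------------------------------------------------------------
# Correlation map (runs test)


def test_cormap_identical_profiles():
    q = np.linspace(0, 0.5, 10)
    p = make_profile(q, np.ones(10))
    run, pval = cormap_test(p, p)
    assert run == 0
    assert pval == 1.0


def test_cormap_hand_counted_example():
    # residual signs (+, +, +, -): longest run 3, P = 6/16 by enumeration
    q = [0.0, 0.1, 0.2, 0.3]
    a = make_profile(q, [2, 2, 2, 0])
    b = make_profile(q, [1, 1, 1, 1])
    run, pval = cormap_test(a, b)
    assert run == 3
    assert pval == pytest.approx(6 / 16)


def test_cormap_single_run_spans_curve():
    q = np.linspace(0, 0.5, 7)
    a = make_profile(q, np.full(7, 2.0))
    b = make_profile(q, np.ones(7))
    run, pval = cormap_test(a, b)
    assert run == 7
    assert pval == pytest.approx(2 / 2**7)


@pytest.mark.parametrize("n", range(1, 13))
def test_cormap_null_matches_enumeration(n):
    """DP run-length null agrees with brute-force enumeration for N <= 12."""
    maxruns = []
    for bits in itertools.product([0, 1], repeat=n):
        best = cur = 1
        for a, b in zip(bits, bits[1:]):
            cur = cur + 1 if a == b else 1
            best = max(best, cur)
        maxruns.append(best)
    for L in range(1, n + 2):
        expected = sum(m >= L for m in maxruns) / 2**n
        assert longest_run_pvalue(n, L) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(1, 200), st.integers(1, 200))
def test_cormap_pvalue_in_unit_interval(n, run):
    p = longest_run_pvalue(n, min(run, n))
    assert 0.0 < p <= 1.0
    assert longest_run_pvalue(n, 1) == 1.0


# ---------------------------------------------------------------------------
# File formats


def test_dat_roundtrip():
    q = np.linspace(0, 0.5, 13)
    p = make_profile(q, np.exp(-q), np.full(13, 0.07))
    buf = io.StringIO()
    write_dat(p, buf, header="demo run")
    buf.seek(0)
    back = read_dat(buf)
    assert np.allclose(back.q, p.q, atol=1e-9)
    assert np.allclose(back.intensity, p.intensity, rtol=1e-8)
    assert np.allclose(back.sigma, p.sigma, rtol=1e-8)


def test_dat_sigma_column_optional():
    back = read_dat(io.StringIO("# c\n0.0 1.0\n0.1 0.9\n"))
    assert np.array_equal(back.sigma, [0.0, 0.0])


def test_crysol_int_reader_skips_header_and_extra_columns():
    text = "Crysol output header line\n0.00 100.0 90.0 10.0 0.0\n0.01 99.0 89.0 10.0 0.0\n"
    p = read_crysol_int(io.StringIO(text))
    assert np.allclose(p.q, [0.0, 0.01])
    assert np.allclose(p.intensity, [100.0, 99.0])
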