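"""Closed-form fixtures, algebraic identities, and scaling laws for TD features."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from emgpr import features_td as td

random_window = arrays(
    float,
    st.integers(min_value=8, max_value=64),
    elements=st.floats(-100, 100, allow_nan=False, width=32),
).filter(lambda x: np.ptp(x) > 1e-6)


class TestFixtureValues:
    """Hand-evaluated values on the shared x4 = [1, -2, 3, -4] window."""

    def test_x4_values(self, x4):
        assert td.mav(x4) == pytest.approx(2.5, rel=1e-9)
        assert td.std(x4) == pytest.approx(math.sqrt(29 / 3), rel=1e-9)
        assert td.var(x4) == pytest.approx(10.0, rel=1e-9)
        assert td.wl(x4) == pytest.approx(15.0, rel=1e-9)
        assert td.zc(x4) == 3
        assert td.peak_trio(x4) == (1, 3.0, 0.0)
        assert td.ssc(x4, 0.0) == 2
        assert td.ssc(x4, 20.0) == 1
        assert td.damv(x4) == pytest.approx(3.75, rel=1e-9)
        assert td.fdim_curve_length(x4, 1) == pytest.approx(11.25, rel=1e-9)
        assert td.mfl(x4) == pytest.approx(math.log10(math.sqrt(83)), rel=1e-9)
        assert td.skew(x4) == pytest.approx(0.0, abs=1e-12)
        assert td.kurt(x4) == pytest.approx(77.5625 / 7.25**2, rel=1e-9)
        assert td.iav(x4) == pytest.approx(10.0, rel=1e-9)
        assert td.hjorth_mobility(x4) == pytest.approx(math.sqrt((672 / 9 / 2) / (29 / 3)), rel=1e-9)
        assert td.dasdv(x4) == pytest.approx(math.sqrt(83 / 3), rel=1e-9)
        assert td.wam(x4, 4.0) == 2
        assert td.perc75(x4) == 3.0
        np.testing.assert_array_equal(td.hist(x4, 9), [1, 0, 1, 0, 0, 0, 1, 0, 1])

    def test_constant_window(self):
        c = np.full(4, 3.0)
        assert td.mav(c) == 3.0
        assert td.std(c) == 0.0
        assert td.wl(c) == 0.0
        assert td.zc(np.ones(4)) == 0
        assert td.peak_trio(np.zeros(4)) == (0, 0.0, 0.0)
        assert td.perc75(c) == 3.0
        assert np.isnan(td.skew(c)) and np.isnan(td.kurt(c))
        assert np.isnan(td.hjorth_mobility(c)) and np.isnan(td.hjorth_complexity(c))
        assert np.isnan(td.mfl(c))
        counts = td.hist(c, 9)
        assert counts[0] == 4 and counts.sum() == 4

    def test_zeros_do_not_count_as_crossings(self):
        assert td.zc(np.array([1.0, 0.0, -1.0])) == 0

    def test_monotone_ramp(self):
        ramp = np.array([0.0, 1.0, 2.0, 3.0])
        assert td.wl(ramp) == 3.0
        assert td.ssc(ramp, 0.0) == 0

    def test_peak_trio_two_equal_peaks(self):
        assert td.peak_trio(np.array([5.0, 5.0, 1.0, 1.0])) == (2, 5.0, 0.0)

    def test_perc75_hundred(self):
        assert td.perc75(np.arange(1.0, 101.0)) == 76.0

    def test_mavs_sequences(self):
        np.testing.assert_allclose(td.mavs([2.0, 5.0, 5.0]), [3.0, 0.0, 0.0])
        np.testing.assert_allclose(td.mavs([4.0]), [0.0])
        np.testing.assert_allclose(td.mavs([1.0, 1.0, 1.0]), [0.0, 0.0, 0.0])

    def test_energy_ratio_values(self):
        # per-channel energies 1, 2, 4, 8
        w = np.zeros((4, 4))
        for j, e in enumerate([1.0, 2.0, 4.0, 8.0]):
            w[j, 0] = math.sqrt(e)
        np.testing.assert_allclose(td.energy_ratio(w), [0.125, 0.03125, 0.0625], rtol=1e-9)

    def test_energy_ratio_identical_channels(self):
        w = np.tile(np.array([1.0, -2.0, 3.0, -4.0]), (4, 1))
        np.testing.assert_allclose(td.energy_ratio(w), [1.0, 1.0, 1.0], rtol=1e-9)
        assert len(td.energy_ratio(w)) == 3


class TestCorrelation:
    def test_self_and_negated(self, x4):
        assert td.cor(x4, x4) == pytest.approx(1.0, rel=1e-12)
        assert td.cor(x4, -x4) == pytest.approx(1.0, rel=1e-12)

    def test_matches_pearson_oracle(self, x4):
        other = np.array([1.0, -2.0, 3.0, 4.0])
        r = td.cor(x4, other)
        assert 0.0 <= r <= 1.0
        assert r == pytest.approx(abs(np.corrcoef(x4, other)[0, 1]), rel=1e-12)

    def test_constant_input_returns_zero(self, x4):
        assert td.cor(x4, np.full(4, 2.0)) == 0.0


class TestFractal:
    def test_fdim_closed_form_on_line(self):
        # for X(i) = i the curve length collapses to floor((N-1)/k) * (N-1) / N
        N, k = 400, 5
        ramp = np.arange(float(N))
        expected = ((N - 1) // k) * (N - 1) / N
        assert td.fdim_curve_length(ramp, k) == pytest.approx(expected, rel=1e-12)

    def test_fdim_invalid_stride(self, x4):
        with pytest.raises(ValueError):
            td.fdim_curve_length(x4, 4)

    def test_hfd_of_line_is_one(self):
        assert td.hfd(np.arange(400.0)) == pytest.approx(1.01, abs=0.02)

    def test_hfd_of_white_noise_between_one_and_two(self):
        rng = np.random.default_rng(0)
        v = td.hfd(rng.normal(size=400))
        assert 1.0 < v < 2.2


class TestHjorth:
    def test_complexity_of_pure_sine_near_one(self):
        t = np.arange(4000) / 2000.0
        x = np.sin(2 * np.pi * 20.0 * t)  # fs >> f
        assert td.hjorth_complexity(x) == pytest.approx(1.0, abs=0.05)


class TestStatistics:
    def test_gaussian_kurtosis_near_three(self):
        x = np.random.default_rng(3).normal(size=100_000)
        assert td.kurt(x) == pytest.approx(3.0, abs=0.1)


class TestIdentitiesAndScaling:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(x=random_window)
    def test_algebraic_identities(self, x):
        N = len(x)
        assert td.iav(x) == pytest.approx(N * td.mav(x), rel=1e-9)
        assert td.damv(x) == pytest.approx(td.wl(x) / N, rel=1e-9)
        # dasdv^2 * (N-1) = 10^(2*mfl)
        assert td.dasdv(x) ** 2 * (N - 1) == pytest.approx(10 ** (2 * td.mfl(x)), rel=1e-6)
        assert td.hist(x, 9).sum() == N

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(x=random_window, a=st.floats(0.1, 50.0))
    def test_homogeneity_and_invariance(self, x, a):
        for f in (td.mav, td.std, td.wl, td.damv, td.dasdv, td.iav):
            assert f(a * x) == pytest.approx(a * f(x), rel=1e-6)
        for f in (td.zc, lambda v: td.ssc(v, 0.0)):
            assert f(a * x) == f(x)
        for f in (td.hjorth_mobility, td.hjorth_complexity, td.skew, td.kurt):
            assert f(a * x) == pytest.approx(f(x), rel=1e-5)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(x=random_window)
    def test_brute_force_equation_oracles(self, x):
        """Direct loop evaluation of the printed sums matches the vectorised code."""
        N = len(x)
        assert td.wl(x) == pytest.approx(sum(abs(x[i] - x[i - 1]) for i in range(1, N)), rel=1e-9)
        assert td.zc(x) == sum(1 for i in range(1, N) if -x[i] * x[i - 1] > 0)
        assert td.ssc(x, 0.0) == sum(
            1 for i in range(1, N - 1) if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > 0
        )
        assert td.wam(x, 0.5) == sum(1 for i in range(N - 1) if abs(x[i] - x[i + 1]) > 0.5)
        assert td.var(x) == pytest.approx(sum(v * v for v in x) / (N - 1), rel=1e-9)
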