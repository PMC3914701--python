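"""Sample-size machinery: the normal-quantile power factor, per-point N
maps, normality screening, Wilcoxon maps against exact enumeration."""

import numpy as np
import pytest
from scipy.special import ndtri

from cardiatlas.power import (
    DifferenceField,
    normality_screen,
    percent_reduction,
    power_constant,
    sample_size_map,
    simulate_power,
    two_sided_normal_critical,
    wilcoxon_significance_map,
    wilcoxon_threshold,
)


class TestPowerConstant:
    def test_unadjusted_alpha_half_power_edge(self):
        """At p -> 0.5 the power term vanishes: f -> u_alpha^2 = 1.96^2."""
        f = power_constant(0.05, 0.5 + 1e-12, 1)
        assert f == pytest.approx(1.959964**2, abs=1e-4)

    def test_quantile_oracle(self):
        """f equals the squared sum of the two normal critical values."""
        for alpha, p, P in [(0.05, 0.8, 1), (0.01, 0.9, 100), (0.05, 0.9, 16386)]:
            expected = (ndtri(1 - alpha / P / 2) + ndtri(p)) ** 2
            assert power_constant(alpha, p, P) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_power(self):
        fs = [power_constant(0.05, p, 50) for p in (0.6, 0.7, 0.8, 0.9, 0.95)]
        assert all(a < b for a, b in zip(fs, fs[1:]))

    def test_two_sided_critical_value(self):
        assert two_sided_normal_critical(0.05) == pytest.approx(1.959964, abs=1e-6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            power_constant(0.0, 0.9)
        with pytest.raises(ValueError):
            power_constant(0.05, 0.4)
        with pytest.raises(ValueError):
            power_constant(0.05, 0.9, 0)


class TestSampleSizeMap:
    def _field(self, diffs, modality="3D"):
        return DifferenceField(np.asarray(diffs, dtype=float), modality)

    def test_delta_quarter_scaling(self, rng):
        d = self._field(rng.normal(0, 1.3, size=(10, 40)))
        m1 = sample_size_map(d, delta_mm=1.0)
        m2 = sample_size_map(d, delta_mm=2.0)
        np.testing.assert_allclose(m2.n_required, m1.n_required / 4)

    def test_zero_differences_give_zero_n(self):
        m = sample_size_map(self._field(np.zeros((5, 7))))
        assert np.all(m.n_required == 0)

    def test_point_permutation_equivariance(self, rng):
        d = rng.normal(size=(8, 30))
        perm = rng.permutation(30)
        m = sample_size_map(self._field(d), n_points_bonferroni=30)
        mp = sample_size_map(self._field(d[:, perm]), n_points_bonferroni=30)
        np.testing.assert_allclose(mp.n_required, m.n_required[perm])

    def test_integer_ceiling_and_summary(self, rng):
        d = self._field(rng.normal(0, 1, size=(20, 50)))
        m = sample_size_map(d)
        assert np.all(m.n_required_int >= m.n_required)
        assert np.all(m.n_required_int < m.n_required + 1)
        s = m.summary()
        assert s["iqr_low"] <= s["median"] <= s["iqr_high"]

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            sample_size_map(self._field(np.zeros((1, 5))))


class TestNormalityScreen:
    def test_gaussian_null_rarely_fails(self):
        rng = np.random.default_rng(5)
        d = DifferenceField(rng.normal(size=(20, 500)))
        screen = normality_screen(d)
        # Bonferroni threshold 0.05/500: essentially no false rejections
        assert screen.failing_fraction < 0.01

    def test_heavy_tails_detected(self):
        rng = np.random.default_rng(6)
        d = np.column_stack(
            [rng.standard_cauchy(200), rng.normal(size=200), rng.normal(size=200)]
        )
        screen = normality_screen(DifferenceField(d))
        assert not screen.passed[0]
        assert screen.passed[1] and screen.passed[2]

    def test_single_point_uses_unadjusted_level(self, rng):
        d = DifferenceField(rng.normal(size=(10, 1)))
        screen = normality_screen(d, alpha=0.05)
        assert screen.threshold == pytest.approx(0.05)

    def test_constant_column_indeterminate(self, rng):
        d = np.column_stack([np.full(10, 2.0), rng.normal(size=10)])
        screen = normality_screen(DifferenceField(d))
        assert screen.indeterminate[0] and not screen.indeterminate[1]


class TestPercentReduction:
    def _maps(self, var2, var3):
        d2 = DifferenceField(np.random.default_rng(0).normal(0, 1, (5, len(var2))))
        m2 = sample_size_map(d2, n_points_bonferroni=100)
        m3 = sample_size_map(d2, n_points_bonferroni=100)
        m2.n_required = np.asarray(var2, dtype=float)
        m3.n_required = np.asarray(var3, dtype=float)
        return m2, m3

    def test_identical_maps_zero_reduction(self, rng):
        m2, m3 = self._maps([50.0, 60], [50.0, 60])
        np.testing.assert_allclose(percent_reduction(m2, m3), [0.0, 0.0])

    def test_arithmetic_example(self):
        m2, m3 = self._maps([100.0], [56.0])
        assert percent_reduction(m2, m3)[0] == pytest.approx(44.0)

    def test_elementwise_oracle_on_random_maps(self, rng):
        n2 = rng.uniform(1, 200, 50)
        n3 = rng.uniform(1, 200, 50)
        m2, m3 = self._maps(n2, n3)
        np.testing.assert_allclose(
            percent_reduction(m2, m3), 100.0 * (n2 - n3) / n2, rtol=1e-12
        )

    def test_zero_n2d_masked(self):
        m2, m3 = self._maps([0.0, 10.0], [5.0, 5.0])
        red = percent_reduction(m2, m3)
        assert np.isnan(red[0]) and red[1] == pytest.approx(50.0)

    def test_mismatched_parameters_rejected(self, rng):
        d = DifferenceField(rng.normal(size=(5, 10)))
        m_a = sample_size_map(d, delta_mm=1.0, n_points_bonferroni=10)
        m_b = sample_size_map(d, delta_mm=2.0, n_points_bonferroni=10)
        with pytest.raises(ValueError, match="delta"):
            percent_reduction(m_a, m_b)


def wilcoxon_exact_enumeration(d):
    """Two-sided signed-rank p-value by enumerating all 2^n sign patterns."""
    d = np.asarray(d, dtype=float)
    assert np.all(d != 0) and len(set(np.abs(d))) == len(d), "no ties for oracle"
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    w_all = []
    for mask in range(2**n):
        signs = [(mask >> i) & 1 for i in range(n)]
        w_all.append(sum(r for r, s in zip(ranks, signs) if s))
    w_all = np.asarray(w_all)
    mean_w = n * (n + 1) / 4
    p = np.mean(np.abs(w_all - mean_w) >= abs(w_obs - mean_w) - 1e-12)
    return p


class TestWilcoxonMap:
    def test_threshold_matches_minus_ln_bonferroni(self):
        assert wilcoxon_threshold(0.05, 16386) == pytest.approx(12.70, abs=0.05)

    def test_small_sample_matches_exact_enumeration(self):
        rng = np.random.default_rng(17)
        n = 6
        a = rng.normal(1.0, 1.0, size=(n, 4))
        b = rng.normal(0.0, 1.0, size=(n, 4))
        res = wilcoxon_significance_map(a, b, n_points_bonferroni=4)
        for j in range(4):
            p_oracle = wilcoxon_exact_enumeration(a[:, j] - b[:, j])
            assert res.p_values[j] == pytest.approx(p_oracle, abs=1e-12)

    def test_identical_inputs_fully_masked(self, rng):
        a = rng.normal(size=(8, 5))
        res = wilcoxon_significance_map(a, a.copy())
        assert res.masked.all()

    def test_large_sample_detects_shift(self):
        rng = np.random.default_rng(3)
        n, p = 60, 10
        a = rng.normal(1.0, 1.0, size=(n, p))
        b = rng.normal(0.0, 1.0, size=(n, p))
        res = wilcoxon_significance_map(a, b, n_points_bonferroni=p)
        assert res.significant.all()

    def test_too_few_subjects_rejected(self, rng):
        a = rng.normal(size=(3, 4))
        with pytest.raises(ValueError, match="at least 5"):
            wilcoxon_significance_map(a, a + 1)


class TestSimulatePower:
    def test_power_increases_with_n(self):
        p_small = simulate_power(10, alpha_adjusted=0.05, n_replicates=2000, rng_seed=0)
        p_large = simulate_power(40, alpha_adjusted=0.05, n_replicates=2000, rng_seed=0)
        assert p_large > p_small

    def test_null_rejects_at_alpha(self):
        p0 = simulate_power(
            30, delta=0.0, alpha_adjusted=0.05, n_replicates=20_000, rng_seed=1
        )
        assert p0 == pytest.approx(0.05, abs=0.01)
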