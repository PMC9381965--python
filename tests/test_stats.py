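"""Location tests, normality screening, routing, subgroup contrast."""

import itertools
import math

import numpy as np
import pytest

from hodasym.asymmetry import dti_asymmetry
from hodasym.calibration import HODCall
from hodasym.core import ValidationError
from hodasym.stats import (
    compare_groups,
    lilliefors_normality,
    paired_t,
    subgroup_contrast,
    welch_t,
    wilcoxon_mann_whitney,
)


class TestLilliefors:
    def test_normal_sample_not_rejected(self, rng):
        x = rng.normal(3.0, 2.0, size=500)
        res = lilliefors_normality(x, seed=1)
        assert res.p_value > 0.05
        assert 0.0 <= res.p_value <= 1.0

    def test_two_point_sample_rejected(self, rng):
        x = rng.choice([0.0, 1.0], size=500)
        res = lilliefors_normality(x, seed=1)
        assert res.p_value < 0.05 and res.significant

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError):
            lilliefors_normality([1.0, 2.0, 3.0])  # n < 4
        with pytest.raises(ValidationError):
            lilliefors_normality([2.0] * 10)  # zero variance

    def test_seeded_reproducibility(self, rng):
        x = rng.normal(size=50)
        assert lilliefors_normality(x, seed=3).p_value == \
            lilliefors_normality(x, seed=3).p_value


class TestPairedT:
    def test_hand_value(self):
        # diffs (-1, -1, -2): mean -4/3, sd 1/sqrt(3), t = -4
        res = paired_t([1, 2, 3], [2, 3, 5])
        d = np.array([-1.0, -1.0, -2.0])
        t_closed = d.mean() / (d.std(ddof=1) / math.sqrt(3))
        assert res.statistic == pytest.approx(t_closed) == pytest.approx(-4.0)
        assert res.df == 2

    def test_zero_difference_variance_errors(self):
        with pytest.raises(ValidationError):
            paired_t([1, 2, 3], [2, 3, 4])  # constant shift of exactly c
        with pytest.raises(ValidationError):
            paired_t([1, 2, 3], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            paired_t([1, 2, 3], [1, 2])

    def test_forced_rejection_with_shift_plus_noise(self, rng):
        a = rng.normal(size=200)
        b = a + 5.0 + rng.normal(0, 0.1, size=200)
        assert paired_t(a, b).p_value < 1e-10


class TestWelchT:
    def test_identical_samples(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_textbook_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        res = welch_t(a, b)
        se = math.sqrt(a.var(ddof=1) / 3 + b.var(ddof=1) / 3)
        t = (a.mean() - b.mean()) / se
        num = (a.var(ddof=1) / 3 + b.var(ddof=1) / 3) ** 2
        den = (a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2
        assert res.statistic == pytest.approx(t)
        assert res.df == pytest.approx(num / den)

    def test_degenerate_constant_samples(self):
        res = welch_t([2.0, 2.0], [5.0, 5.0])
        assert res.degenerate and math.isinf(res.statistic) and res.p_value == 0.0
        res_eq = welch_t([2.0, 2.0], [2.0, 2.0])
        assert res_eq.degenerate and res_eq.p_value == 1.0

    def test_swap_invariance(self, rng):
        a, b = rng.normal(size=12), rng.normal(1, 2, size=9)
        r1, r2 = welch_t(a, b), welch_t(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.statistic == pytest.approx(-r2.statistic)


def enumerate_wmw_p(a, b):
    """Exact two-sided WMW p by full enumeration of group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    N = n1 * len(b)

    def u_of(group_a):
        rest = list(pooled)
        ga = list(group_a)
        for x in ga:
            rest.remove(x)
        return sum(1 for x in ga for y in rest if x > y)

    u_obs = u_of(a)
    lo, hi = min(u_obs, N - u_obs), max(u_obs, N - u_obs)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = u_of([pooled[i] for i in comb])
        total += 1
        if u <= lo or u >= hi:
            count += 1
    return count / total


class TestWilcoxonMannWhitney:
    def test_exact_small_example(self):
        res = wilcoxon_mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)  # 2 of 6 arrangements

    def test_symmetric_multisets_give_p_one(self):
        res = wilcoxon_mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_exact_matches_enumeration(self, rng):
        for _ in range(20):
            n1, n2 = rng.integers(2, 6), rng.integers(2, 7)
            pooled = rng.permutation(rng.normal(size=n1 + n2))
            a, b = pooled[:n1], pooled[n1:]
            res = wilcoxon_mann_whitney(a, b)
            assert res.p_value == pytest.approx(enumerate_wmw_p(a, b), abs=1e-12)

    def test_exact_close_to_asymptotic_at_n8(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(0.5, 1.0, size=8)
            exact = wilcoxon_mann_whitney(a, b).p_value
            approx = mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic").pvalue
            assert abs(exact - approx) <= 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_mann_whitney([], [1.0])


class TestTypeICalibration:
    def test_rejection_rate_under_null(self, rng):
        """welch_t and WMW reject at alpha=0.05 in 5% +/- 1% of seeded
        null replicates (both samples from one normal)."""
        n_rep = 10_000
        rej_w = rej_u = 0
        for _ in range(n_rep):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            rej_w += welch_t(a, b).p_value < 0.05
            rej_u += wilcoxon_mann_whitney(a, b).p_value < 0.05
        assert abs(rej_w / n_rep - 0.05) < 0.01
        assert abs(rej_u / n_rep - 0.05) < 0.01


class TestRouting:
    def test_normal_data_routes_to_t(self, rng):
        a, b = rng.normal(size=80), rng.normal(0.2, 1, size=70)
        res, routing = compare_groups(a, b, seed=2)
        assert routing["normal"] and res.test_name == "welch_t"

    def test_non_normal_data_routes_to_wmw(self, rng):
        a = rng.exponential(size=200) ** 3
        b = rng.normal(size=100)
        res, routing = compare_groups(a, b, seed=2)
        assert not routing["normal"]
        assert res.test_name == "wilcoxon_mann_whitney"

    def test_paired_routing(self, rng):
        a = rng.normal(size=60)
        b = a + rng.normal(0.5, 1.0, size=60)
        res, routing = compare_groups(a, b, paired=True, seed=2)
        assert routing["paired"] and res.test_name == "paired_t"


class TestSubgroupContrast:
    def _call(self, sid, exceeds):
        return HODCall(sid, "PD", 5.0 if exceeds else 1.0, exceeds,
                       "right", "right", True if exceeds else None)

    def _dti(self, sid, fa_diff, md_diff):
        fa = dti_asymmetry(0.45 * (1 + fa_diff / 100), 0.45, subject_id=sid, map="FA")
        md = dti_asymmetry(8e-4 * (1 + md_diff / 100), 8e-4, subject_id=sid, map="MD")
        return [fa, md]

    def test_forced_ordering(self):
        dti, calls = [], []
        for i in range(4):
            calls.append(self._call(f"p{i}", True))
            dti += self._dti(f"p{i}", -40.0 - i, 9.0 + i)
        for i in range(4, 8):
            calls.append(self._call(f"p{i}", False))
            dti += self._dti(f"p{i}", -1.0 + 0.1 * i, 0.5 - 0.1 * i)
        out = subgroup_contrast(dti, calls)
        assert out["FA"].mean_diff_pd_plus < out["FA"].mean_diff_pd_minus
        assert out["MD"].mean_diff_pd_plus > out["MD"].mean_diff_pd_minus
        assert out["FA"].test is not None and out["MD"].test is not None

    def test_empty_group_not_computable(self):
        calls = [self._call(f"p{i}", False) for i in range(4)]
        dti = sum((self._dti(f"p{i}", -1.0 + i * 0.5, 0.5 * i) for i in range(4)), [])
        out = subgroup_contrast(dti, calls)
        assert out["FA"].test is None and out["FA"].n_pd_plus == 0

    def test_missing_pd_call_errors(self):
        with pytest.raises(ValidationError):
            subgroup_contrast(self._dti("p0", -10, 5), [])
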