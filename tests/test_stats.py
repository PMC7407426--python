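"""Exact signed-rank, SPI-vs-1, Feltz-Miller CV test, significance maps."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_h
from scipy import stats as sps

from lungstrain import (
    feltz_miller_cv_test,
    roi_significance_maps,
    spi_vs_one_test,
    wilcoxon_signed_rank,
)
from lungstrain.stats_tests import GroupROIData


def brute_force_signed_rank_p(d, alternative):
    """Literal enumeration of all 2^n sign assignments (oracle)."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = np.array(
        [ranks[np.array(signs, bool)].sum() for signs in itertools.product([0, 1], repeat=n)]
    )
    p_g = (ws >= w_obs - 1e-12).mean()
    p_l = (ws <= w_obs + 1e-12).mean()
    if alternative == "greater":
        return p_g
    if alternative == "less":
        return p_l
    return min(1.0, 2 * min(p_g, p_l))


class TestWilcoxonSignedRank:
    def test_n5_all_positive_one_sided(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 6.0), alternative="greater")
        assert res.p_value == pytest.approx(1 / 32)
        assert res.statistic == 15.0

    def test_n5_all_positive_two_sided_floor(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 6.0), alternative="two-sided")
        assert res.p_value == pytest.approx(2 / 32)  # can never reach 0.05

    def test_identical_pairs_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank(x, x)
        assert res.p_value == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.ones(3), np.ones(4))

    @pytest.mark.parametrize("alternative", ["greater", "less", "two-sided"])
    def test_matches_bruteforce_enumeration_on_random_inputs(self, alternative):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            n = rng.integers(2, 11)
            # half-integer values force ties in |d| with decent probability
            d = rng.integers(-4, 5, size=n) + 0.5 * rng.integers(0, 2, size=n)
            if (d == 0).all():
                continue
            p = wilcoxon_signed_rank(d, alternative=alternative).p_value
            assert p == pytest.approx(brute_force_signed_rank_p(d, alternative), abs=1e-12)

    def test_matches_scipy_exact_when_no_ties(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.3, 1.0, 12)
        ours = wilcoxon_signed_rank(x, alternative="greater").p_value
        ref = sps.wilcoxon(x, alternative="greater", method="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-12)


class TestSpiVsOne:
    def test_all_spi_one_not_significant(self):
        with pytest.warns(UserWarning):
            res = spi_vs_one_test(np.ones(5))
        assert res.p_value == 1.0

    def test_n5_all_above_one_signed_rank(self):
        res = spi_vs_one_test(np.array([1.05, 1.1, 1.2, 1.01, 1.3]), alternative="greater")
        assert res.p_value == pytest.approx(1 / 32)

    def test_mann_whitney_mode_maximal_u(self):
        res = spi_vs_one_test(
            np.array([1.05, 1.1, 1.2, 1.01, 1.3]), alternative="greater", mode="mann_whitney"
        )
        assert res.statistic == 25.0  # every SPI beats every reference value

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            spi_vs_one_test(np.array([]))


class TestFeltzMiller:
    def test_identical_groups_d_zero(self):
        x = np.array([1.0, 1.2, 0.9, 1.1, 1.05])
        res = feltz_miller_cv_test([x, x.copy()])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_scale_invariance_of_statistic(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(0.0, 0.2, 40)
        b = rng.lognormal(0.0, 0.35, 40)
        d0 = feltz_miller_cv_test([a, b]).statistic
        d1 = feltz_miller_cv_test([2.7 * a, b]).statistic
        d2 = feltz_miller_cv_test([a, 0.3 * b]).statistic
        assert d1 == pytest.approx(d0, rel=1e-9)
        assert d2 == pytest.approx(d0, rel=1e-9)

    def test_input_validation(self):
        ok = np.array([1.0, 1.1, 0.9])
        with pytest.raises(ValueError, match="2 groups"):
            feltz_miller_cv_test([ok])
        with pytest.raises(ValueError, match="n >= 2"):
            feltz_miller_cv_test([ok, np.array([1.0])])
        with pytest.raises(ValueError, match="positive"):
            feltz_miller_cv_test([ok, np.array([-1.0, -2.0, -0.5])])

    def test_power_against_twofold_cv_ratio(self):
        """CV ratio 2:1 at n = 100 per group is detected almost surely."""
        rng = np.random.default_rng(99)
        n_rep, n = 1000, 100
        # lognormal sigma chosen for CVs ~0.2 vs ~0.4
        a = rng.lognormal(0.0, 0.198, (n_rep, n))
        b = rng.lognormal(0.0, 0.385, (n_rep, n))
        rej = np.mean(
            [feltz_miller_cv_test([a[i], b[i]]).p_value < 0.05 for i in range(n_rep)]
        )
        assert rej > 0.9


class TestSignificanceMaps:
    def _group_data(self, rng, n_subj=5, amplify=0.1, n=10, noise=0.01):
        base = rng.uniform(0.15, 0.35, (n_subj, n, n))
        base[:, 0, 0] = np.nan  # one void cell everywhere
        t3 = base + amplify + rng.normal(0, noise, base.shape)
        samples = {
            t: [
                {
                    (i, j): rng.normal(m[i, j], 0.05 * (1 + 3 * (t == "T3") * (amplify > 0)), 50)
                    for i in range(n)
                    for j in range(n)
                    if np.isfinite(m[i, j])
                }
                for m in arrs
            ]
            for t, arrs in (("T1", base), ("T3", t3))
        }
        return GroupROIData(mean={"T1": base, "T3": t3}, samples=samples)

    def test_uniform_amplification_flags_all_testable_cells(self):
        rng = np.random.default_rng(0)
        data = self._group_data(rng, amplify=0.1)
        maps = roi_significance_maps(data, alpha=0.05, alternative="greater")
        for fam in ("strain_t1_vs_t3", "spi_vs_1"):
            sm = maps[fam]
            assert sm.n_testable == 99
            assert sm.n_significant == sm.n_testable
        assert maps["shi_t1_vs_t3"].n_significant == maps["shi_t1_vs_t3"].n_testable

    def test_alpha_zero_flags_nothing(self):
        rng = np.random.default_rng(1)
        data = self._group_data(rng, amplify=0.1)
        maps = roi_significance_maps(data, alpha=0.0)
        assert all(m.n_significant == 0 for m in maps.values())

    def test_void_cells_untestable(self):
        rng = np.random.default_rng(2)
        maps = roi_significance_maps(self._group_data(rng))
        for m in maps.values():
            assert not m.testable[0, 0]
            assert np.isnan(m.p_values[0, 0])

    def test_single_subject_untestable(self):
        rng = np.random.default_rng(3)
        data = self._group_data(rng, n_subj=1)
        maps = roi_significance_maps(data)
        assert maps["strain_t1_vs_t3"].n_testable == 0


@settings(max_examples=30, deadline=None)
@given(
    st_h.lists(st_h.integers(min_value=-6, max_value=6), min_size=2, max_size=8).filter(
        lambda v: any(x != 0 for x in v)
    )
)
def test_signed_rank_exact_p_is_valid_probability(diffs):
    """Exact p-values are within (0, 1] and symmetric under sign flip."""
    d = np.asarray(diffs, float)
    p_g = wilcoxon_signed_rank(d, alternative="greater").p_value
    p_l = wilcoxon_signed_rank(-d, alternative="less").p_value
    assert 0 < p_g <= 1
    assert p_g == pytest.approx(p_l, abs=1e-12)
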