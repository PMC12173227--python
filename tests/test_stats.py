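import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neqbrain.stats import bh_adjust, cohens_d, perm_ranksum, spearman_perm


def exhaustive_ranksum_p(x, y):
    """Brute-force enumeration oracle for the two-sided rank-sum test."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    nx = len(x)
    center = nx * (len(pooled) + 1) / 2
    obs = abs(ranks[:nx].sum() - center)
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), nx):
        total += 1
        if abs(ranks[list(comb)].sum() - center) >= obs - 1e-12:
            count += 1
    return count / total


class TestPermRanksum:
    def test_separated_samples_match_enumeration(self):
        # all 20 assignments enumerable: exactly the two extreme splits
        # reach the observed statistic -> p = 0.1
        x, y = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        assert exhaustive_ranksum_p(x, y) == pytest.approx(0.1)
        res = perm_ranksum(x, y, n_perm=20_000, seed=1)
        assert res.p_value == pytest.approx(0.1, abs=0.01)

    def test_identical_samples_p_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = perm_ranksum(x, x, n_perm=2000, seed=0)
        assert res.p_value > 0.9

    def test_p_never_zero(self):
        res = perm_ranksum(np.arange(5.0), np.arange(5.0) + 100, n_perm=50, seed=0)
        assert res.p_value >= 1 / 51

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        reps = 200
        for i in range(reps):
            x = rng.standard_normal(20)
            y = rng.standard_normal(20)
            if perm_ranksum(x, y, n_perm=400, seed=i).p_value < 0.05:
                hits += 1
        assert 0.02 <= hits / reps <= 0.09

    def test_deterministic_given_seed(self, rng):
        x, y = rng.standard_normal(10), rng.standard_normal(10)
        a = perm_ranksum(x, y, n_perm=500, seed=9)
        b = perm_ranksum(x, y, n_perm=500, seed=9)
        assert a.p_value == b.p_value

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            perm_ranksum([1.0], [2.0, 3.0], n_perm=10, seed=0)


class TestBH:
    def step_up_oracle(self, p, alpha):
        """Textbook step-up rule, written independently."""
        m = len(p)
        order = np.argsort(p)
        sig = np.zeros(m, bool)
        max_r = 0
        for r in range(1, m + 1):
            if p[order[r - 1]] <= alpha * r / m:
                max_r = r
        sig[order[:max_r]] = True
        return sig

    def test_three_test_thresholds(self):
        thr, _ = bh_adjust([0.01, 0.02, 0.04], alpha=0.05)
        assert thr == pytest.approx([0.05 / 3, 2 * 0.05 / 3, 0.05])

    def test_all_significant_when_largest_passes(self):
        _, sig = bh_adjust([0.01, 0.02, 0.04], alpha=0.05)
        assert sig.all()

    def test_single_test_reduces_to_alpha(self):
        thr, sig = bh_adjust([0.04], alpha=0.05)
        assert thr[0] == pytest.approx(0.05)
        assert sig[0]

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(max_examples=50, deadline=None)
    def test_matches_step_up_oracle(self, p, alpha):
        _, sig = bh_adjust(p, alpha)
        assert np.array_equal(sig, self.step_up_oracle(np.asarray(p), alpha))

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_flags_monotone_in_p(self, p):
        _, sig = bh_adjust(p, 0.05)
        p = np.asarray(p)
        for i in range(len(p)):
            for j in range(len(p)):
                if p[i] <= p[j] and sig[j]:
                    assert sig[i]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([])


class TestCohensD:
    def test_equal_means_zero_negligible(self, rng):
        x = rng.standard_normal(30)
        d, desc = cohens_d(x, x + 0.0)
        assert d == 0
        assert desc == "negligible"

    def test_large_sample_uncorrected(self, rng):
        # n = 30 + 30 >= 50: mean difference 1, pooled SD 1 -> d = 1
        x = rng.standard_normal(30)
        x = (x - x.mean()) / x.std(ddof=1)
        d, desc = cohens_d(x, x - 1.0)
        assert d == pytest.approx(1.0, rel=1e-9)
        assert desc == "large"

    def test_small_sample_correction_factor(self, rng):
        # n = 10 + 10 < 50: multiply by 1 - 3/(4*20 - 9) = 1 - 3/71
        x = rng.standard_normal(10)
        x = (x - x.mean()) / x.std(ddof=1)
        d, _ = cohens_d(x, x - 1.0)
        assert d == pytest.approx(1 - 3 / 71, rel=1e-9)

    @pytest.mark.parametrize(
        "shift,expected",
        [(0.1, "negligible"), (0.3, "small"), (0.6, "medium"), (1.0, "large")],
    )
    def test_descriptor_cutoffs(self, shift, expected):
        # constructed samples with pooled SD exactly 1 and n >= 50
        x = np.concatenate([np.zeros(25) - 1, np.zeros(25) + 1]) * (
            1 / np.std(np.concatenate([np.zeros(25) - 1, np.zeros(25) + 1]), ddof=1)
        )
        y = x - shift
        d, desc = cohens_d(x, y)
        assert d == pytest.approx(shift, rel=1e-9)
        assert desc == expected

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestSpearmanPerm:
    def test_monotone_transform_gives_one(self, rng):
        x = rng.standard_normal(20)
        res = spearman_perm(x, np.exp(x), n_perm=200, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self, rng):
        x = rng.standard_normal(20)
        res = spearman_perm(x, -x, n_perm=200, seed=0)
        assert res.statistic == pytest.approx(-1.0)

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        reps = 200
        for i in range(reps):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30)
            if spearman_perm(x, y, n_perm=400, seed=i).p_value < 0.05:
                hits += 1
        assert 0.02 <= hits / reps <= 0.09

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman_perm([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], n_perm=10, seed=0)

    def test_agrees_with_scipy_statistic(self, rng):
        from scipy.stats import spearmanr

        x, y = rng.standard_normal(25), rng.standard_normal(25)
        res = spearman_perm(x, y, n_perm=10, seed=0)
        assert res.statistic == pytest.approx(spearmanr(x, y).statistic)
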