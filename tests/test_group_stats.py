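import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hralab import (
    InsufficientDataError,
    RepeatedMeasuresBlock,
    UndefinedCorrelationError,
    condition_deltas,
    dunn_bonferroni,
    friedman_test,
    spearman_correlation,
)


def ordered_block(n=9, k=3):
    """Every subject ranks the conditions identically (no ties)."""
    return RepeatedMeasuresBlock(
        np.tile(np.arange(1.0, k + 1), (n, 1)) + np.arange(n)[:, None] * 10,
        conditions=tuple(f"c{i}" for i in range(k)),
    )


class TestFriedman:
    def test_perfectly_ordered_rows(self):
        res = friedman_test(ordered_block())
        assert res.statistic == pytest.approx(18.0)
        assert res.p_value == pytest.approx(stats.chi2.sf(18.0, 2), rel=1e-12)
        assert res.p_value == pytest.approx(1.2341e-4, rel=1e-3)

    def test_identical_columns_give_null_result(self):
        block = RepeatedMeasuresBlock(
            np.tile(np.arange(9.0)[:, None], (1, 3)), conditions=("a", "b", "c")
        )
        res = friedman_test(block)
        assert res.statistic == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_scipy_including_ties(self, seed):
        r = np.random.default_rng(seed)
        data = np.round(r.standard_normal((7, 4)), 1)  # rounding forces ties
        block = RepeatedMeasuresBlock(data, conditions=("a", "b", "c", "d"))
        mine = friedman_test(block)
        ref = stats.friedmanchisquare(*data.T)
        assert mine.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_invariant_to_row_monotone_transform(self, rng):
        data = rng.normal(size=(9, 3))
        a = friedman_test(RepeatedMeasuresBlock(data))
        b = friedman_test(RepeatedMeasuresBlock(np.exp(data)))
        assert a.statistic == pytest.approx(b.statistic)

    def test_too_few_subjects(self):
        with pytest.raises(InsufficientDataError):
            friedman_test(RepeatedMeasuresBlock(np.ones((2, 3))))

    def test_exact_permutation_matches_brute_force_enumeration(self):
        import itertools

        n = 4
        rng = np.random.default_rng(5)
        data = rng.standard_normal((n, 3))
        block = RepeatedMeasuresBlock(data)
        exact = friedman_test(block, method="exact")
        # independent oracle: enumerate all 6^n rank assignments
        perms = list(itertools.permutations((1.0, 2.0, 3.0)))
        q_obs = exact.statistic
        tail = 0
        for assignment in itertools.product(perms, repeat=n):
            sums = np.sum(assignment, axis=0)
            q = float(np.sum(sums**2)) / n - 12.0 * n
            tail += q >= q_obs - 1e-9
        assert exact.p_value == pytest.approx(tail / 6.0**n, abs=1e-12)

    def test_exact_p_of_unanimous_ordering(self):
        # all rows agree: only the 6 unanimous assignments reach max Q
        res = friedman_test(ordered_block(n=4), method="exact")
        assert res.p_value == pytest.approx(6.0 / 6.0**4, abs=1e-15)

    def test_exact_method_rejects_ties_and_wrong_k(self):
        tied = RepeatedMeasuresBlock(np.array([[1.0, 1.0, 2.0]] * 4))
        with pytest.raises(ValueError):
            friedman_test(tied, method="exact")
        four = RepeatedMeasuresBlock(np.random.default_rng(0).normal(size=(4, 4)),
                                     conditions=("a", "b", "c", "d"))
        with pytest.raises(ValueError):
            friedman_test(four, method="exact")


class TestDunnBonferroni:
    def test_identical_columns_all_adjusted_p_one(self):
        block = RepeatedMeasuresBlock(
            np.tile(np.arange(9.0)[:, None], (1, 3)), conditions=("a", "b", "c")
        )
        res = dunn_bonferroni(block)
        assert all(p == 1.0 for _z, p in res.pairwise.values())

    def test_extreme_pair_of_ordered_block(self):
        res = dunn_bonferroni(ordered_block())
        z, p_adj = res.pairwise[("c0", "c2")]
        assert abs(z) == pytest.approx(2.0 / np.sqrt(12.0 / 54.0), abs=1e-12)
        assert abs(z) == pytest.approx(4.2426, abs=1e-4)
        assert p_adj == pytest.approx(6.6e-5, rel=0.01)

    def test_adjusted_never_below_unadjusted(self, rng):
        for _ in range(10):
            block = RepeatedMeasuresBlock(rng.normal(size=(6, 3)))
            res = dunn_bonferroni(block)
            for z, p_adj in res.pairwise.values():
                assert p_adj >= 2 * stats.norm.sf(abs(z)) - 1e-15
                assert p_adj <= 1.0


class TestSpearman:
    def test_perfect_monotone(self):
        up = spearman_correlation([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        down = spearman_correlation([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert up.statistic == pytest.approx(1.0, abs=1e-12)
        assert down.statistic == pytest.approx(-1.0, abs=1e-12)

    def test_closed_form_on_tie_free_permutation(self):
        rng = np.random.default_rng(99)
        x = np.arange(1.0, 10.0)
        y = rng.permutation(x)
        res = spearman_correlation(x, y)
        d = stats.rankdata(x) - stats.rankdata(y)
        n = len(x)
        rho = 1 - 6 * np.sum(d**2) / (n * (n**2 - 1))
        assert res.statistic == pytest.approx(rho, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        a = spearman_correlation(x, y)
        b = spearman_correlation(np.exp(x), y**3)
        assert a.statistic == pytest.approx(b.statistic, abs=1e-12)

    def test_constant_variable_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_correlation([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_length_contract(self):
        with pytest.raises(InsufficientDataError):
            spearman_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestConditionDeltas:
    @staticmethod
    def table():
        return pd.DataFrame(
            [
                {"subject_id": "s1", "condition": "rest", "hr": 64.0},
                {"subject_id": "s1", "condition": "snsa_stim", "hr": 75.0},
                {"subject_id": "s1", "condition": "recovery", "hr": 65.0},
                {"subject_id": "s2", "condition": "rest", "hr": 60.0},
                {"subject_id": "s2", "condition": "snsa_stim", "hr": 72.0},
                {"subject_id": "s2", "condition": "recovery", "hr": 61.0},
            ]
        )

    def test_stim_minus_rest(self):
        deltas = condition_deltas(self.table(), "hr", "stim-rest")
        assert deltas["s1"] == pytest.approx(11.0)
        assert deltas["s2"] == pytest.approx(12.0)

    def test_antisymmetry_of_pair_order(self):
        t = self.table()
        a = condition_deltas(t, "hr", "recovery-stim")
        assert a["s1"] == pytest.approx(65.0 - 75.0)

    def test_identical_conditions_give_zero(self):
        t = self.table()
        t["hr"] = 70.0
        assert (condition_deltas(t, "hr", "stim-rest") == 0).all()

    def test_subject_missing_condition_dropped_with_warning(self, caplog):
        t = self.table().iloc[:-1]  # s2 loses recovery
        with caplog.at_level("WARNING"):
            deltas = condition_deltas(t, "hr", "recovery-stim")
        assert list(deltas.index) == ["s1"]
        assert "dropping" in caplog.text
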