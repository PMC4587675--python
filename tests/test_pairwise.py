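"""Tests for robust LSD comparisons, pattern assignment, fold-change calls."""

import numpy as np
import pytest
from scipy import stats

from betanova import (
    BetaConfig,
    assign_pattern,
    classical_f,
    fold_change_classify,
    hybrid_f,
    pairwise_test,
    robust_lsd_threshold,
)
from betanova.estimators import GaussianParams
from betanova.pairwise import PairwiseResult
import dataclasses


def _pattern_from_adjusted(groups, config, alpha=0.05):
    """Pattern from within-gene Bonferroni-adjusted pairwise p-values."""
    results = pairwise_test(groups, config, alpha=alpha, adjust="bonferroni")
    decided = [
        dataclasses.replace(r, significant=r.p_adjusted <= alpha) for r in results
    ]
    return assign_pattern(decided, len(groups))

from conftest import make_de_record


def _params(variances):
    return [
        GaussianParams(mean=0.0, variance=v, source="mle") for v in variances
    ]


class TestLsdThreshold:
    def test_beta_zero_matches_textbook_fisher_lsd(self, rng):
        # Fisher's LSD from the classical ANOVA mean square error
        groups = [rng.normal(m, 0.5, 4) for m in (1.0, 2.0, 2.5)]
        sizes = [4, 4, 4]
        n, m = 12, 3
        ssw = sum(len(g) * g.var() for g in groups)
        mse = ssw / (n - m)
        expected = stats.t.ppf(0.975, n - m) * np.sqrt(mse * (1 / 4 + 1 / 4))
        params = [
            GaussianParams(mean=g.mean(), variance=g.var(), source="mle")
            for g in groups
        ]
        got = robust_lsd_threshold(params, sizes, 0.05, (0, 1))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_balanced_sizes_symmetric(self):
        params = _params([0.4, 0.2, 0.3, 0.1])
        lsds = {
            robust_lsd_threshold(params, [5, 5, 5, 5], 0.05, (i, j))
            for i in range(4)
            for j in range(i + 1, 4)
        }
        assert len({round(v, 12) for v in lsds}) == 1

    def test_scale_relation(self):
        params = _params([0.4, 0.2])
        doubled = _params([0.8, 0.4])
        base = robust_lsd_threshold(params, [3, 3], 0.05, (0, 1))
        big = robust_lsd_threshold(doubled, [3, 3], 0.05, (0, 1))
        assert big == pytest.approx(base * np.sqrt(2), rel=1e-12)


class TestPairwiseTest:
    def test_equal_means_not_significant(self, rng, config):
        groups = [rng.normal(3.0, 0.01, 5) for _ in range(3)]
        results = pairwise_test(groups, config)
        assert not any(r.significant for r in results)

    def test_recovers_two_block_pattern(self, config):
        # means 3,3,5,5 with sigma2=0.05 and n_j=3: the cross pairs separate
        # while the within-block pairs do not, in the vast majority of
        # replicates (within-gene Bonferroni leaves ~alpha-level splits, so
        # the bound is set with binomial margin below the ~94% observed rate)
        correct = 0
        reps = 100
        for seed in range(reps):
            r = np.random.default_rng(seed)
            groups = [r.normal(m, np.sqrt(0.05), 3) for m in (3, 3, 5, 5)]
            pattern = _pattern_from_adjusted(groups, config)
            correct += pattern.partition == ((1, 2), (3, 4))
        assert correct / reps >= 0.90

    def test_two_block_pattern_survives_outlier(self, config):
        correct = 0
        reps = 100
        for seed in range(reps):
            r = np.random.default_rng(1000 + seed)
            groups = [r.normal(m, np.sqrt(0.05), 3) for m in (3, 3, 5, 5)]
            groups[0][int(r.integers(0, 3))] = 7.0 + max(g.max() for g in groups)
            pattern = _pattern_from_adjusted(groups, config)
            correct += pattern.partition == ((1, 2), (3, 4))
        assert correct / reps >= 0.90

    def test_m2_agrees_with_omnibus(self, config):
        # with two groups the LSD decision is the omnibus test (t^2 = F)
        for seed in range(50):
            r = np.random.default_rng(seed)
            delta = r.choice([0.0, 0.3, 1.5])
            groups = [r.normal(3.0, 0.3, 4), r.normal(3.0 + delta, 0.3, 4)]
            omni = hybrid_f(groups, config)
            pair = pairwise_test(groups, config, alpha=0.05)[0]
            assert pair.significant == (omni.p_value < 0.05)
            assert pair.p_value == pytest.approx(omni.p_value, rel=1e-9)

    def test_swap_symmetry_of_direction(self, rng, config):
        groups = [rng.normal(4.0, 0.05, 4), rng.normal(1.0, 0.05, 4)]
        fwd = pairwise_test(groups, config)[0]
        rev = pairwise_test(groups[::-1], config)[0]
        assert fwd.significant == rev.significant
        assert {fwd.direction, rev.direction} == {"up", "down"}
        assert fwd.mean_diff == pytest.approx(rev.mean_diff, rel=1e-12)

    def test_within_gene_adjustment(self, rng, config):
        groups = [rng.normal(m, 0.2, 3) for m in (2.0, 2.1, 4.0)]
        results = pairwise_test(groups, config, adjust="bonferroni")
        for r in results:
            assert r.p_adjusted >= r.p_value - 1e-12


class TestAssignPattern:
    def _pairs(self, sig):
        out = []
        for (i, j), s in sig.items():
            out.append(
                PairwiseResult(
                    pair=(i, j), mean_diff=1.0, lsd=0.5, significant=s,
                    p_value=0.5, direction="none",
                )
            )
        return out

    def test_no_significant_pairs(self):
        sig = {(i, j): False for i in range(1, 5) for j in range(i + 1, 5)}
        pattern = assign_pattern(self._pairs(sig), 4)
        assert pattern.partition == ((1, 2, 3, 4),)

    def test_all_significant_pairs(self):
        sig = {(i, j): True for i in range(1, 5) for j in range(i + 1, 5)}
        pattern = assign_pattern(self._pairs(sig), 4)
        assert pattern.partition == ((1,), (2,), (3,), (4,))
        assert str(pattern) == "{1}|{2}|{3}|{4}"

    def test_non_transitive_calls_merge(self):
        # 1~2 and 2~3 equal but 1-3 different: merged into one class
        sig = {(1, 2): False, (2, 3): False, (1, 3): True}
        pattern = assign_pattern(self._pairs(sig), 3)
        assert pattern.partition == ((1, 2, 3),)

    def test_relabeling_invariance(self):
        sig = {(1, 2): False, (2, 3): True, (1, 3): True}
        base = assign_pattern(self._pairs(sig), 3)
        relab = {("b", "c"): False, ("c", "a"): True, ("b", "a"): True}
        other = assign_pattern(self._pairs(relab), 3, labels=["b", "c", "a"])
        assert base.partition == ((1, 2), (3,))
        assert other.partition == (("b", "c"), ("a",))


class TestFoldChange:
    @pytest.mark.parametrize(
        "mi, mj, expected",
        [(3.0, 3.0, "none"), (4.0, 1.0, "up"), (1.0, 4.0, "down"),
         (2.0, 1.1, "none")],
    )
    def test_ratio_mode(self, mi, mj, expected):
        assert fold_change_classify(mi, mj) == expected

    def test_log2_mode(self):
        assert fold_change_classify(5.2, 4.0, scale="log2") == "up"
        assert fold_change_classify(4.0, 5.2, scale="log2") == "down"
        assert fold_change_classify(4.5, 4.0, scale="log2") == "none"

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError):
            fold_change_classify(-1.0, 2.0)
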