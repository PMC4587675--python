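"""Robust LSD pairwise comparisons, expression patterns, fold-change calls.

After a significant omnibus F_beta test, the robust least-significant-
difference rule declares groups i and j different when

    |mu_i - mu_j| > LSD_beta = t_{alpha/2, n-m} sqrt(MSE_beta (1/n_i + 1/n_j)),

with MSE_beta = sum_j n_j s2_j / (n - m) built from the hybrid variance
estimates.  At beta = 0 this is exactly Fisher's LSD.  The m(m-1)/2 pairwise
decisions are summarised as an expression pattern: the partition of
conditions into equal-mean classes, obtained as the connected components of
the graph whose edges are the non-significant pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .estimators import BetaConfig, GaussianParams, hybrid_estimate
from .testing import adjust_pvalues, record_scale, _group_arrays

__all__ = [
    "ExpressionPattern",
    "PairwiseResult",
    "assign_pattern",
    "fold_change_classify",
    "pairwise_test",
    "robust_lsd_threshold",
]


@dataclass(frozen=True)
class PairwiseResult:
    """Decision for one unordered pair of conditions."""

    pair: tuple
    mean_diff: float
    lsd: float
    significant: bool
    p_value: float
    direction: str  # "up", "down" or "none" under the 2-fold rule
    p_adjusted: float | None = None


@dataclass(frozen=True)
class ExpressionPattern:
    """Partition of condition labels into equal-mean classes."""

    partition: tuple[tuple, ...]

    def __str__(self) -> str:
        return "|".join(
            "{" + ",".join(str(c) for c in block) + "}" for block in self.partition
        )


def robust_lsd_threshold(
    params: Sequence[GaussianParams],
    sizes: Sequence[int],
    alpha: float,
    pair: tuple[int, int],
) -> float:
    """LSD_beta for one pair of groups given per-group hybrid estimates."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    sizes = np.asarray(sizes, dtype=float)
    variances = np.array([p.variance for p in params], dtype=float)
    n = sizes.sum()
    m = sizes.size
    mse = float((sizes * variances).sum() / (n - m))
    i, j = pair
    t_crit = stats.t.ppf(1.0 - alpha / 2.0, df=n - m)
    return float(t_crit * np.sqrt(mse * (1.0 / sizes[i] + 1.0 / sizes[j])))


def fold_change_classify(
    mean_i: float, mean_j: float, threshold: float = 1.0, scale: str = "ratio"
) -> str:
    """Classify a pair as up/down/none by the log2 fold-change rule.

    In ``"ratio"`` mode (default) the statistic is ``log2(mean_i / mean_j)``
    and both means must be positive; in ``"log2"`` mode the means are taken
    to be on the log2 scale already and the statistic is their difference.
    ``|statistic| > threshold`` (default 1, i.e. 2-fold) yields "up"/"down".
    """
    if scale == "ratio":
        if mean_i <= 0 or mean_j <= 0:
            raise ValueError("ratio fold change needs positive means")
        log_fc = np.log2(mean_i / mean_j)
    elif scale == "log2":
        log_fc = mean_i - mean_j
    else:
        raise ValueError("scale must be 'ratio' or 'log2'")
    if log_fc > threshold:
        return "up"
    if log_fc < -threshold:
        return "down"
    return "none"


def pairwise_test(
    record,
    config: BetaConfig,
    alpha: float = 0.05,
    labels: Sequence | None = None,
    fold_threshold: float = 1.0,
    fold_scale: str = "ratio",
    adjust: str | None = None,
    init_scale: float | None = None,
) -> list[PairwiseResult]:
    """All m(m-1)/2 robust LSD comparisons for one gene.

    A pair is significant when its absolute hybrid mean difference exceeds
    LSD_beta; the two-sided p-value is from the t distribution with n - m
    degrees of freedom of the standardised difference.  The direction is the
    fold-change class for significant pairs and "none" otherwise.  When
    ``adjust`` is "bh" or "bonferroni" the within-gene family of pairs is
    adjusted and reported in ``p_adjusted``.
    """
    groups = _group_arrays(record)
    m = len(groups)
    if labels is None:
        labels = list(range(1, m + 1))
    if len(labels) != m:
        raise ValueError("labels length must match the number of groups")
    scale = record_scale(groups, config) if init_scale is None else init_scale
    fitted = [hybrid_estimate(g, config, init_scale=scale) for g in groups]
    params = [p for p, _ in fitted]
    sizes = np.array([g.size for g in groups], dtype=float)
    n = sizes.sum()
    mse = float((sizes * np.array([p.variance for p in params])).sum() / (n - m))
    df = n - m
    results = []
    for i in range(m):
        for j in range(i + 1, m):
            diff = abs(params[i].mean - params[j].mean)
            lsd = robust_lsd_threshold(params, sizes, alpha, (i, j))
            se = np.sqrt(mse * (1.0 / sizes[i] + 1.0 / sizes[j]))
            p = float(2.0 * stats.t.sf(diff / se, df=df))
            significant = bool(diff > lsd)
            direction = "none"
            if significant:
                direction = fold_change_classify(
                    params[i].mean, params[j].mean, fold_threshold, fold_scale
                )
            results.append(
                PairwiseResult(
                    pair=(labels[i], labels[j]),
                    mean_diff=float(diff),
                    lsd=float(lsd),
                    significant=significant,
                    p_value=p,
                    direction=direction,
                )
            )
    if adjust is not None:
        adjusted = adjust_pvalues([r.p_value for r in results], adjust)
        results = [
            PairwiseResult(
                pair=r.pair,
                mean_diff=r.mean_diff,
                lsd=r.lsd,
                significant=r.significant,
                p_value=r.p_value,
                direction=r.direction,
                p_adjusted=float(a),
            )
            for r, a in zip(results, adjusted)
        ]
    return results


def assign_pattern(
    pairwise: Sequence[PairwiseResult], m: int, labels: Sequence | None = None
) -> ExpressionPattern:
    """Derive the equal-mean partition from a complete set of pairwise calls.

    Conditions joined by a non-significant pair fall in the same class
    (connected components), so a non-transitive set of calls merges into one
    class -- the most permissive reading of the pairwise matrix.
    """
    if labels is None:
        labels = list(range(1, m + 1))
    index = {lab: i for i, lab in enumerate(labels)}
    if len(pairwise) != m * (m - 1) // 2:
        raise ValueError("pairwise results must cover all m(m-1)/2 pairs")
    rows, cols = [], []
    for r in pairwise:
        i, j = index[r.pair[0]], index[r.pair[1]]
        if not r.significant:
            rows += [i, j]
            cols += [j, i]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    _, comp = connected_components(adj, directed=False)
    blocks: dict[int, list] = {}
    for lab, c in zip(labels, comp):
        blocks.setdefault(int(c), []).append(lab)
    ordered = sorted(blocks.values(), key=lambda b: index[b[0]])
    return ExpressionPattern(partition=tuple(tuple(b) for b in ordered))
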