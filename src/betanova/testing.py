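"""Gene-level omnibus tests: classical F, hybrid F_beta, permutation p-values.

For a gene observed in m >= 2 conditions with group sizes n_j, the one-way
ANOVA F-statistic is

    F = [sum_j n_j (mu_j - mu)^2 / (m - 1)] / [sum_j n_j s2_j / (n - m)],

where mu_j and s2_j are the per-group mean and MLE variance (divisor n_j,
so n_j * s2_j is the within-group sum of squares) and mu = sum n_j mu_j / n.
The hybrid statistic F_beta plugs in the hybrid estimates instead: the MLE
for groups without flagged outliers and the minimum beta-divergence fit for
groups with them.  Parametric p-values for both statistics come from the
upper tail of F(m-1, n-m); per-gene permutation p-values are available as a
distribution-free alternative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import (
    BetaConfig,
    GaussianParams,
    GroupSample,
    hybrid_estimate,
    hybrid_estimate_batch,
    mle_estimate,
    pooled_robust_scale,
)

__all__ = [
    "BatchTestResult",
    "GeneTestResult",
    "adjust_pvalues",
    "classical_f",
    "classical_f_batch",
    "count_label_splits",
    "f_pvalue",
    "hybrid_f",
    "moderated_scale",
    "record_scale",
    "hybrid_f_batch",
    "kruskal_wallis_batch",
    "permutation_pvalue",
]


@dataclass(frozen=True)
class GeneTestResult:
    """Omnibus test result for one gene."""

    gene_id: str
    f_stat: float
    df1: int
    df2: int
    p_value: float
    method: str
    group_params: tuple[GaussianParams, ...]
    outlier_mask: tuple[np.ndarray, ...]
    pooled_mean: float
    p_adjusted: float | None = None


@dataclass
class BatchTestResult:
    """Vectorised omnibus test results for a gene x sample matrix.

    ``group_means``/``group_variances`` are (G, m); ``source_beta`` marks the
    (gene, group) cells that used the robust estimate; ``outlier_mask`` is
    (G, n) in the input sample order.
    """

    f: np.ndarray
    df1: int
    df2: int
    p: np.ndarray
    group_means: np.ndarray
    group_variances: np.ndarray
    source_beta: np.ndarray
    outlier_mask: np.ndarray
    pooled_mean: np.ndarray
    group_labels: list
    group_sizes: np.ndarray
    method: str


def _group_arrays(record) -> list[np.ndarray]:
    groups = []
    for g in record:
        if isinstance(g, GroupSample):
            groups.append(np.asarray(g.values, dtype=float))
        else:
            groups.append(np.asarray(g, dtype=float))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if g.ndim != 1 or g.size < 2:
            raise ValueError("each group needs at least two observations")
        if not np.all(np.isfinite(g)):
            raise ValueError("non-finite expression value")
    return groups


def _f_from_params(
    means: np.ndarray, variances: np.ndarray, sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """F statistic and pooled mean from per-group (mean, variance, n).

    Accepts (m,) vectors or (G, m) matrices; reduces along the last axis.
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    n = sizes.sum()
    m = sizes.shape[-1]
    pooled = (sizes * means).sum(axis=-1) / n
    ssb = (sizes * (means - np.expand_dims(pooled, -1)) ** 2).sum(axis=-1)
    msw = (sizes * variances).sum(axis=-1) / (n - m)
    if np.any(msw <= 0):
        raise ZeroDivisionError("within-group mean square is zero (degenerate gene)")
    f = (ssb / (m - 1)) / msw
    return f, pooled


def moderated_scale(
    X: np.ndarray, indices: Sequence[np.ndarray], variance_floor: float = 1e-12
) -> np.ndarray:
    """Per-gene starting scale, floored at the across-gene median scale.

    A gene with a handful of samples carries very little information about
    its own error variance, and a chance underestimate would let the
    reweighting iteration lock onto a tight pair of points and mistake
    ordinary noise for outliers.  Because the one-way layout shares its
    error variance across genes as well as groups, each gene's pooled
    robust scale is floored at the median of those scales over all genes --
    the same borrowing of scale information across genes that moderated
    t/F statistics rely on.  Genes noisier than the bulk keep their own
    larger scale.
    """
    scale = pooled_robust_scale(X, indices, variance_floor)
    if scale.size > 1:
        scale = np.maximum(scale, np.median(scale))
    return scale


def record_scale(record, config: BetaConfig) -> float:
    """Pooled robust error variance of one gene's one-way layout.

    The one-way model shares a single error variance across groups, and
    tiny groups (n_j = 2, 3) carry almost no scale information alone, so
    every group's reweighting iteration is started at this gene-level
    pooled scale.
    """
    groups = _group_arrays(record)
    pooled = np.concatenate(groups)[None, :]
    offset = 0
    indices = []
    for g in groups:
        indices.append(np.arange(offset, offset + g.size))
        offset += g.size
    return float(pooled_robust_scale(pooled, indices, config.variance_floor)[0])


def f_pvalue(f: float, df1: int, df2: int) -> float:
    """Upper-tail probability of F(df1, df2) at the observed statistic."""
    if f < 0:
        raise ValueError("F statistic must be non-negative")
    return float(stats.f.sf(f, df1, df2))


def classical_f(record, gene_id: str = "") -> GeneTestResult:
    """Classical one-way ANOVA F-test from the per-group MLEs."""
    groups = _group_arrays(record)
    params = tuple(mle_estimate(g) for g in groups)
    sizes = np.array([g.size for g in groups], dtype=float)
    means = np.array([p.mean for p in params])
    variances = np.array([p.variance for p in params])
    f, pooled = _f_from_params(means, variances, sizes)
    df1 = len(groups) - 1
    df2 = int(sizes.sum()) - len(groups)
    return GeneTestResult(
        gene_id=gene_id,
        f_stat=float(f),
        df1=df1,
        df2=df2,
        p_value=f_pvalue(float(f), df1, df2),
        method="classical",
        group_params=params,
        outlier_mask=tuple(np.zeros(g.size, dtype=bool) for g in groups),
        pooled_mean=float(pooled),
    )


def hybrid_f(record, config: BetaConfig, gene_id: str = "") -> GeneTestResult:
    """Hybrid F_beta test: per-group hybrid estimates plugged into the F form.

    Reduces to :func:`classical_f` exactly when ``config.beta == 0`` or when
    no observation in any group is flagged as outlying.
    """
    groups = _group_arrays(record)
    scale = record_scale(groups, config)
    fitted = [hybrid_estimate(g, config, init_scale=scale) for g in groups]
    params = tuple(p for p, _ in fitted)
    masks = tuple(mask for _, mask in fitted)
    sizes = np.array([g.size for g in groups], dtype=float)
    means = np.array([p.mean for p in params])
    variances = np.array([p.variance for p in params])
    f, pooled = _f_from_params(means, variances, sizes)
    df1 = len(groups) - 1
    df2 = int(sizes.sum()) - len(groups)
    return GeneTestResult(
        gene_id=gene_id,
        f_stat=float(f),
        df1=df1,
        df2=df2,
        p_value=f_pvalue(float(f), df1, df2),
        method="hybrid",
        group_params=params,
        outlier_mask=masks,
        pooled_mean=float(pooled),
    )


def _group_index(groups: Sequence) -> tuple[list, list[np.ndarray]]:
    """Unique labels (in order of first appearance) and their column indices."""
    labels_arr = np.asarray(groups)
    seen: dict = {}
    for lab in labels_arr:
        if lab not in seen:
            seen[lab] = None
    labels = list(seen)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    indices = [np.flatnonzero(labels_arr == lab) for lab in labels]
    for idx in indices:
        if idx.size < 2:
            raise ValueError("every group needs at least two samples")
    return labels, indices


def _batch_test(
    X: np.ndarray, groups: Sequence, config: BetaConfig | None, method: str
) -> BatchTestResult:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a (genes, samples) matrix")
    labels, indices = _group_index(groups)
    if sum(idx.size for idx in indices) != X.shape[1]:
        raise ValueError("group labels do not cover the sample columns")
    n_genes = X.shape[0]
    m = len(labels)
    sizes = np.array([idx.size for idx in indices], dtype=float)
    means = np.empty((n_genes, m))
    variances = np.empty((n_genes, m))
    source_beta = np.zeros((n_genes, m), dtype=bool)
    mask = np.zeros(X.shape, dtype=bool)
    init_scale = None
    if method != "classical":
        init_scale = moderated_scale(X, indices, config.variance_floor)
    for j, idx in enumerate(indices):
        sub = X[:, idx]
        if method == "classical":
            means[:, j] = sub.mean(axis=1)
            variances[:, j] = sub.var(axis=1)
        else:
            mu, var, sub_mask, used_beta = hybrid_estimate_batch(sub, config, init_scale)
            means[:, j] = mu
            variances[:, j] = var
            source_beta[:, j] = used_beta
            mask[:, idx] = sub_mask
    f, pooled = _f_from_params(means, variances, sizes)
    df1 = m - 1
    df2 = int(sizes.sum()) - m
    p = stats.f.sf(f, df1, df2)
    return BatchTestResult(
        f=f,
        df1=df1,
        df2=df2,
        p=p,
        group_means=means,
        group_variances=variances,
        source_beta=source_beta,
        outlier_mask=mask,
        pooled_mean=pooled,
        group_labels=labels,
        group_sizes=sizes.astype(int),
        method=method,
    )


def classical_f_batch(X: np.ndarray, groups: Sequence) -> BatchTestResult:
    """Classical F-test for every row of a gene x sample matrix."""
    return _batch_test(X, groups, None, "classical")


def hybrid_f_batch(X: np.ndarray, groups: Sequence, config: BetaConfig) -> BatchTestResult:
    """Hybrid F_beta test for every row of a gene x sample matrix."""
    method = "classical" if config.beta == 0 else "hybrid"
    res = _batch_test(X, groups, config, method)
    res.method = "hybrid"
    return res


def kruskal_wallis_batch(X: np.ndarray, groups: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Kruskal-Wallis H statistic and p-value per gene (rank-based baseline)."""
    X = np.asarray(X, dtype=float)
    _, indices = _group_index(groups)
    stats_out = np.empty(X.shape[0])
    pvals = np.empty(X.shape[0])
    for i in range(X.shape[0]):
        h, p = stats.kruskal(*(X[i, idx] for idx in indices))
        stats_out[i] = h
        pvals[i] = p
    return stats_out, pvals


def count_label_splits(sizes: Sequence[int]) -> int:
    """Number of distinct ordered assignments of n items to groups of given sizes."""
    n = sum(sizes)
    count = 1
    for s in sizes:
        count *= math.comb(n, s)
        n -= s
    return count


def _enumerate_assignments(sizes: Sequence[int]):
    """Yield index tuples (per group) covering every distinct assignment."""
    n = sum(sizes)

    def rec(remaining: tuple, sizes_left: Sequence[int]):
        if len(sizes_left) == 1:
            yield (remaining,)
            return
        k = sizes_left[0]
        for chosen in itertools.combinations(remaining, k):
            chosen_set = set(chosen)
            rest = tuple(i for i in remaining if i not in chosen_set)
            for tail in rec(rest, sizes_left[1:]):
                yield (chosen,) + tail

    yield from rec(tuple(range(n)), list(sizes))


def permutation_pvalue(
    record,
    config: BetaConfig,
    n_permutations: int = 1000,
    seed: int | None = None,
    max_exhaustive: int = 10_000,
) -> float:
    """Per-gene permutation p-value of the hybrid F_beta statistic.

    Group labels are permuted over the gene's pooled observations.  When the
    number of distinct assignments is at most ``max_exhaustive`` the full
    enumeration is used and ``p = #{F_perm >= F_obs} / n_splits`` (the
    identity split is included, so ``p >= 1/n_splits``); otherwise
    ``n_permutations`` random relabelings are drawn and the add-one
    estimator ``p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations)``
    is returned.
    """
    groups = _group_arrays(record)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    sizes = [g.size for g in groups]
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        # every relabeling gives the same (degenerate) statistic
        return 1.0
    labels = np.repeat(np.arange(len(sizes)), sizes)
    observed = hybrid_f(groups, config).f_stat
    n_splits = count_label_splits(sizes)
    if n_splits <= max_exhaustive:
        perm_rows = np.empty((n_splits, pooled.size))
        for r, assignment in enumerate(_enumerate_assignments(sizes)):
            order = np.fromiter(itertools.chain.from_iterable(assignment), dtype=int)
            perm_rows[r] = pooled[order]
        batch = hybrid_f_batch(perm_rows, labels, config)
        # observed split is one of the enumerated rows; >= keeps it counted
        return float(np.mean(batch.f >= observed - 1e-12))
    rng = np.random.default_rng(seed)
    perm_rows = np.empty((n_permutations, pooled.size))
    for r in range(n_permutations):
        perm_rows[r] = pooled[rng.permutation(pooled.size)]
    batch = hybrid_f_batch(perm_rows, labels, config)
    exceed = int(np.sum(batch.f >= observed - 1e-12))
    return float((1 + exceed) / (1 + n_permutations))


def adjust_pvalues(pvalues, method: str = "bh") -> np.ndarray:
    """Multiplicity-adjusted p-values (``"bh"`` step-up or ``"bonferroni"``)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError("method must be 'bh' or 'bonferroni'")
    return multipletests(p, method=key)[1]
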