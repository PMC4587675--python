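"""Seeded synthetic expression studies: Gaussian one-way layouts + outliers.

The generator draws gene x sample matrices under the one-way ANOVA model
``x_jk = mu_j + eps``, ``eps ~ N(0, sigma2)``.  Equally expressed (EE) genes
share one mean across conditions, drawn uniformly from ``mean_range``;
differentially expressed (DE) genes follow an expression pattern -- a
partition of the conditions into equal-mean classes -- with one mean per
class and distinct class means kept apart by a minimum separation.
Contamination replaces selected observations by additive outliers
``x* = d + max(gene's clean values)`` with ``d ~ U(d_range)``, so every
injected value strictly exceeds the gene's clean maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SimulationSpec",
    "SyntheticDataset",
    "default_patterns",
    "generate_dataset",
    "inject_outliers",
]


def default_patterns(m: int) -> tuple[tuple[tuple[int, ...], ...], ...]:
    """Default DE patterns per number of conditions (0-based group indices).

    For m = 2 the single pattern mu1 != mu2; for m = 4 the three patterns
    (i) mu1 = mu2 != mu3 = mu4, (ii) mu1 = mu2 != mu3 != mu4 and
    (iii) all four distinct, in equal shares.  Other m default to the
    all-distinct pattern.
    """
    if m == 2:
        return (((0,), (1,)),)
    if m == 4:
        return (
            ((0, 1), (2, 3)),
            ((0, 1), (2,), (3,)),
            ((0,), (1,), (2,), (3,)),
        )
    return (tuple((j,) for j in range(m)),)


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of a synthetic study.

    The defaults reproduce the two-condition small-sample study: 20,000
    genes with 300 DE, group means in (2, 5), sigma2 = 0.05, n_j = 3, and no
    contamination.  ``outliers_per_gene`` is ``None`` for the default rule
    max(1, floor(0.05 n)), an explicit integer, or ``"one_or_two"`` for a
    seeded choice between 1 and 2 per contaminated gene.
    """

    m: int = 2
    sizes: tuple[int, ...] = (3, 3)
    n_genes: int = 20_000
    n_de: int = 300
    mean_range: tuple[float, float] = (2.0, 5.0)
    sigma2: float = 0.05
    patterns: tuple[tuple[tuple[int, ...], ...], ...] | None = None
    pattern_counts: tuple[int, ...] | None = None
    outlier_gene_fraction: float = 0.0
    outliers_per_gene: int | str | None = None
    d_range: tuple[float, float] = (5.0, 10.0)
    min_de_separation: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("need m >= 2 conditions")
        if len(self.sizes) != self.m or any(s < 2 for s in self.sizes):
            raise ValueError("sizes must give n_j >= 2 for each of m groups")
        if not 0 <= self.n_de <= self.n_genes:
            raise ValueError("n_de must lie in [0, n_genes]")
        if not 0.0 <= self.outlier_gene_fraction <= 1.0:
            raise ValueError("outlier_gene_fraction must lie in [0, 1]")
        lo, hi = self.mean_range
        if hi <= lo:
            raise ValueError("mean_range must be increasing")
        if self.min_de_separation is not None:
            if self.min_de_separation < 0:
                raise ValueError("min_de_separation must be >= 0")
            if self.min_de_separation >= hi - lo:
                raise ValueError("min_de_separation must be below the mean-range width")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if isinstance(self.outliers_per_gene, str) and self.outliers_per_gene != "one_or_two":
            raise ValueError("outliers_per_gene must be None, an int, or 'one_or_two'")
        self.resolved_patterns()  # validate patterns/counts up front

    @property
    def n_total(self) -> int:
        return int(sum(self.sizes))

    @property
    def de_separation(self) -> float:
        """Minimum gap between distinct DE class means.

        Defaults (when ``min_de_separation`` is None) are calibrated against
        the clean-data operating characteristics of the two study designs:
        2.5 for two conditions on the (2, 5) range and 0.65 for multi-
        condition patterns on the (3, 5) range.
        """
        if self.min_de_separation is not None:
            return self.min_de_separation
        return 2.5 if self.m == 2 else 0.65

    def resolved_patterns(self) -> tuple[tuple, tuple[int, ...]]:
        """DE patterns and their gene counts (near-equal split by default)."""
        patterns = self.patterns or default_patterns(self.m)
        for pat in patterns:
            flat = sorted(g for block in pat for g in block)
            if flat != list(range(self.m)):
                raise ValueError(f"pattern {pat} is not a partition of 0..{self.m - 1}")
            if len(pat) < 2:
                raise ValueError("a DE pattern needs at least two classes")
        if self.pattern_counts is not None:
            counts = tuple(self.pattern_counts)
            if len(counts) != len(patterns) or sum(counts) != self.n_de:
                raise ValueError("pattern_counts must sum to n_de, one per pattern")
        else:
            k = len(patterns)
            base = self.n_de // k
            counts = tuple(base + (1 if i < self.n_de % k else 0) for i in range(k))
        return patterns, counts


@dataclass
class SyntheticDataset:
    """A generated study: matrix, truth labels, and contamination record."""

    values: np.ndarray  # (G, n)
    gene_ids: list[str]
    sample_ids: list[str]
    group_labels: np.ndarray  # (n,) str
    truth: np.ndarray  # (G,) bool, True = DE
    pattern_truth: list  # per gene: partition tuple for DE genes, None for EE
    outlier_mask: np.ndarray  # (G, n) bool
    group_means: np.ndarray  # (G, m) planted means
    spec: SimulationSpec

    def copy(self) -> "SyntheticDataset":
        return SyntheticDataset(
            values=self.values.copy(),
            gene_ids=list(self.gene_ids),
            sample_ids=list(self.sample_ids),
            group_labels=self.group_labels.copy(),
            truth=self.truth.copy(),
            pattern_truth=list(self.pattern_truth),
            outlier_mask=self.outlier_mask.copy(),
            group_means=self.group_means.copy(),
            spec=self.spec,
        )


def _draw_class_means(
    rng: np.random.Generator, count: int, n_classes: int, spec: SimulationSpec
) -> np.ndarray:
    """Draw (count, n_classes) separated means uniformly within mean_range.

    The nominal separation is shrunk to 0.9 width / (n_classes - 1) when a
    pattern has too many classes for the requested gap to fit inside the
    range (one tenth of the range is kept as random slack).
    """
    lo, hi = spec.mean_range
    width = hi - lo
    sep = 0.0
    if n_classes > 1:
        sep = min(spec.de_separation, 0.9 * width / (n_classes - 1))
    slack = width - (n_classes - 1) * sep
    draws = rng.uniform(lo, lo + slack, size=(count, n_classes))
    draws.sort(axis=1)
    draws += sep * np.arange(n_classes)
    return rng.permuted(draws, axis=1)


def generate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Generate a clean study from a spec (bit-reproducible from its seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])
    G, n, m = spec.n_genes, spec.n_total, spec.m
    patterns, counts = spec.resolved_patterns()
    group_means = np.empty((G, m))
    pattern_truth: list = [None] * G
    truth = np.zeros(G, dtype=bool)

    n_ee = G - spec.n_de
    group_means[:n_ee] = rng.uniform(*spec.mean_range, size=n_ee)[:, None]
    row = n_ee
    for pat, count in zip(patterns, counts):
        class_means = _draw_class_means(rng, count, len(pat), spec)
        for c, block in enumerate(pat):
            for g in block:
                group_means[row : row + count, g] = class_means[:, c]
        for r in range(row, row + count):
            pattern_truth[r] = pat
        truth[row : row + count] = True
        row += count

    order = rng.permutation(G)
    group_means = group_means[order]
    truth = truth[order]
    pattern_truth = [pattern_truth[i] for i in order]

    reps = np.repeat(np.arange(m), spec.sizes)
    noise = rng.normal(0.0, math.sqrt(spec.sigma2), size=(G, n))
    values = group_means[:, reps] + noise

    group_labels = np.array([f"g{j + 1}" for j in reps])
    sample_counter: dict[int, int] = {}
    sample_ids = []
    for j in reps:
        sample_counter[j] = sample_counter.get(j, 0) + 1
        sample_ids.append(f"g{j + 1}_s{sample_counter[j]}")
    gene_ids = [f"gene_{i + 1:05d}" for i in range(G)]

    return SyntheticDataset(
        values=values,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        group_labels=group_labels,
        truth=truth,
        pattern_truth=pattern_truth,
        outlier_mask=np.zeros((G, n), dtype=bool),
        group_means=group_means,
        spec=spec,
    )


def _outliers_per_gene(spec: SimulationSpec, rng: np.random.Generator, count: int) -> np.ndarray:
    rule = spec.outliers_per_gene
    n = spec.n_total
    if rule is None:
        k = max(1, int(math.floor(0.05 * n)))
        return np.full(count, k, dtype=int)
    if rule == "one_or_two":
        return rng.integers(1, 3, size=count)
    k = int(rule)
    if not 1 <= k <= n:
        raise ValueError("outliers_per_gene must lie in [1, n_total]")
    return np.full(count, k, dtype=int)


def inject_outliers(data: SyntheticDataset, spec: SimulationSpec | None = None) -> SyntheticDataset:
    """Contaminate a clean dataset per its spec's outlier plan.

    ceil(outlier_gene_fraction * G) genes are chosen uniformly; in each, the
    per-gene number of positions (default max(1, floor(0.05 n))) is drawn
    uniformly over the samples and replaced by ``d + max(clean values)``
    with ``d ~ U(d_range)``.  The input is not modified.
    """
    spec = spec or data.spec
    out = data.copy()
    if spec.outlier_gene_fraction == 0.0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    G, n = out.values.shape
    n_contaminated = int(math.ceil(spec.outlier_gene_fraction * G))
    genes = rng.choice(G, size=n_contaminated, replace=False)
    k_out = _outliers_per_gene(spec, rng, n_contaminated)
    lo_d, hi_d = spec.d_range
    for gene, k in zip(genes, k_out):
        positions = rng.choice(n, size=int(k), replace=False)
        clean_max = out.values[gene].max()
        out.values[gene, positions] = clean_max + rng.uniform(lo_d, hi_d, size=int(k))
        out.outlier_mask[gene, positions] = True
    return out
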