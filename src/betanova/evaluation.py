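"""Ranking metrics and the benchmark runner over replicate synthetic studies.

Metrics follow the usual DE-benchmark conventions: a gene ranking statistic
(F or F_beta; higher = more differentially expressed) is cut at the top k
(k = true DE count, so FDR and FNR coincide by construction), or at a
p-value threshold, and confusion rates are computed against the planted
truth.  ROC AUC uses the rank (Mann-Whitney) formulation; the partial AUC
is the unnormalized trapezoidal area of the empirical ROC restricted to
FPR <= fpr_max (so a perfect ranking reaches fpr_max, chance reaches
fpr_max^2 / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .estimators import BetaConfig
from .simulate import SimulationSpec, generate_dataset, inject_outliers
from .testing import (
    adjust_pvalues,
    classical_f_batch,
    hybrid_f_batch,
    kruskal_wallis_batch,
)

__all__ = [
    "ConfusionMetrics",
    "PerformanceReport",
    "RocResult",
    "benchmark",
    "roc_auc",
    "score_dataset",
    "top_k_confusion",
    "tpr_at_alpha",
]

METHODS = ("hybrid", "classical_anova", "kw_baseline")


@dataclass(frozen=True)
class ConfusionMetrics:
    tpr: float
    fpr: float
    tnr: float
    fnr: float
    fdr: float
    mer: float


@dataclass(frozen=True)
class RocResult:
    auc: float
    pauc: float
    fpr_max: float


@dataclass
class PerformanceReport:
    """Per-method means and Monte-Carlo standard errors over replicates."""

    summary: pd.DataFrame
    replicates: pd.DataFrame
    reps: int
    seeds: list[int]


def top_k_confusion(scores, truth, k: int) -> ConfusionMetrics:
    """Confusion rates after declaring the top-k ranked genes DE.

    Ties are broken by stable gene order.  TPR = TP/P over the true-DE set,
    FPR = FP/N over the true-EE set, FDR = FP/k, MER = (FP + FN)/G.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must align")
    G = scores.size
    if not 0 < k <= G:
        raise ValueError("k must lie in [1, G]")
    order = np.argsort(-scores, kind="stable")
    declared = np.zeros(G, dtype=bool)
    declared[order[:k]] = True
    P = int(truth.sum())
    N = G - P
    if P == 0 or N == 0:
        raise ValueError("both DE and EE genes must be present")
    tp = int(np.sum(declared & truth))
    fp = k - tp
    fn = P - tp
    return ConfusionMetrics(
        tpr=tp / P,
        fpr=fp / N,
        tnr=1.0 - fp / N,
        fnr=fn / P,
        fdr=fp / k,
        mer=(fp + fn) / G,
    )


def roc_auc(scores, truth, fpr_max: float = 0.2) -> RocResult:
    """Full-ranking AUC and unnormalized partial AUC at FPR <= fpr_max."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if truth.all() or not truth.any():
        raise ValueError("both classes must be present")
    if not 0.0 < fpr_max <= 1.0:
        raise ValueError("fpr_max must lie in (0, 1]")
    auc = float(roc_auc_score(truth, scores))
    fpr, tpr, _ = roc_curve(truth, scores)
    # close the ROC at fpr_max by linear interpolation, then integrate
    tpr_at_max = float(np.interp(fpr_max, fpr, tpr))
    keep = fpr < fpr_max
    grid = np.append(fpr[keep], fpr_max)
    height = np.append(tpr[keep], tpr_at_max)
    pauc = float(np.trapezoid(height, grid))
    return RocResult(auc=auc, pauc=pauc, fpr_max=fpr_max)


def tpr_at_alpha(
    pvalues, truth, alpha: float, adjust: str = "none"
) -> tuple[float, float]:
    """(TPR, FPR) after declaring DE at (optionally adjusted) p <= alpha."""
    p = np.asarray(pvalues, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if adjust != "none":
        p = adjust_pvalues(p, adjust)
    declared = p <= alpha
    P = int(truth.sum())
    N = truth.size - P
    if P == 0 or N == 0:
        raise ValueError("both DE and EE genes must be present")
    tpr = float(np.sum(declared & truth) / P)
    fpr = float(np.sum(declared & ~truth) / N)
    return tpr, fpr


def score_dataset(
    values: np.ndarray,
    group_labels: Sequence,
    method: str,
    config: BetaConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(scores, pvalues) for every gene under one scoring method."""
    if method == "hybrid":
        res = hybrid_f_batch(values, group_labels, config or BetaConfig())
        return res.f, res.p
    if method == "classical_anova":
        res = classical_f_batch(values, group_labels)
        return res.f, res.p
    if method == "kw_baseline":
        return kruskal_wallis_batch(values, group_labels)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def benchmark(
    spec: SimulationSpec,
    methods: Sequence[str] = ("hybrid", "classical_anova"),
    reps: int = 10,
    seed: int = 0,
    config: BetaConfig | None = None,
    fpr_max: float = 0.2,
    alpha: float | None = None,
    adjustments: Sequence[str] = ("none", "bh", "bonferroni"),
) -> PerformanceReport:
    """Average ranking metrics for each method over seeded replicate studies.

    Every replicate regenerates (and, if the spec asks, contaminates) a
    dataset with its own derived seed, scores all genes with each method,
    and computes top-k confusion (k = true DE count), AUC and pAUC; when
    ``alpha`` is given, threshold TPR/FPR at raw and adjusted p-values are
    added.  Each summary cell is the mean of per-dataset values with its
    Monte-Carlo standard error alongside.
    """
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
    config = config or BetaConfig()
    rng = np.random.default_rng(seed)
    rep_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=reps)]
    rows = []
    for rep, rep_seed in enumerate(rep_seeds):
        rep_spec = dc_replace(spec, seed=rep_seed)
        data = generate_dataset(rep_spec)
        if rep_spec.outlier_gene_fraction > 0:
            data = inject_outliers(data, rep_spec)
        k = int(data.truth.sum())
        for method in methods:
            scores, pvals = score_dataset(data.values, data.group_labels, method, config)
            cm = top_k_confusion(scores, data.truth, k)
            roc = roc_auc(scores, data.truth, fpr_max)
            row = {
                "rep": rep,
                "seed": rep_seed,
                "method": method,
                "tpr": cm.tpr,
                "fpr": cm.fpr,
                "tnr": cm.tnr,
                "fnr": cm.fnr,
                "fdr": cm.fdr,
                "mer": cm.mer,
                "auc": roc.auc,
                "pauc": roc.pauc,
            }
            if alpha is not None:
                for adj in adjustments:
                    tpr, fpr = tpr_at_alpha(pvals, data.truth, alpha, adj)
                    row[f"tpr_alpha_{adj}"] = tpr
                    row[f"fpr_alpha_{adj}"] = fpr
            rows.append(row)
    replicates = pd.DataFrame(rows)
    metric_cols = [c for c in replicates.columns if c not in ("rep", "seed", "method")]
    grouped = replicates.groupby("method", sort=False)[metric_cols]
    means = grouped.mean()
    ses = grouped.std(ddof=1) / np.sqrt(reps) if reps > 1 else grouped.mean() * 0.0
    summary = means.join(ses, rsuffix="_se")
    return PerformanceReport(summary=summary, replicates=replicates, reps=reps, seeds=rep_seeds)
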