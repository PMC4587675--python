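"""Expression-matrix I/O, validation, and the high-level analysis entry points.

Input is a rectangular TSV/CSV table (first column gene identifiers, header
row sample identifiers, log-scale intensities) plus a sample -> condition
mapping given inline or as a two-column sidecar file.  Values are assumed
already normalised / log-transformed; missing values are rejected, not
imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .estimators import BetaConfig
from .pairwise import assign_pattern, pairwise_test
from .testing import (
    adjust_pvalues,
    classical_f_batch,
    hybrid_f_batch,
    moderated_scale,
    permutation_pvalue,
)

__all__ = [
    "ExpressionMatrix",
    "ValidationError",
    "read_expression",
    "read_group_map",
    "run_pairwise",
    "run_test",
    "weight_report",
    "write_table",
]

logger = logging.getLogger("betanova")


class ValidationError(ValueError):
    """Input data failed validation (malformed table, bad group map, ...)."""


@dataclass
class ExpressionMatrix:
    """A validated gene x sample matrix with a condition factor."""

    values: pd.DataFrame  # genes x samples
    groups: pd.Series  # sample_id -> condition label

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dups[:5])}")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample ids")
        if self.values.isna().any().any():
            na = self.values.isna()
            n_missing = int(na.to_numpy().sum())
            gene = na.any(axis=1).idxmax()
            sample = na.loc[gene].idxmax()
            raise ValidationError(
                f"{n_missing} missing value(s); first at gene {gene!r}, "
                f"sample {sample!r} (imputation is out of scope)"
            )
        unknown = set(self.groups.index) - set(self.values.columns)
        if unknown:
            raise ValidationError(f"group map names unknown samples: {sorted(unknown)[:5]}")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValidationError(f"samples without a group: {sorted(missing)[:5]}")
        self.groups = self.groups.loc[self.values.columns]
        counts = self.groups.value_counts()
        if (counts < 2).any():
            small = counts[counts < 2].index.tolist()
            raise ValidationError(f"groups with fewer than 2 samples: {small}")
        if len(counts) < 2:
            raise ValidationError("need at least two conditions")

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    @property
    def group_labels(self) -> np.ndarray:
        return self.groups.to_numpy()


def read_group_map(source) -> pd.Series:
    """Sample -> condition mapping from a dict or a two-column TSV/CSV file."""
    if isinstance(source, Mapping):
        return pd.Series(source)
    if isinstance(source, pd.Series):
        return source
    path = Path(source)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if frame.shape[1] < 2:
        raise ValidationError("group file needs columns: sample, group")
    return pd.Series(frame.iloc[:, 1].to_numpy(), index=frame.iloc[:, 0].to_numpy())


def read_expression(path, groups, fmt: str | None = None) -> ExpressionMatrix:
    """Load and validate an expression table with its group assignment."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    sep = "," if fmt == "csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0)
    except (pd.errors.ParserError, OSError) as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc
    non_numeric = [
        c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)
    ]
    if non_numeric:
        raise ValidationError(f"non-numeric expression columns: {non_numeric[:5]}")
    return ExpressionMatrix(values=frame.astype(float), groups=read_group_map(groups))


def write_table(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Write a result table as TSV with a stable header."""
    frame.to_csv(path, sep="\t", index=index, float_format="%.6g")


def _result_frames(matrix: ExpressionMatrix, res, adjust: str):
    labels = res.group_labels
    table = pd.DataFrame({"gene_id": matrix.gene_ids})
    table["f_stat"] = res.f
    table["df1"] = res.df1
    table["df2"] = res.df2
    table["p_value"] = res.p
    table["p_adjusted"] = adjust_pvalues(res.p, adjust)
    table["n_outliers"] = res.outlier_mask.sum(axis=1)
    for j, lab in enumerate(labels):
        table[f"mean_{lab}"] = res.group_means[:, j]
        table[f"var_{lab}"] = res.group_variances[:, j]
        table[f"source_{lab}"] = np.where(res.source_beta[:, j], "beta", "mle")
    return table


def _outlier_frame(matrix: ExpressionMatrix, res, config: BetaConfig) -> pd.DataFrame:
    from .estimators import predicted_weight_quantile

    rows = []
    if config.beta > 0:
        delta = predicted_weight_quantile(config.beta, config.tail_prob)
        gene_idx, sample_idx = np.nonzero(res.outlier_mask)
        X = matrix.matrix
        for g, s in zip(gene_idx, sample_idx):
            lab = matrix.group_labels[s]
            j = res.group_labels.index(lab)
            mu = res.group_means[g, j]
            var = res.group_variances[g, j]
            w = float(np.exp(-config.beta * (X[g, s] - mu) ** 2 / (2 * var)))
            rows.append(
                {
                    "gene_id": matrix.gene_ids[g],
                    "sample_id": matrix.sample_ids[s],
                    "value": X[g, s],
                    "weight": w,
                    "delta": delta,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "value", "weight", "delta"])


def run_test(
    matrix: ExpressionMatrix,
    config: BetaConfig | None = None,
    method: str = "hybrid",
    adjust: str = "bh",
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Omnibus test per gene; returns (result table, outlier report).

    ``method`` is "hybrid", "classical" or "permutation" (hybrid statistic
    with per-gene permutation p-values).
    """
    config = config or BetaConfig()
    X = matrix.matrix
    labels = matrix.group_labels
    if method == "classical":
        res = classical_f_batch(X, labels)
    elif method in ("hybrid", "permutation"):
        res = hybrid_f_batch(X, labels, config)
    else:
        raise ValidationError(f"unknown test method {method!r}")
    if method == "permutation":
        _, indices = _split_indices(labels, res.group_labels)
        perm = np.empty(X.shape[0])
        for i in range(X.shape[0]):
            record = [X[i, idx] for idx in indices]
            perm[i] = permutation_pvalue(
                record, config, n_permutations=n_permutations, seed=seed + i
            )
        res.p = perm
    table = _result_frames(matrix, res, adjust)
    report = _outlier_frame(matrix, res, config)
    logger.info(
        "tested %d genes (m=%d, n=%d): beta=%g tail_prob=%g seed=%d; "
        "%d genes on the robust path, %d flagged observations",
        X.shape[0],
        len(res.group_labels),
        X.shape[1],
        config.beta,
        config.tail_prob,
        seed,
        int(res.source_beta.any(axis=1).sum()),
        int(res.outlier_mask.sum()),
    )
    return table, report


def _split_indices(sample_labels: np.ndarray, group_order: Sequence):
    indices = [np.flatnonzero(sample_labels == lab) for lab in group_order]
    return list(group_order), indices


def run_pairwise(
    matrix: ExpressionMatrix,
    config: BetaConfig | None = None,
    alpha: float = 0.05,
    adjust: str = "bh",
    fold_threshold: float = 1.0,
    fold_scale: str = "ratio",
    expand_all: bool = False,
    omnibus_alpha: float | None = None,
) -> pd.DataFrame:
    """Robust LSD pairwise table, one row per (gene, pair).

    By default only genes whose omnibus F_beta is significant at
    ``omnibus_alpha`` (defaults to ``alpha``) are expanded; ``expand_all``
    lifts that gate.  Pair p-values are adjusted within each gene's
    m(m-1)/2 family.
    """
    config = config or BetaConfig()
    omnibus_alpha = alpha if omnibus_alpha is None else omnibus_alpha
    X = matrix.matrix
    labels = matrix.group_labels
    res = hybrid_f_batch(X, labels, config)
    _, indices = _split_indices(labels, res.group_labels)
    scales = moderated_scale(X, indices, config.variance_floor)
    m = len(res.group_labels)
    rows = []
    for i in range(X.shape[0]):
        if not expand_all and res.p[i] > omnibus_alpha:
            continue
        record = [X[i, idx] for idx in indices]
        results = pairwise_test(
            record,
            config,
            alpha=alpha,
            labels=res.group_labels,
            fold_threshold=fold_threshold,
            fold_scale=fold_scale,
            adjust=adjust,
            init_scale=float(scales[i]),
        )
        pattern = assign_pattern(results, m, labels=res.group_labels)
        for r in results:
            rows.append(
                {
                    "gene_id": matrix.gene_ids[i],
                    "pair": f"{r.pair[0]}:{r.pair[1]}",
                    "mean_diff": r.mean_diff,
                    "lsd": r.lsd,
                    "significant": r.significant,
                    "p_value": r.p_value,
                    "p_adjusted": r.p_adjusted,
                    "direction": r.direction,
                    "pattern": str(pattern),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "pair",
            "mean_diff",
            "lsd",
            "significant",
            "p_value",
            "p_adjusted",
            "direction",
            "pattern",
        ],
    )


def weight_report(matrix: ExpressionMatrix, config: BetaConfig | None = None) -> pd.DataFrame:
    """Beta-weight of every observation plus its outlier flag."""
    from .estimators import hybrid_estimate_batch, predicted_weight_quantile

    config = config or BetaConfig()
    if config.beta == 0:
        raise ValidationError("weight report needs beta > 0")
    X = matrix.matrix
    labels = matrix.group_labels
    delta = predicted_weight_quantile(config.beta, config.tail_prob)
    group_order = list(dict.fromkeys(labels))
    weights = np.empty_like(X)
    flags = np.zeros(X.shape, dtype=bool)
    from .estimators import beta_estimate_batch

    indices = [np.flatnonzero(labels == lab) for lab in group_order]
    init_scale = moderated_scale(X, indices, config.variance_floor)
    for lab, idx in zip(group_order, indices):
        sub = X[:, idx]
        mu, var, _, _, _ = beta_estimate_batch(sub, config, init_scale)
        w = np.exp(-config.beta * (sub - mu[:, None]) ** 2 / (2 * var[:, None]))
        weights[:, idx] = w
        flags[:, idx] = w <= delta
    frame = pd.DataFrame(weights, index=matrix.gene_ids, columns=matrix.sample_ids)
    long = frame.reset_index(names="gene_id").melt(
        id_vars="gene_id", var_name="sample_id", value_name="weight"
    )
    flag_frame = pd.DataFrame(flags, index=matrix.gene_ids, columns=matrix.sample_ids)
    long["outlier"] = flag_frame.reset_index(names="gene_id").melt(
        id_vars="gene_id", var_name="sample_id", value_name="flag"
    )["flag"]
    long["delta"] = delta
    return long
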