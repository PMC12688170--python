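"""Clustering feature space: top-MAD transcripts plus recurrently mutated genes.

Variability is the unscaled median absolute deviation of log2(TPM+1);
mutation prevalence counts a gene once per sample against the full cohort
denominator and keeps genes strictly above the rate threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import CohortError, ExpressionMatrix, MutationTable

logger = logging.getLogger("leukotype")


@dataclass
class FeatureSet:
    """Selected features with per-feature provenance scores.

    ``expression_genes`` maps gene class → ordered gene list; ``scores``
    holds the MAD (expression) or prevalence (mutation) behind each pick.
    """

    expression_genes: dict[str, list[str]] = field(default_factory=dict)
    mutation_genes: list[str] = field(default_factory=list)
    scores: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    mutation_indicator: pd.DataFrame | None = None

    def all_expression_genes(self) -> list[str]:
        return [g for genes in self.expression_genes.values() for g in genes]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls, genes in self.expression_genes.items():
            for g in genes:
                rows.append((g, f"expression:{cls}", self.scores.get(g, np.nan)))
        for g in self.mutation_genes:
            rows.append((g, "mutation", self.scores.get(g, np.nan)))
        return pd.DataFrame(rows, columns=["feature", "layer", "score"])


@dataclass
class FeatureMatrix:
    """Sample × feature blocks consumed by the clustering ensemble."""

    continuous: pd.DataFrame  # samples × genes, log2(TPM+1)
    binary: pd.DataFrame | None = None  # samples × genes, 0/1

    @property
    def sample_ids(self) -> list[str]:
        return list(self.continuous.index)


def median_absolute_deviation(values) -> float:
    """Unscaled MAD: median(|x − median(x)|)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise CohortError("MAD of an empty vector is undefined")
    if not np.isfinite(arr).all():
        raise CohortError("MAD requires finite values")
    return float(np.median(np.abs(arr - np.median(arr))))


def drop_flat_features(matrix: pd.DataFrame) -> pd.DataFrame:
    """Remove zero-variance rows; error if nothing would remain."""
    var = matrix.var(axis=1, ddof=0)
    keep = var > 0
    n_drop = int((~keep).sum())
    if keep.sum() == 0:
        raise CohortError("all features are flat")
    if n_drop:
        logger.info("drop_flat_features: removed %d flat rows", n_drop)
    return matrix[keep]


def select_top_mad(
    expr: ExpressionMatrix,
    n_per_class: int = 1000,
    classes: tuple[str, ...] = ("mRNA", "lncRNA"),
    combined_pool: bool = False,
) -> FeatureSet:
    """Top-``n_per_class`` genes per class by MAD of log2(TPM+1).

    Ties at the cutoff break lexicographically by gene id. With
    ``combined_pool=True`` a single pool across the requested classes is
    ranked instead and ``n_per_class`` caps the pooled list.
    """
    if n_per_class < 1:
        raise CohortError("n_per_class must be >= 1")
    log_expr = expr.log2().values
    log_expr = drop_flat_features(log_expr)
    mad = log_expr.apply(
        lambda row: np.median(np.abs(row - np.median(row))), axis=1
    )
    available = set(expr.gene_class.unique())
    for cls in classes:
        if cls not in available:
            raise CohortError(f"gene class {cls!r} absent from annotation")
    fs = FeatureSet(scores=mad)

    def _take(pool: pd.Index, n: int, label: str) -> list[str]:
        ranked = sorted(pool, key=lambda g: (-mad[g], g))
        if len(ranked) < n:
            warnings.warn(
                f"only {len(ranked)} {label} features available (requested {n})",
                stacklevel=3,
            )
        return ranked[:n]

    if combined_pool:
        pool = log_expr.index[expr.gene_class[log_expr.index].isin(classes)]
        fs.expression_genes["combined"] = _take(pool, n_per_class, "combined")
    else:
        for cls in classes:
            pool = log_expr.index[expr.gene_class[log_expr.index] == cls]
            fs.expression_genes[cls] = _take(pool, n_per_class, cls)
    return fs


def filter_mutation_prevalence(
    mut: MutationTable,
    samples,
    min_rate: float = 0.03,
) -> FeatureSet:
    """Genes mutated in strictly more than ``min_rate`` of ``samples``.

    The denominator is the full supplied sample universe, mutated or not.
    Also emits the binary gene × sample indicator over that universe.
    """
    samples = list(samples)
    if not samples:
        raise CohortError("empty sample universe")
    indicator = mut.genes_by_sample()
    indicator = indicator.reindex(columns=samples, fill_value=0)
    if indicator.empty:
        indicator = pd.DataFrame(
            np.zeros((0, len(samples)), dtype=int), columns=samples
        )
    prevalence = indicator.sum(axis=1) / len(samples)
    keep = prevalence[prevalence > min_rate]
    genes = sorted(keep.index)
    return FeatureSet(
        mutation_genes=genes,
        scores=prevalence.loc[genes] if genes else pd.Series(dtype=float),
        mutation_indicator=indicator.loc[genes],
    )


def build_feature_matrix(
    expr: ExpressionMatrix,
    expr_features: FeatureSet,
    mut_features: FeatureSet | None = None,
) -> FeatureMatrix:
    """Assemble the sample × feature blocks for the clustering ensemble."""
    genes = expr_features.all_expression_genes()
    continuous = expr.log2().values.loc[genes].T
    binary = None
    if mut_features is not None and mut_features.mutation_genes:
        binary = mut_features.mutation_indicator.T.reindex(
            continuous.index, fill_value=0
        )
    return FeatureMatrix(continuous=continuous, binary=binary)
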