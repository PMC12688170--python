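"""Tumor-microenvironment characterization from bulk expression.

Three scorers, all per sample:

* population abundance — arithmetic mean of log2(TPM+1) over a cell
  population's marker genes (eight immune and two stromal populations by
  default);
* functional orientation — geometric mean of TPM+1 over a small literature
  signature (immunosuppression, T-cell activation/survival, Tregs, MHC-I,
  myeloid chemotaxis, TLS) plus four suppression programs (TITR, MDSC,
  C-ECM, Wnt/TGF-β);
* rank-based single-sample enrichment — a weighted in-set vs out-set ECDF
  difference summed along the within-sample expression ranking, used for
  the immune (IES) and stromal (SES) enrichment scores.

Default marker/orientation lists ship as editable GMT data files; any
:class:`~leukotype.core_io.GeneSetCollection` can replace them.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .core_io import CohortError, ExpressionMatrix, GeneSetCollection, read_gmt

ORIENTATION_SETS = {
    "immunosuppression": ["CXCL12", "TGFB1", "TGFB3", "LGALS1"],
    "t_cell_activation": ["CXCL9", "CXCL10", "CXCL16", "IFNG", "IL15"],
    "t_cell_survival": ["CD70", "CD27"],
    "tregs": ["FOXP3", "TNFRSF18"],
    "mhc_class_i": ["HLA-A", "HLA-B", "HLA-C", "HLA-E", "HLA-F", "HLA-G", "B2M"],
    "myeloid_chemotaxis": ["CCL2"],
    "tls": ["CXCL13"],
}


def default_orientation_sets() -> GeneSetCollection:
    """The seven functional-orientation signatures (literature gene lists)."""
    return GeneSetCollection(
        {name: ("orientation", list(genes)) for name, genes in ORIENTATION_SETS.items()}
    )


def _load_data_gmt(name: str) -> GeneSetCollection:
    with resources.as_file(
        resources.files("leukotype").joinpath("data", name)
    ) as path:
        return read_gmt(path)


def default_population_markers() -> GeneSetCollection:
    """Editable default marker sets for the 8+2 TME populations."""
    return _load_data_gmt("tme_population_markers.gmt")


def default_suppression_sets() -> GeneSetCollection:
    """TITR / MDSC / C-ECM / Wnt-TGFβ suppression program defaults."""
    return _load_data_gmt("tme_suppression_sets.gmt")


def population_abundance(
    expr: ExpressionMatrix, marker_sets: GeneSetCollection
) -> pd.DataFrame:
    """Mean log2(TPM+1) over each marker set's measured genes, per sample."""
    log_expr = expr.log2().values
    scores = {}
    for name, _, genes in marker_sets.items():
        measured = [g for g in genes if g in log_expr.index]
        if not measured:
            raise CohortError(f"marker set {name!r} has no measured gene")
        scores[name] = log_expr.loc[measured].mean(axis=0)
    return pd.DataFrame(scores)


def orientation_score(expr: ExpressionMatrix, genes) -> pd.Series:
    """Geometric mean of TPM+1 over the set's measured genes.

    The +1 pseudocount makes all-zero profiles score exactly 1 and keeps the
    score equivariant under a common scaling of TPM+1.
    """
    if expr.log_transformed:
        tpm = np.exp2(expr.values) - 1.0
    else:
        tpm = expr.values
    measured = [g for g in genes if g in tpm.index]
    if not measured:
        raise CohortError("orientation set has no measured gene")
    return np.exp(np.log(tpm.loc[measured] + 1.0).mean(axis=0))


def orientation_profile(
    expr: ExpressionMatrix, collections: GeneSetCollection
) -> pd.DataFrame:
    return pd.DataFrame(
        {name: orientation_score(expr, genes) for name, _, genes in collections.items()}
    )


def ssgsea_score(
    expr_sample: pd.Series, gene_set, alpha: float = 0.25
) -> float:
    """Rank-weighted single-sample enrichment of ``gene_set``.

    Genes are ranked by descending expression (rank value N for the highest);
    the score is the mean over ranking positions of the difference between
    the rank^alpha-weighted in-set ECDF and the unweighted out-set ECDF.
    Positive when the set concentrates at the top of the sample's ranking;
    invariant under any strictly monotone transform of expression.
    """
    x = expr_sample.to_numpy(float)
    n = len(x)
    genes = expr_sample.index.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    m = int(in_set.sum())
    if m < 2:
        raise CohortError("gene set needs >= 2 measured genes")
    if m >= n:
        raise CohortError("gene set must be a strict subset of the universe")
    order = np.argsort(-x, kind="stable")
    hit = in_set[order]
    rank_values = np.arange(n, 0, -1, dtype=float)  # N .. 1 down the ranking
    w = rank_values**alpha * hit
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~hit) / (n - m)
    # center by the uniform-placement baseline (set-independent, so a
    # randomly placed set scores ~0 while orderings are untouched)
    w_all = np.cumsum(rank_values**alpha)
    baseline = w_all / w_all[-1] - np.arange(1, n + 1) / n
    return float(np.sum(p_in - p_out - baseline) / n)


def enrichment_scores(
    expr: ExpressionMatrix,
    immune_set,
    stromal_set,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """IES and SES per sample (single-sample enrichment of the two sets)."""
    log_expr = expr.log2().values
    rows = {}
    for sample in log_expr.columns:
        col = log_expr[sample]
        rows[sample] = {
            "IES": ssgsea_score(col, immune_set, alpha),
            "SES": ssgsea_score(col, stromal_set, alpha),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def tme_profile(
    expr: ExpressionMatrix,
    population_markers: GeneSetCollection | None = None,
    orientation_sets: GeneSetCollection | None = None,
    suppression_sets: GeneSetCollection | None = None,
    immune_set=None,
    stromal_set=None,
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Full per-sample TME profile: abundances, orientations, suppression
    programs and (when immune/stromal sets are given or derivable) IES/SES."""
    population_markers = population_markers or default_population_markers()
    orientation_sets = orientation_sets or default_orientation_sets()
    suppression_sets = suppression_sets or default_suppression_sets()
    measured_genes = set(expr.values.index)
    parts = [population_abundance(expr, population_markers)]
    for coll in (orientation_sets, suppression_sets):
        usable = {
            n: (d, g) for n, d, g in coll.items() if set(g) & measured_genes
        }
        if usable:
            parts.append(orientation_profile(expr, GeneSetCollection(usable)))
    if immune_set is None:
        immune_set = [
            g
            for name, _, genes in population_markers.items()
            if name not in ("endothelial_cells", "fibroblasts")
            for g in genes
        ]
    if stromal_set is None:
        stromal_set = [
            g
            for name, _, genes in population_markers.items()
            if name in ("endothelial_cells", "fibroblasts")
            for g in genes
        ]
    measured = set(expr.values.index)
    if len(set(immune_set) & measured) >= 2 and len(set(stromal_set) & measured) >= 2:
        parts.append(
            enrichment_scores(
                expr,
                [g for g in immune_set if g in measured],
                [g for g in stromal_set if g in measured],
                alpha,
            )
        )
    return pd.concat(parts, axis=1)
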