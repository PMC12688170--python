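"""Nearest-template prediction of subtypes from a marker signature.

Each subtype contributes a binary template over the disjoint union of
marker genes; a sample's log2(TPM+1) profile, restricted to that universe
and standardized within-sample, is assigned to the template with the
smallest cosine distance. Significance comes from a resampled null of
random gene sets of matching sizes, with BH adjustment across samples.
Within-sample standardization makes the call invariant to any positive
affine rescaling of a sample's profile, which attenuates cross-platform
batch effects without cohort-level correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import CohortError, ExpressionMatrix
from .subtype_signatures import SignatureSet, bh_adjust


@dataclass
class TemplateMatrix:
    """Binary subtype templates over the union of signature genes."""

    genes: list[str]
    templates: pd.DataFrame  # genes × subtypes, 0/1

    def __post_init__(self) -> None:
        if self.templates.shape[1] < 2:
            raise CohortError("nearest-template prediction needs >= 2 templates")
        sums = self.templates.sum(axis=0)
        if (sums == 0).any():
            raise CohortError("every template needs at least one marker")
        if (self.templates.sum(axis=1) != 1).any():
            raise CohortError("marker lists must be pairwise disjoint")

    @property
    def subtypes(self) -> list[int]:
        return list(self.templates.columns)


def build_templates(signature: SignatureSet) -> TemplateMatrix:
    """Binary templates: 1 on a subtype's own markers, 0 elsewhere."""
    genes = signature.all_genes()
    templates = pd.DataFrame(
        0, index=pd.Index(genes, name="gene"), columns=sorted(signature.markers)
    )
    for subtype in signature.markers:
        templates.loc[signature.genes(subtype), subtype] = 1
    return TemplateMatrix(genes, templates)


def _cosine_distance(profiles: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """1 − cosine similarity between row profiles and template columns.

    Templates are mean-centered first; with the profiles already centered
    within-sample, cosine then coincides with Pearson correlation, so a
    sample whose standardized profile equals a template's standardized
    pattern sits at distance exactly 0.
    """
    t = templates - templates.mean(axis=0, keepdims=True)
    pn = np.linalg.norm(profiles, axis=1, keepdims=True)
    tn = np.linalg.norm(t, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = (profiles @ t) / (pn * tn)
    return 1.0 - cos


def ntp_classify(
    expr: ExpressionMatrix,
    templates: TemplateMatrix,
    n_null: int = 1000,
    seed: int = 0,
    fdr_max: float = 0.05,
    min_coverage: float = 0.8,
) -> pd.DataFrame:
    """Classify every sample by nearest template.

    Expression is taken to log2(TPM+1) internally. Missing template genes
    are dropped from all templates symmetrically provided coverage stays at
    ``min_coverage`` or above. Returns a per-sample DataFrame with the
    predicted subtype, the distance to each template, the resampling p, BH
    adjusted p and a ``confident`` flag; unclassifiable (zero-variance)
    profiles carry subtype 0 and NaN distances.
    """
    log_expr = expr.log2().values
    measured = [g for g in templates.genes if g in log_expr.index]
    coverage = len(measured) / len(templates.genes)
    if coverage < min_coverage:
        missing = [g for g in templates.genes if g not in log_expr.index]
        raise CohortError(
            f"template coverage {coverage:.2f} < {min_coverage}; "
            f"missing genes include {missing[:10]}"
        )
    T = templates.templates.loc[measured].to_numpy(float)
    sizes = T.sum(axis=0).astype(int)
    if (sizes == 0).any():
        raise CohortError("a template lost all its markers to missing genes")
    X = log_expr.loc[measured].to_numpy(float).T  # samples × genes
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    ok = sd[:, 0] > 0
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    D = _cosine_distance(Z, T)

    # null: distances of random gene sets of each template's size, drawn
    # from all measured genes in the full expression matrix
    rng = np.random.default_rng(seed)
    n_genes_total = log_expr.shape[0]
    full = log_expr.to_numpy(float).T
    full_mu = full.mean(axis=1, keepdims=True)
    full_sd = full.std(axis=1, ddof=0, keepdims=True)
    Zfull = np.where(full_sd > 0, (full - full_mu) / np.where(full_sd > 0, full_sd, 1.0), 0.0)

    pred_idx = np.nanargmin(np.where(np.isfinite(D), D, np.inf), axis=1)
    obs = D[np.arange(len(D)), pred_idx]
    null_counts = np.zeros(len(D))
    pred_sizes = sizes[pred_idx]
    uniq_sizes = np.unique(pred_sizes)
    null_by_size: dict[int, np.ndarray] = {}
    norms = np.linalg.norm(Zfull, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    for size in uniq_sizes:
        # centered binary template of this size: since each row of Zfull sums
        # to 0, its inner product with the centered template is just the sum
        # over the drawn genes, and the template norm is sqrt(s(1-s/N))
        t_norm = np.sqrt(size * (1.0 - size / n_genes_total))
        null_d = np.empty((len(D), n_null))
        for b in range(n_null):
            cols = rng.choice(n_genes_total, size=size, replace=False)
            sim = Zfull[:, cols].sum(axis=1) / (norms * t_norm)
            null_d[:, b] = 1.0 - sim
        null_by_size[int(size)] = null_d
    p = np.ones(len(D))
    for i in range(len(D)):
        null_d = null_by_size[int(pred_sizes[i])][i]
        p[i] = (1.0 + (null_d <= obs[i]).sum()) / (1.0 + n_null)
    adj = bh_adjust(p)

    subtype_ids = np.asarray(templates.subtypes)
    result = pd.DataFrame(index=pd.Index(expr.sample_ids, name="sample_id"))
    result["subtype"] = np.where(ok, subtype_ids[pred_idx], 0)
    for j, c in enumerate(templates.subtypes):
        result[f"dist_{c}"] = np.where(ok, D[:, j], np.nan)
    result["p"] = np.where(ok, p, np.nan)
    result["adj_p"] = np.where(ok, adj, np.nan)
    result["confident"] = ok & (adj < fdr_max)
    return result
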