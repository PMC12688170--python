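"""SBS-96 mutation catalogs and per-sample signature exposure fitting.

Single-base substitutions are tallied into the 96 canonical categories
(six pyrimidine-centered substitution classes × 16 flanking-base contexts;
purine-centered records are reverse-complemented first). Counts can be
reweighted from exome to genome trinucleotide frequencies before fitting.
Exposures are obtained by nonnegative least squares against a signature
catalog, iteratively dropping signatures below a minimum weight and
refitting until stable — the convention of reference-signature refitting
tools. The residual is 1 − cosine similarity between the reconstructed and
observed spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .core_io import CohortError, MutationTable

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical SBS-96 category order: substitution class, then 5' flank, then 3'.
SBS96_CATEGORIES = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in "ACGT"
    for three in "ACGT"
)

#: The 32 pyrimidine-centered trinucleotides (context universe for ratios).
PYRIMIDINE_TRINUCLEOTIDES = tuple(
    f"{five}{mid}{three}" for mid in "CT" for five in "ACGT" for three in "ACGT"
)


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_sbs96(
    mut: MutationTable,
    effects: tuple[str, ...] = ("nonsense", "missense", "silent"),
) -> pd.DataFrame:
    """Per-sample SBS-96 count vectors (samples × 96 categories).

    Non-SNV records (multi-base ref/alt, indel symbols) and excluded effect
    classes are dropped; purine references are strand-flipped to the
    pyrimidine frame.
    """
    counts: dict[str, np.ndarray] = {}
    cat_index = {c: i for i, c in enumerate(SBS96_CATEGORIES)}
    for idx, rec in mut.records.iterrows():
        ref, alt = str(rec["ref"]).upper(), str(rec["alt"]).upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGT" or alt not in "ACGT":
            continue  # not a single-base substitution
        if rec["effect"] not in effects:
            continue
        context = str(rec["context"]).upper()
        if len(context) != 3 or any(b not in "ACGT" for b in context):
            raise CohortError(f"malformed trinucleotide context at record {idx}")
        if context[1] != ref:
            raise CohortError(
                f"context middle base != ref at record {idx} "
                f"({context!r} vs {ref!r})"
            )
        if ref in "AG":
            context = _revcomp(context)
            ref = context[1]
            alt = alt.translate(_COMPLEMENT)
        category = f"{context[0]}[{ref}>{alt}]{context[2]}"
        sample = rec["sample_id"]
        if sample not in counts:
            counts[sample] = np.zeros(96, dtype=int)
        counts[sample][cat_index[category]] += 1
    return pd.DataFrame.from_dict(
        counts, orient="index", columns=list(SBS96_CATEGORIES)
    ).rename_axis("sample_id")


def _category_context(category: str) -> str:
    return category[0] + category[2] + category[6]


def normalize_exome2genome(vector: pd.Series, tri_ratio: pd.Series) -> pd.Series:
    """Reweight a 96-category vector by per-context genome/exome ratios."""
    missing = [
        c for c in PYRIMIDINE_TRINUCLEOTIDES if c not in tri_ratio.index
    ]
    if missing:
        raise CohortError(f"missing trinucleotide ratios: {missing[:5]}")
    if (tri_ratio.loc[list(PYRIMIDINE_TRINUCLEOTIDES)] <= 0).any():
        raise CohortError("trinucleotide ratios must be positive")
    out = vector.copy().astype(float)
    for cat in out.index:
        out[cat] = out[cat] * float(tri_ratio[_category_context(cat)])
    return out


@dataclass
class ExposureVector:
    """Nonnegative signature weights (Σ ≤ 1) plus the unexplained residual."""

    sample_id: str
    weights: pd.Series
    residual: float

    def __post_init__(self) -> None:
        if (self.weights < -1e-9).any():
            raise CohortError("negative exposure weight")
        if self.weights.sum() > 1.0 + 1e-6:
            raise CohortError("exposure weights exceed 1")


def load_catalog(path) -> pd.DataFrame:
    """Signature catalog TSV: 96 category rows × signature columns."""
    cat = pd.read_csv(path, sep="\t", index_col=0)
    cat = cat.reindex(list(SBS96_CATEGORIES))
    if cat.isna().any().any():
        raise CohortError("catalog must cover all 96 categories")
    sums = cat.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise CohortError("each catalog signature must sum to 1")
    return cat


def toy_catalog() -> pd.DataFrame:
    """The packaged 5-signature synthetic catalog (for tests and examples)."""
    with resources.as_file(
        resources.files("leukotype").joinpath("data", "toy_sbs_catalog.tsv")
    ) as path:
        return load_catalog(path)


def fit_exposures(
    vector: pd.Series,
    catalog: pd.DataFrame,
    min_weight: float = 0.06,
) -> ExposureVector:
    """NNLS signature refitting with iterative minimum-weight pruning."""
    v = vector.reindex(catalog.index).to_numpy(float)
    if np.isnan(v).any():
        raise CohortError("vector does not cover the catalog's categories")
    total = v.sum()
    if total <= 0:
        raise CohortError("empty mutation spectrum")
    v = v / total
    if not len(catalog.columns):
        raise CohortError("empty catalog")
    active = list(catalog.columns)
    C = catalog.to_numpy(float)
    while True:
        idx = [catalog.columns.get_loc(s) for s in active]
        w, _ = nnls(C[:, idx], v)
        below = [s for s, wi in zip(active, w) if 0 < wi < min_weight]
        if not below:
            break
        active = [s for s in active if s not in below]
        if not active:
            break
    weights = pd.Series(0.0, index=catalog.columns, name="weight")
    if active:
        weights.loc[active] = w
    if weights.sum() > 1.0:
        weights /= weights.sum()
    recon = C @ weights.to_numpy()
    norm = np.linalg.norm(recon) * np.linalg.norm(v)
    residual = 1.0 - (float(recon @ v) / norm if norm > 0 else 0.0)
    sample_id = str(vector.name) if vector.name is not None else ""
    return ExposureVector(sample_id, weights, float(residual))


def fit_cohort_exposures(
    counts: pd.DataFrame,
    catalog: pd.DataFrame,
    min_weight: float = 0.06,
    pooled: bool = False,
) -> pd.DataFrame:
    """Exposures for every sample (rows) or for the pooled cohort spectrum."""
    if pooled:
        pooled_vec = counts.sum(axis=0)
        pooled_vec.name = "pooled"
        ev = fit_exposures(pooled_vec, catalog, min_weight)
        out = ev.weights.to_frame().T
        out.index = ["pooled"]
        out["residual"] = ev.residual
        return out
    rows = {}
    for sample, vec in counts.iterrows():
        ev = fit_exposures(vec, catalog, min_weight)
        rows[sample] = {**ev.weights.to_dict(), "residual": ev.residual}
    return pd.DataFrame.from_dict(rows, orient="index")
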