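"""Synthetic multi-omics B-ALL-like cohorts with known subtype structure.

The generator plants K latent subtypes and gives each downstream stage a
recoverable signal: disjoint blocks of upregulated marker genes in log-normal
TPM expression, subtype-enriched gene mutations, a CIMP+/CIMP− methylation
architecture (promoter-island hypermethylation plus enhancer hypomethylation
in CIMP+ samples, a high-β island background in normals), microenvironment
marker shifts, and subtype-dependent exponential survival with independent
uniform censoring. True labels are returned separately and never written
into the cohort layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import (
    ClinicalTable,
    CohortError,
    ExpressionMatrix,
    MethylationMatrix,
    MutationTable,
    OmicsCohort,
    ProbeAnnotation,
    assemble_cohort,
)

#: Marker sets used for the microenvironment layer; subtype shifts reference
#: these names. Genes are synthetic ids so no external list is load-bearing.
TME_MARKER_GENES = {
    "endothelial": [f"ENDO{i:02d}" for i in range(1, 11)],
    "fibroblasts": [f"FIBRO{i:02d}" for i in range(1, 11)],
    "t_cells": [f"TCELL{i:02d}" for i in range(1, 11)],
    "monocytic": [f"MONO{i:02d}" for i in range(1, 11)],
}

_SNV_TRIPLES = [
    (r, a) for r in "ACGT" for a in "ACGT" if r != a
]
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Expression effects are additive in log2 units (``de_log2fc``), mutation
    rates are per-sample Bernoulli probabilities, methylation β values are
    Beta draws, and hazards are events/month.
    """

    n_samples: int = 120
    k_subtypes: int = 3
    mixing_proportions: tuple[float, ...] | None = None  # default: equal
    n_genes: int = 2000
    lncrna_fraction: float = 0.25
    n_markers_per_subtype: int = 100
    de_log2fc: float = 2.0
    baseline_log_expr_mean: float = 3.0
    baseline_log_expr_sd: float = 1.5
    noise_log_expr_sd: float = 1.0
    n_mut_genes: int = 40
    n_enriched_mut_genes_per_subtype: int = 3
    background_mut_rate: float = 0.03
    enriched_mut_rate: float = 0.45
    n_island_promoter_probes: int = 300
    n_enhancer_probes: int = 200
    n_background_probes: int = 300
    normal_high_beta_fraction: float = 0.3
    cimp_positive_subtypes: tuple[int, ...] = (3,)
    beta_hyper: tuple[float, float] = (8.0, 2.0)
    beta_hypo: tuple[float, float] = (2.0, 8.0)
    beta_background: tuple[float, float] = (3.0, 3.0)
    beta_normal_high: tuple[float, float] = (45.0, 2.0)
    n_normal_methylation_samples: int = 9
    hazards: tuple[float, ...] = (0.04, 0.08, 0.012)
    censor_max_months: float = 60.0
    tme_shifts: dict[int, dict[str, float]] = field(
        default_factory=lambda: {1: {"endothelial": 1.5, "fibroblasts": 1.0}}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_subtypes < 1:
            raise CohortError("k_subtypes must be >= 1")
        if self.mixing_proportions is None:
            self.mixing_proportions = tuple(
                [1.0 / self.k_subtypes] * self.k_subtypes
            )
        if len(self.mixing_proportions) != self.k_subtypes:
            raise CohortError("mixing_proportions length must equal k_subtypes")
        if abs(sum(self.mixing_proportions) - 1.0) > 1e-8:
            raise CohortError("mixing_proportions must sum to 1")
        if self.k_subtypes * self.n_markers_per_subtype > self.n_genes:
            raise CohortError("marker blocks exceed n_genes")
        for rate in (self.background_mut_rate, self.enriched_mut_rate):
            if not 0.0 <= rate <= 1.0:
                raise CohortError("mutation rates must lie in [0, 1]")
        if len(self.hazards) < self.k_subtypes:
            raise CohortError("one hazard per subtype required")
        if any(h <= 0 for h in self.hazards[: self.k_subtypes]):
            raise CohortError("hazards must be positive")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Independent per-layer generators spawned from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def allocate_labels(n_samples: int, proportions) -> np.ndarray:
    """Deterministic subtype allocation: largest-remainder rounding, in order."""
    k = len(proportions)
    raw = np.asarray(proportions) * n_samples
    counts = np.floor(raw).astype(int)
    remainder = n_samples - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    return np.repeat(np.arange(1, k + 1), counts)


def marker_blocks(config: SimConfig) -> dict[int, list[str]]:
    """Disjoint planted marker gene ids per subtype (G0001, G0002, ...)."""
    blocks = {}
    for s in range(1, config.k_subtypes + 1):
        start = (s - 1) * config.n_markers_per_subtype
        blocks[s] = [
            f"G{g + 1:05d}" for g in range(start, start + config.n_markers_per_subtype)
        ]
    return blocks


def _simulate_expression(config: SimConfig, labels, rng) -> ExpressionMatrix:
    n, g = config.n_samples, config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(g)]
    tme_genes = [gene for genes in TME_MARKER_GENES.values() for gene in genes]
    all_genes = gene_ids + tme_genes
    baseline = rng.normal(
        config.baseline_log_expr_mean, config.baseline_log_expr_sd, size=len(all_genes)
    ).clip(min=0.0)
    log2x = baseline[:, None] + rng.normal(
        0.0, config.noise_log_expr_sd, size=(len(all_genes), n)
    )
    blocks = marker_blocks(config)
    gene_pos = {gid: i for i, gid in enumerate(all_genes)}
    for s, genes in blocks.items():
        cols = labels == s
        rows = [gene_pos[gid] for gid in genes]
        log2x[np.ix_(rows, np.where(cols)[0])] += config.de_log2fc
    for s, shifts in config.tme_shifts.items():
        if s > config.k_subtypes:
            continue
        cols = np.where(labels == s)[0]
        for set_name, shift in shifts.items():
            rows = [gene_pos[gid] for gid in TME_MARKER_GENES[set_name]]
            log2x[np.ix_(rows, cols)] += shift
    log2x = log2x.clip(min=0.0)
    tpm = np.exp2(log2x) - 1.0
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    values = pd.DataFrame(tpm, index=all_genes, columns=sample_ids)
    gene_class = pd.Series("mRNA", index=values.index)
    if config.lncrna_fraction > 0:
        # lncRNAs interleave with marker blocks so both classes carry signal
        stride = max(2, int(round(1.0 / config.lncrna_fraction)))
        lnc = np.zeros(len(all_genes), dtype=bool)
        lnc[:g][np.arange(g) % stride == 0] = True
        gene_class.iloc[lnc] = "lncRNA"
    return ExpressionMatrix(values, gene_class)


def _simulate_mutations(config: SimConfig, labels, sample_ids, rng) -> MutationTable:
    genes = [f"MUT{i + 1:03d}" for i in range(config.n_mut_genes)]
    rates = np.full((config.n_mut_genes, config.n_samples), config.background_mut_rate)
    per = config.n_enriched_mut_genes_per_subtype
    for s in range(1, config.k_subtypes + 1):
        rows = slice((s - 1) * per, s * per)
        rates[rows, labels == s] = config.enriched_mut_rate
    hits = rng.random(rates.shape) < rates
    rows = []
    gi, si = np.where(hits)
    for g_idx, s_idx in zip(gi, si):
        ref_i = rng.integers(4)
        ref = _BASES[ref_i]
        alt = _BASES[(ref_i + rng.integers(1, 4)) % 4]
        flank = _BASES[rng.integers(4, size=2)]
        rows.append({
            "sample_id": sample_ids[s_idx],
            "gene": genes[g_idx],
            "chrom": str(1 + g_idx % 22),
            "pos": int(1_000_000 + 1000 * g_idx + s_idx),
            "ref": ref,
            "alt": alt,
            "context": flank[0] + ref + flank[1],
            "effect": ["missense", "nonsense", "silent"][int(rng.integers(3))],
            "vaf": float(rng.uniform(0.05, 0.6)),
        })
    from .core_io import MUTATION_COLUMNS
    records = pd.DataFrame(rows, columns=MUTATION_COLUMNS)
    return MutationTable(records)


def _probe_layout(config: SimConfig) -> ProbeAnnotation:
    rows = []
    for i in range(config.n_island_promoter_probes):
        rows.append((f"cgPRO{i + 1:04d}", "island", True, False))
    for i in range(config.n_enhancer_probes):
        rows.append((f"cgENH{i + 1:04d}", "openSea", False, True))
    for i in range(config.n_background_probes):
        cls = ["island", "shore", "shelf"][i % 3]
        rows.append((f"cgBKG{i + 1:04d}", cls, False, False))
    table = pd.DataFrame(
        rows, columns=["probe_id", "cgi_class", "promoter", "enhancer"]
    ).set_index("probe_id")
    table["gene_body"] = False
    table["UTR"] = False
    return ProbeAnnotation(table)


def _beta_draw(rng, ab: tuple[float, float], size) -> np.ndarray:
    return rng.beta(ab[0], ab[1], size=size)


def _simulate_methylation(
    config: SimConfig, labels, sample_ids, rng
) -> tuple[MethylationMatrix, ProbeAnnotation]:
    annot = _probe_layout(config)
    probes = list(annot.table.index)
    cimp_pos = np.isin(labels, list(config.cimp_positive_subtypes))
    n_t = config.n_samples
    beta = np.empty((len(probes), n_t))
    is_pro = annot.table["promoter"].to_numpy()
    is_enh = annot.table["enhancer"].to_numpy()
    is_bkg = ~(is_pro | is_enh)
    for j in range(n_t):
        if cimp_pos[j]:
            beta[is_pro, j] = _beta_draw(rng, config.beta_hyper, is_pro.sum())
            beta[is_enh, j] = _beta_draw(rng, config.beta_hypo, is_enh.sum())
        else:
            beta[is_pro, j] = _beta_draw(rng, config.beta_hypo, is_pro.sum())
            beta[is_enh, j] = _beta_draw(rng, config.beta_hyper, is_enh.sum())
        beta[is_bkg, j] = _beta_draw(rng, config.beta_background, is_bkg.sum())
    df = pd.DataFrame(beta, index=probes, columns=sample_ids)
    groups = pd.Series("tumor", index=df.columns)
    meth = MethylationMatrix(df, groups)
    return meth, annot


def simulate_normals(
    n: int, config: SimConfig, rng: np.random.Generator | None = None
) -> MethylationMatrix:
    """Normal-sample β panel: a configured fraction of island-promoter probes
    sits near β ≈ 0.96 (the background-noise band the CIMP probe filter must
    exclude); everything else is low-methylation background."""
    if n < 2:
        raise CohortError("need at least 2 normal samples")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    annot = _probe_layout(config)
    probes = list(annot.table.index)
    is_pro = annot.table["promoter"].to_numpy()
    n_high = int(round(is_pro.sum() * config.normal_high_beta_fraction))
    high = np.zeros(len(probes), dtype=bool)
    high[np.where(is_pro)[0][:n_high]] = True
    beta = np.empty((len(probes), n))
    beta[high] = _beta_draw(rng, config.beta_normal_high, (high.sum(), n))
    beta[~high] = _beta_draw(rng, (2.0, 10.0), ((~high).sum(), n))
    ids = [f"N{i + 1:03d}" for i in range(n)]
    df = pd.DataFrame(beta, index=probes, columns=ids)
    return MethylationMatrix(df, pd.Series("normal", index=df.columns))


def _simulate_clinical(config: SimConfig, labels, sample_ids, rng) -> ClinicalTable:
    n = config.n_samples
    hazards = np.asarray(config.hazards)[labels - 1]
    event_t = rng.exponential(1.0 / hazards)
    censor_t = rng.uniform(0.0, config.censor_max_months, size=n)
    os_time = np.minimum(event_t, censor_t)
    os_event = event_t <= censor_t
    efs_event_t = event_t * rng.uniform(0.5, 1.0, size=n)
    efs_time = np.minimum(efs_event_t, censor_t)
    efs_event = efs_event_t <= censor_t
    table = pd.DataFrame(
        {
            "age": rng.integers(15, 71, size=n),
            "sex": rng.choice(["M", "F"], size=n),
            "wbc": np.round(rng.lognormal(2.0, 1.0, size=n), 1),
            "disease_status": rng.choice(["ND", "RR"], size=n, p=[0.8, 0.2]),
            "ph_status": rng.choice(["pos", "neg"], size=n, p=[0.4, 0.6]),
            "ph_like": rng.random(n) < 0.1,
            "nccn_risk": rng.choice(["standard", "high"], size=n),
            "mrd1": rng.choice(["pos", "neg"], size=n),
            "mrd2": rng.choice(["pos", "neg"], size=n),
            "hsct": rng.random(n) < 0.45,
            "os_time": np.round(os_time, 2),
            "os_event": os_event,
            "efs_time": np.round(efs_time, 2),
            "efs_event": efs_event,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ClinicalTable(table)


def simulate_cohort(config: SimConfig) -> tuple[OmicsCohort, np.ndarray]:
    """Generate one cohort; returns ``(cohort, true_labels)``.

    ``true_labels`` is an array of 1-based subtype ids aligned with the
    cohort's sample order; it is never stored inside the cohort.
    """
    rng_expr, rng_mut, rng_meth, rng_clin = _substreams(config.seed, 4)
    labels = allocate_labels(config.n_samples, config.mixing_proportions)
    expr = _simulate_expression(config, labels, rng_expr)
    sample_ids = expr.sample_ids
    mut = _simulate_mutations(config, labels, sample_ids, rng_mut)
    meth, _ = _simulate_methylation(config, labels, sample_ids, rng_meth)
    clin = _simulate_clinical(config, labels, sample_ids, rng_clin)
    cohort = assemble_cohort(expr, mut, meth, clin)
    return cohort, labels


def probe_annotation(config: SimConfig) -> ProbeAnnotation:
    """The probe layout shared by tumor and normal methylation layers."""
    return _probe_layout(config)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
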