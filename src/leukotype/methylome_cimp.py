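"""CpG-island methylator phenotype (CIMP) calling and differential methylation.

Candidate probes are CpG-island probes that are not already near-fully
methylated in normal samples (mean β > 0.9 excluded as background) and show
high variability across tumors (SD > 0.25). Ward clustering of tumor β
profiles over those probes yields two epi-clusters; the one with the larger
mean β is CIMP+. Differential methylation uses a moderated t on M-values
(log2 β/(1−β), β clipped away from 0/1) with the effect reported as Δβ, and
region composition/enrichment contrasts DMPs against a background probe set
with per-category Fisher tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .clinical_stats import fisher_exact
from .core_io import CohortError, MethylationMatrix, ProbeAnnotation
from .subtype_signatures import bh_adjust, moderated_ttest


@dataclass
class CimpResult:
    selected_probes: list[str]
    epi_cluster: pd.Series  # tumor sample -> "CIMP+" / "CIMP-"
    cluster_mean_beta: dict[str, float]

    def __post_init__(self) -> None:
        if not self.cluster_mean_beta["CIMP+"] > self.cluster_mean_beta["CIMP-"]:
            raise CohortError("CIMP+ must have strictly greater mean β")


def select_cimp_probes(
    meth: MethylationMatrix,
    annot: ProbeAnnotation,
    normal_beta_max: float = 0.9,
    tumor_sd_min: float = 0.25,
    sd_on_all_samples: bool = False,
) -> list[str]:
    """Island probes passing the normal-background and variability filters.

    ``sd_on_all_samples=True`` computes the SD filter over tumors and
    normals pooled instead of tumors only.
    """
    tumors = meth.tumor_samples()
    normals = meth.normal_samples()
    if len(normals) < 2 or len(tumors) < 4:
        raise CohortError("need >= 2 normal and >= 4 tumor samples")
    islands = [p for p in annot.probes_of_class("island") if p in meth.beta.index]
    n_island = len(islands)
    if not n_island:
        raise CohortError("no annotated island probes present in the matrix")
    normal_mean = meth.beta.loc[islands, normals].mean(axis=1)
    after_normal = normal_mean.index[normal_mean <= normal_beta_max]
    sd_cols = tumors + normals if sd_on_all_samples else tumors
    sd = meth.beta.loc[after_normal, sd_cols].std(axis=1, ddof=1)
    selected = list(sd.index[sd > tumor_sd_min])
    if not selected:
        raise CohortError(
            "no probe survives: "
            f"{n_island} island, {len(after_normal)} after normal-β filter, "
            f"0 after SD filter"
        )
    return selected


def call_cimp(meth: MethylationMatrix, selected_probes) -> CimpResult:
    """Two-group Ward clustering of tumor β profiles over selected probes."""
    tumors = meth.tumor_samples()
    probes = list(selected_probes)
    if len(tumors) < 4:
        raise CohortError("need >= 4 tumor samples")
    if len(probes) < 2:
        raise CohortError("need >= 2 selected probes")
    X = meth.beta.loc[probes, tumors].to_numpy(float).T
    Z = linkage(X, method="ward")
    raw = fcluster(Z, t=2, criterion="maxclust")
    means = {c: X[raw == c].mean() for c in (1, 2)}
    if np.isclose(means[1], means[2]):
        raise CohortError("clusters have identical mean β; orientation undefined")
    hyper = max(means, key=means.get)
    labels = pd.Series(
        np.where(raw == hyper, "CIMP+", "CIMP-"), index=tumors, name="epi_cluster"
    )
    return CimpResult(
        selected_probes=probes,
        epi_cluster=labels,
        cluster_mean_beta={
            "CIMP+": float(means[hyper]),
            "CIMP-": float(means[3 - hyper]),
        },
    )


def beta_to_m(beta: np.ndarray, clip: tuple[float, float] = (0.001, 0.999)) -> np.ndarray:
    """M-value transform log2(β/(1−β)) with β clipped away from 0 and 1."""
    b = np.clip(np.asarray(beta, dtype=float), clip[0], clip[1])
    return np.log2(b / (1.0 - b))


def call_dmps(
    meth: MethylationMatrix,
    group_a,
    group_b,
    adj_p_max: float = 0.05,
    min_delta_beta: float = 0.0,
    annot: ProbeAnnotation | None = None,
) -> pd.DataFrame:
    """Differentially methylated probes between two sample groups.

    Moderated t on M-values; Δβ = mean β(a) − mean β(b) is the reported
    effect, its sign setting the hyper/hypo direction. Returns the probes
    passing ``adj_p < adj_p_max`` and ``|Δβ| ≥ min_delta_beta``, annotated
    with CGI class and region flags when an annotation is supplied.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 3 or len(group_b) < 3:
        raise CohortError("each group needs >= 3 samples")
    beta_a = meth.beta[group_a].to_numpy(float)
    beta_b = meth.beta[group_b].to_numpy(float)
    res = moderated_ttest(beta_to_m(beta_a), beta_to_m(beta_b))
    delta = beta_a.mean(axis=1) - beta_b.mean(axis=1)
    table = pd.DataFrame(
        {
            "delta_beta": delta,
            "t": res["t"].to_numpy(),
            "p": res["p"].to_numpy(),
            "adj_p": bh_adjust(res["p"].to_numpy()),
        },
        index=meth.beta.index,
    )
    table["direction"] = np.where(table["delta_beta"] >= 0, "hyper", "hypo")
    out = table[
        (table["adj_p"] < adj_p_max) & (table["delta_beta"].abs() >= min_delta_beta)
    ].copy()
    if annot is not None:
        ann = annot.table.reindex(out.index)
        out["cgi_class"] = ann["cgi_class"]
        for flag in ("promoter", "enhancer", "gene_body", "UTR"):
            out[flag] = ann[flag].fillna(False).astype(bool)
    return out


def region_distribution(
    dmps: pd.DataFrame,
    annot: ProbeAnnotation,
    background_probes,
) -> pd.DataFrame:
    """Per-direction region composition with Fisher enrichment vs background.

    One row per (direction, category); categories are the CGI classes and
    the region flags. Enrichment compares DMP membership in the category
    against the background probe set (odds ratio + two-sided Fisher p, BH
    across categories within a direction).
    """
    if not len(dmps):
        raise CohortError("empty DMP table")
    background_probes = [p for p in background_probes if p in annot.table.index]
    if not background_probes:
        raise CohortError("empty background probe set")
    bg = annot.table.loc[background_probes]
    rows = []
    categories = [("cgi_class", c) for c in ("island", "shore", "shelf", "openSea")]
    categories += [("flag", f) for f in ("promoter", "enhancer", "gene_body", "UTR")]
    for direction in ("hyper", "hypo"):
        sub = dmps[dmps["direction"] == direction]
        if not len(sub):
            continue
        ann = annot.table.reindex(sub.index)
        pvals = []
        for kind, cat in categories:
            if kind == "cgi_class":
                in_dmp = (ann["cgi_class"] == cat).sum()
                in_bg = (bg["cgi_class"] == cat).sum()
            else:
                in_dmp = ann[cat].fillna(False).astype(bool).sum()
                in_bg = bg[cat].astype(bool).sum()
            n_dmp, n_bg = len(sub), len(bg)
            table = [
                [int(in_dmp), int(n_dmp - in_dmp)],
                [int(in_bg), int(n_bg - in_bg)],
            ]
            a, b_, c, d = table[0][0], table[0][1], table[1][0], table[1][1]
            odds = (a * d) / (b_ * c) if b_ * c > 0 else np.inf
            if min(a + b_, c + d) == 0 or min(a + c, b_ + d) == 0:
                p = 1.0
            else:
                p = fisher_exact(table)
            pvals.append(p)
            rows.append(
                {
                    "direction": direction,
                    "category": cat,
                    "n_dmp": int(in_dmp),
                    "fraction_dmp": in_dmp / n_dmp,
                    "n_background": int(in_bg),
                    "fraction_background": in_bg / n_bg,
                    "odds_ratio": odds,
                    "p": p,
                }
            )
        adj = bh_adjust(pvals)
        for i, r in enumerate(rows[-len(pvals):]):
            r["adj_p"] = adj[i]
    return pd.DataFrame(rows)
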