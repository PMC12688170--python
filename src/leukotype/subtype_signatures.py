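"""One-vs-rest differential expression, marker-signature derivation, GSEA.

Differential expression uses a moderated t statistic: per-gene pooled
variances are shrunk toward a common prior whose scale and degrees of
freedom are estimated from the whole variance distribution by moment
matching on log s² (the single-factor special case of the empirical-Bayes
linear-model framework). Signatures take, per subtype, the top upregulated
markers unique to that subtype; enrichment uses the classic preranked
weighted Kolmogorov–Smirnov running statistic with gene-label permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .core_io import CohortError, ExpressionMatrix, GeneSetCollection


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise CohortError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi² prior (d0, s0²) to observed
    residual variances with ``df`` degrees of freedom each.

    Returns ``(prior_df, prior_var)``; ``prior_df`` may be ``inf`` when the
    observed spread of log variances is no larger than sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-12)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    excess = ((e - e_mean) ** 2).sum() / max(len(e) - 1, 1) - special.polygamma(
        1, df / 2.0
    )
    if excess <= 0:
        return float("inf"), float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(float(excess))
    s0_sq = np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    return float(d0), float(s0_sq)


def moderated_ttest(
    a: np.ndarray, b: np.ndarray, prior_df: float | None = None
) -> pd.DataFrame:
    """Row-wise moderated two-sample t-test (rows = features).

    ``prior_df`` overrides the estimated prior degrees of freedom
    (0 → ordinary pooled t; ``inf`` → complete shrinkage to the prior
    variance). Returns diff / t / df / p per row.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 3 or n2 < 3:
        raise CohortError("each group needs at least 3 samples")
    diff = a.mean(axis=1) - b.mean(axis=1)
    df = n1 + n2 - 2
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df
    d0, s0_sq = estimate_variance_prior(s2, df)
    if prior_df is not None:
        d0 = float(prior_df)
    if np.isinf(d0):
        post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = df + d0
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame({"diff": diff, "t": t, "df": df_total, "p": p})


def de_one_vs_rest(
    expr: ExpressionMatrix,
    labels,
    subtype: int,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """One-vs-rest moderated t on log2(TPM+1); BH-adjusted p-values.

    Returns a gene-indexed DataFrame with log2fc / t / p / adj_p.
    """
    labels = np.asarray(labels)
    log_expr = expr.log2().values
    in_grp = labels == subtype
    if in_grp.sum() < 3 or (~in_grp).sum() < 3:
        raise CohortError("subtype and rest each need >= 3 samples")
    X = log_expr.to_numpy(float)
    res = moderated_ttest(X[:, in_grp], X[:, ~in_grp], prior_df=prior_df)
    out = pd.DataFrame(
        {
            "log2fc": res["diff"].to_numpy(),
            "t": res["t"].to_numpy(),
            "p": res["p"].to_numpy(),
        },
        index=log_expr.index,
    )
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Signature derivation
# ---------------------------------------------------------------------------

@dataclass
class SignatureSet:
    """Per-subtype ordered marker lists with their DE evidence."""

    markers: dict[int, pd.DataFrame]  # subtype -> DataFrame(log2fc, adj_p)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for subtype, table in self.markers.items():
            genes = set(table.index)
            overlap = genes & seen
            if overlap:
                raise CohortError(
                    f"marker lists overlap (subtype {subtype}): {sorted(overlap)[:5]}"
                )
            seen |= genes

    def genes(self, subtype: int) -> list[str]:
        return list(self.markers[subtype].index)

    def all_genes(self) -> list[str]:
        return [g for t in self.markers.values() for g in t.index]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subtype, table in self.markers.items():
            for gene, row in table.iterrows():
                rows.append((subtype, gene, row["log2fc"], row["adj_p"]))
        return pd.DataFrame(rows, columns=["subtype", "gene", "log2fc", "adj_p"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SignatureSet":
        markers = {
            int(s): grp.set_index("gene")[["log2fc", "adj_p"]]
            for s, grp in frame.groupby("subtype")
        }
        return cls(markers)


def derive_signature(
    de_tables: dict[int, pd.DataFrame],
    top_n: int = 50,
    adj_p_max: float = 0.05,
) -> SignatureSet:
    """Top-``top_n`` upregulated unique markers per subtype.

    A gene qualifying (log2fc > 0, adj_p < ``adj_p_max``) for two or more
    subtypes is removed from all lists; survivors are ranked by descending
    log2fc within their subtype.
    """
    candidates = {
        s: t[(t["log2fc"] > 0) & (t["adj_p"] < adj_p_max)]
        for s, t in de_tables.items()
    }
    if all(len(c) == 0 for c in candidates.values()):
        raise CohortError("no subtype yields any candidate marker")
    counts: dict[str, int] = {}
    for c in candidates.values():
        for g in c.index:
            counts[g] = counts.get(g, 0) + 1
    shared = {g for g, n in counts.items() if n > 1}
    markers = {}
    for s, c in candidates.items():
        unique = c[~c.index.isin(shared)]
        ranked = unique.sort_values(
            ["log2fc"], ascending=False, kind="mergesort"
        ).head(top_n)
        if len(ranked) < top_n:
            warnings.warn(
                f"subtype {s}: only {len(ranked)} unique markers (requested {top_n})",
                stacklevel=2,
            )
        markers[s] = ranked[["log2fc", "adj_p"]]
    return SignatureSet(markers)


# ---------------------------------------------------------------------------
# Preranked GSEA
# ---------------------------------------------------------------------------

def _running_es(scores: np.ndarray, hit_mask: np.ndarray, weight: float):
    """Signed max-deviation of the weighted KS running sum."""
    n = len(scores)
    n_hit = int(hit_mask.sum())
    inc = np.abs(scores) ** weight * hit_mask
    denom = inc.sum()
    if denom == 0:  # all hit scores are 0 under weight>0: fall back to uniform
        inc = hit_mask.astype(float)
        denom = inc.sum()
    running = np.cumsum(inc / denom - (~hit_mask) / (n - n_hit))
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak, running


def preranked_gsea_single(
    ranked: pd.Series,
    gene_set,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> dict:
    """ES / NES / empirical p / leading edge for one gene set.

    ``ranked`` maps gene → score, already sorted by descending score
    (descending log2 fold change in the standard workflow). The null
    permutes gene labels: hit positions are redrawn uniformly.
    """
    if n_perm < 100:
        raise CohortError("n_perm must be >= 100")
    if np.any(np.diff(ranked.to_numpy(float)) > 0):
        ranked = ranked.sort_values(ascending=False, kind="mergesort")
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(float)
    hit_mask = np.isin(genes, list(gene_set))
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise CohortError("gene set has no overlap with the ranked universe")
    es, peak, running = _running_es(scores, hit_mask, weight)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n = len(genes)
    for b in range(n_perm):
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, size=n_hit, replace=False)] = True
        null[b], _, _ = _running_es(scores, mask, weight)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if len(same_sign):
        nes = es / np.mean(np.abs(same_sign))
        p = (1.0 + (np.abs(same_sign) >= abs(es)).sum()) / (1.0 + len(same_sign))
    else:
        nes = 0.0 if es == 0 else np.inf * np.sign(es)
        p = 1.0 / (1.0 + n_perm)
    if es >= 0:
        leading = [g for g, h in zip(genes[: peak + 1], hit_mask[: peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak:], hit_mask[peak:]) if h]
    return {
        "es": es,
        "nes": float(nes),
        "p": float(p),
        "n_hits": n_hit,
        "leading_edge": leading,
    }


def preranked_gsea(
    ranked: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Preranked GSEA over a whole collection with BH across gene sets."""
    rows = {}
    rng = np.random.default_rng(seed)
    for name in collection.names():
        sub = int(rng.integers(2**31))
        rows[name] = preranked_gsea_single(
            ranked, collection.genes(name), n_perm, weight, sub
        )
    out = pd.DataFrame.from_dict(rows, orient="index")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out
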