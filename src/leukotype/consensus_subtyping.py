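"""Consensus-ensemble subtype discovery.

A registry of classical partitioners is run on the selected feature space;
their agreement is summarized in a sample × sample consensus matrix (the
fraction of base partitions co-assigning each pair), which is itself
clustered to produce the final subtype labels. The number of subtypes is
chosen by combining two curves over candidate k: a cluster prediction index
(CPI, defined here as the mean pairwise adjusted Rand index between base
partitions) and the Tibshirani gap statistic. Silhouette widths on the
consensus distance 1 − M report per-subtype cohesion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.cluster import AgglomerativeClustering, KMeans, SpectralClustering
from sklearn.decomposition import NMF
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from .core_io import CohortError
from .feature_selection import FeatureMatrix

logger = logging.getLogger("leukotype")

DEFAULT_ALGORITHMS = ("kmeans", "ward", "pam", "spectral", "gmm", "nmf")


@dataclass
class PartitionEnsemble:
    k: int
    sample_ids: list[str]
    partitions: list[tuple[str, np.ndarray]]
    seed: int

    def __post_init__(self) -> None:
        expected = set(range(1, self.k + 1))
        for name, labels in self.partitions:
            if len(labels) != len(self.sample_ids):
                raise CohortError(f"partition {name}: wrong label count")
            if set(np.unique(labels)) != expected:
                raise CohortError(
                    f"partition {name}: labels must cover 1..{self.k} "
                    f"with no empty cluster"
                )


@dataclass
class ConsensusMatrix:
    sample_ids: list[str]
    M: np.ndarray

    def __post_init__(self) -> None:
        M = self.M
        if M.shape != (len(self.sample_ids),) * 2:
            raise CohortError("consensus matrix shape mismatch")
        if not np.allclose(M, M.T):
            raise CohortError("consensus matrix must be symmetric")
        if not np.allclose(np.diag(M), 1.0):
            raise CohortError("consensus diagonal must be 1")
        if (M < -1e-12).any() or (M > 1 + 1e-12).any():
            raise CohortError("consensus entries must lie in [0, 1]")

    def distance(self) -> np.ndarray:
        D = 1.0 - self.M
        np.fill_diagonal(D, 0.0)
        return np.maximum(D, 0.0)


@dataclass
class SubtypeModel:
    k: int
    sample_ids: list[str]
    labels: np.ndarray
    consensus: ConsensusMatrix
    silhouette_per_sample: np.ndarray
    silhouette_per_cluster: dict[int, float]
    silhouette_mean: float
    cpi_curve: pd.Series
    gap_curve: pd.DataFrame
    seed: int
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "seed": int(self.seed),
            "algorithms": list(self.algorithms),
            "labels": {s: int(l) for s, l in zip(self.sample_ids, self.labels)},
            "silhouette_mean": float(self.silhouette_mean),
            "silhouette_per_cluster": {
                str(c): float(v) for c, v in self.silhouette_per_cluster.items()
            },
            "cpi_curve": {str(k): float(v) for k, v in self.cpi_curve.items()},
            "gap_curve": {
                str(k): {"gap": float(r["gap"]), "se": float(r["se"])}
                for k, r in self.gap_curve.iterrows()
            },
        }


# ---------------------------------------------------------------------------
# Feature preparation
# ---------------------------------------------------------------------------

def _standardized_concat(fm: FeatureMatrix) -> np.ndarray:
    """Z-score continuous columns; scale binary columns to unit variance."""
    blocks = []
    X = fm.continuous.to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    blocks.append((X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep])
    if fm.binary is not None and fm.binary.shape[1]:
        B = fm.binary.to_numpy(float)
        sd = B.std(axis=0, ddof=0)
        keep = sd > 0
        if keep.any():
            blocks.append(B[:, keep] / sd[keep])
    return np.hstack(blocks)


def _mixed_distance(fm: FeatureMatrix) -> np.ndarray:
    """Mean of Spearman-correlation distance (continuous block) and Jaccard
    distance (binary block); rank-based so monotone-invariant."""
    X = fm.continuous.to_numpy(float)
    ranks = np.apply_along_axis(rankdata, 1, X)
    rho = np.corrcoef(ranks)
    d_cont = 1.0 - rho
    parts = [np.clip(d_cont, 0.0, 2.0)]
    if fm.binary is not None and fm.binary.shape[1]:
        B = fm.binary.to_numpy(bool)
        inter = (B[:, None, :] & B[None, :, :]).sum(axis=2).astype(float)
        union = (B[:, None, :] | B[None, :, :]).sum(axis=2).astype(float)
        with np.errstate(invalid="ignore"):
            jac = np.where(union > 0, 1.0 - inter / union, 0.0)
        parts.append(jac)
    D = np.mean(parts, axis=0)
    np.fill_diagonal(D, 0.0)
    return (D + D.T) / 2.0


def _gaussian_affinity(D: np.ndarray) -> np.ndarray:
    sigma = np.median(D[np.triu_indices_from(D, k=1)])
    sigma = sigma if sigma > 0 else 1.0
    A = np.exp(-(D ** 2) / (2.0 * sigma ** 2))
    np.fill_diagonal(A, 1.0)
    return A


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel to contiguous 1..k (order of first appearance)."""
    _, inv = np.unique(labels, return_inverse=True)
    return inv + 1


def _repair_empty(labels: np.ndarray, X: np.ndarray, k: int) -> np.ndarray:
    """Deterministically fill empty clusters: move the member of the largest
    cluster farthest from its centroid into the empty slot."""
    labels = labels.copy()
    for c in range(1, k + 1):
        while (labels == c).sum() == 0:
            sizes = np.bincount(labels, minlength=k + 1)
            big = int(np.argmax(sizes[1:]) + 1)
            members = np.where(labels == big)[0]
            centroid = X[members].mean(axis=0)
            far = members[int(np.argmax(((X[members] - centroid) ** 2).sum(axis=1)))]
            labels[far] = c
    return labels


# ---------------------------------------------------------------------------
# Base partitioners
# ---------------------------------------------------------------------------

def _pam_once(D: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = D.shape[0]
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(200):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.where(labels == c)[0]
            if len(members) == 0:
                # reseed from the point worst-served by current medoids
                new[c] = int(np.argmax(D[:, medoids].min(axis=1)))
                continue
            within = D[np.ix_(members, members)].sum(axis=1)
            new[c] = members[int(np.argmin(within))]
        if np.array_equal(np.sort(new), np.sort(medoids)):
            break
        medoids = new
    return np.argmin(D[:, medoids], axis=1) + 1


def _pam(
    D: np.ndarray, k: int, rng: np.random.Generator, restarts: int = 5
) -> np.ndarray:
    """Partitioning around medoids (alternating assign/update) on a
    precomputed distance matrix; best of several random restarts."""
    best_labels, best_cost = None, np.inf
    for _ in range(restarts):
        labels = _pam_once(D, k, rng)
        cost = sum(
            D[np.ix_(labels == c, labels == c)].sum() for c in np.unique(labels)
        )
        if cost < best_cost - 1e-12:
            best_labels, best_cost = labels, cost
    return best_labels


def _snf_fuse(affinities: list[np.ndarray], iterations: int = 10) -> np.ndarray:
    """Cross-diffusion fusion of per-layer affinities (row-normalized)."""
    def norm(W):
        P = W / W.sum(axis=1, keepdims=True)
        return (P + P.T) / 2.0

    P = [norm(W) for W in affinities]
    if len(P) == 1:
        return P[0]
    for _ in range(iterations):
        new = []
        for i, Pi in enumerate(P):
            others = np.mean([P[j] for j in range(len(P)) if j != i], axis=0)
            new.append(norm(Pi @ others @ Pi.T))
        P = new
    return np.mean(P, axis=0)


def run_base_partitions(
    fm: FeatureMatrix,
    k: int,
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS,
    seed: int = 0,
) -> PartitionEnsemble:
    """Run every requested base algorithm at a fixed ``k``.

    Registry: kmeans, ward (Euclidean), pam (mixed rank/Jaccard distance),
    spectral (Gaussian affinity), gmm (diagonal-covariance mixture), nmf
    (shifted expression, dominant factor), snf (per-layer affinity fusion +
    spectral).
    """
    n = len(fm.sample_ids)
    if k < 2:
        raise CohortError("k must be >= 2")
    if k > n:
        raise CohortError("k exceeds the number of samples")
    if len(algorithms) < 2:
        raise CohortError("at least 2 base algorithms are required")
    unknown = set(algorithms) - {
        "kmeans", "ward", "pam", "spectral", "gmm", "nmf", "snf"
    }
    if unknown:
        raise CohortError(f"unknown algorithms: {sorted(unknown)}")

    X = _standardized_concat(fm)
    D_mixed = _mixed_distance(fm)
    rng = np.random.default_rng(seed)
    partitions: list[tuple[str, np.ndarray]] = []
    for name in algorithms:
        sub = int(rng.integers(2**31))
        if name == "kmeans":
            labels = KMeans(k, n_init=10, random_state=sub).fit_predict(X) + 1
        elif name == "ward":
            labels = AgglomerativeClustering(k, linkage="ward").fit_predict(X) + 1
        elif name == "pam":
            labels = _pam(D_mixed, k, np.random.default_rng(sub))
        elif name == "spectral":
            A = _gaussian_affinity(squareform(pdist(X)))
            labels = SpectralClustering(
                k, affinity="precomputed", random_state=sub, assign_labels="kmeans"
            ).fit_predict(A) + 1
        elif name == "gmm":
            gm = GaussianMixture(
                k, covariance_type="diag", n_init=3, random_state=sub, reg_covar=1e-4
            )
            labels = gm.fit_predict(X) + 1
        elif name == "nmf":
            # classic consensus-NMF orientation: genes × samples, per-gene
            # standardized then shifted nonnegative; a sample's label is its
            # dominant coefficient factor
            expr = fm.continuous.to_numpy(float)
            sd_g = expr.std(axis=0, ddof=0)
            Zg = (expr - expr.mean(axis=0)) / np.where(sd_g > 0, sd_g, 1.0)
            shifted = (Zg - Zg.min()).T
            model = NMF(k, init="nndsvda", random_state=sub, max_iter=500, tol=1e-4)
            model.fit(shifted)
            labels = np.argmax(model.components_, axis=0) + 1
        elif name == "snf":
            aff = [_gaussian_affinity(squareform(pdist(X)))]
            if fm.binary is not None and fm.binary.shape[1]:
                B = fm.binary.to_numpy(bool)
                inter = (B[:, None, :] & B[None, :, :]).sum(axis=2).astype(float)
                union = (B[:, None, :] | B[None, :, :]).sum(axis=2).astype(float)
                with np.errstate(invalid="ignore"):
                    Db = np.where(union > 0, 1.0 - inter / union, 0.0)
                np.fill_diagonal(Db, 0.0)
                aff.append(_gaussian_affinity(Db))
            fused = _snf_fuse(aff)
            labels = SpectralClustering(
                k, affinity="precomputed", random_state=sub
            ).fit_predict(fused) + 1
        labels = _canonical(_repair_empty(np.asarray(labels), X, k))
        partitions.append((name, labels))
    return PartitionEnsemble(k, list(fm.sample_ids), partitions, seed)


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def consensus_matrix(ensemble: PartitionEnsemble) -> ConsensusMatrix:
    """M[i, j] = fraction of base partitions co-assigning samples i and j."""
    if not ensemble.partitions:
        raise CohortError("empty ensemble")
    n = len(ensemble.sample_ids)
    M = np.zeros((n, n))
    for _, labels in ensemble.partitions:
        M += (labels[:, None] == labels[None, :]).astype(float)
    M /= len(ensemble.partitions)
    return ConsensusMatrix(ensemble.sample_ids, M)


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """1 = largest cluster; ties broken by smallest contained sample index."""
    ids = np.unique(labels)
    order = sorted(
        ids, key=lambda c: (-(labels == c).sum(), int(np.argmax(labels == c)))
    )
    mapping = {c: i + 1 for i, c in enumerate(order)}
    return np.array([mapping[c] for c in labels])


def consensus_labels(cm: ConsensusMatrix, k: int) -> np.ndarray:
    """Average-linkage hierarchical clustering of D = 1 − M, cut at k."""
    D = cm.distance()
    n_profiles = len(np.unique(np.round(cm.M, 12), axis=0))
    if k > n_profiles:
        raise CohortError(
            f"k={k} exceeds the {n_profiles} distinct consensus profiles"
        )
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise CohortError(f"average linkage could not produce {k} clusters")
    return _renumber_by_size(raw)


def silhouette_scores(
    labels: np.ndarray, distance: np.ndarray
) -> tuple[np.ndarray, dict[int, float], float]:
    """Standard silhouette widths on a precomputed distance matrix.

    Singleton clusters score 0 by convention. Returns per-sample values,
    per-cluster means and the overall mean.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if len(ids) < 2:
        raise CohortError("silhouette requires at least 2 clusters")
    n = len(labels)
    s = np.zeros(n)
    for i in range(n):
        own = labels[i]
        mates = (labels == own) & (np.arange(n) != i)
        if not mates.any():
            s[i] = 0.0
            continue
        a = distance[i, mates].mean()
        b = min(distance[i, labels == c].mean() for c in ids if c != own)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    per_cluster = {int(c): float(s[labels == c].mean()) for c in ids}
    return s, per_cluster, float(s.mean())


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def _pooled_dispersion(X: np.ndarray, k: int, seed: int) -> float:
    """k-means within-cluster sum of squares (Tibshirani's W_k)."""
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    km = KMeans(k, n_init=5, random_state=seed).fit(X)
    return float(km.inertia_)


def gap_statistic(
    fm: FeatureMatrix | np.ndarray,
    k_range,
    B: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Gap(k) = mean_B log W*_k − log W_k with a uniform-over-range reference.

    Returns a DataFrame indexed by k with columns gap / se / log_w; the
    one-standard-error rule (smallest k with Gap(k) ≥ Gap(k+1) − se(k+1))
    is left to the caller as a secondary report.
    """
    if B < 2:
        raise CohortError("B must be >= 2")
    X = fm if isinstance(fm, np.ndarray) else _standardized_concat(fm)
    n = X.shape[0]
    k_range = [int(k) for k in k_range]
    if any(k < 1 or k > n - 1 for k in k_range):
        raise CohortError("k_range must lie within [1, n-1]")
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    rows = []
    ref_logs = np.empty((B, len(k_range)))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(2**31))
        for j, k in enumerate(k_range):
            ref_logs[b, j] = np.log(_pooled_dispersion(ref, k, ref_seed))
    for j, k in enumerate(k_range):
        log_w = np.log(_pooled_dispersion(X, k, seed))
        gap = float(ref_logs[:, j].mean() - log_w)
        se = float(ref_logs[:, j].std(ddof=0) * np.sqrt(1.0 + 1.0 / B))
        rows.append((k, gap, se, log_w))
    return pd.DataFrame(
        rows, columns=["k", "gap", "se", "log_w"]
    ).set_index("k")


def cpi(
    fm: FeatureMatrix,
    k_range,
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS,
    seed: int = 0,
) -> pd.Series:
    """Mean pairwise adjusted Rand index between base partitions, per k."""
    if len(algorithms) < 2:
        raise CohortError("CPI needs at least 2 base algorithms")
    values = {}
    for k in k_range:
        ens = run_base_partitions(fm, int(k), algorithms, seed)
        labels = [l for _, l in ens.partitions]
        aris = [
            adjusted_rand_score(labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
        values[int(k)] = float(np.mean(aris))
    return pd.Series(values, name="cpi")


def fit_subtypes(
    fm: FeatureMatrix,
    k_range=(2, 3, 4, 5),
    algorithms: tuple[str, ...] = DEFAULT_ALGORITHMS,
    gap_B: int = 20,
    seed: int = 0,
) -> SubtypeModel:
    """Full subtype discovery: select k by the mean rank of CPI and Gap,
    build the consensus matrix at that k, cut it, score silhouettes."""
    k_range = [int(k) for k in k_range]
    cpi_curve = cpi(fm, k_range, algorithms, seed)
    gap_curve = gap_statistic(fm, k_range, B=gap_B, seed=seed)
    cpi_rank = rankdata(cpi_curve.loc[k_range].to_numpy())
    # gap curves plateau past the true k; values within one reference
    # standard error of the maximum are statistically indistinguishable
    # from it and share an (average) rank, so the plateau cannot outrank
    # its own onset
    gap_vals = gap_curve.loc[k_range, "gap"].to_numpy().copy()
    se_at_max = float(gap_curve.loc[k_range, "se"].to_numpy()[np.argmax(gap_vals)])
    plateau = gap_vals >= gap_vals.max() - se_at_max
    gap_vals[plateau] = gap_vals.max()
    gap_rank = rankdata(gap_vals)
    mean_rank = (cpi_rank + gap_rank) / 2.0
    best = k_range[int(np.argmax(mean_rank))]  # argmax takes first (smaller k) on ties
    ensemble = run_base_partitions(fm, best, algorithms, seed)
    cm = consensus_matrix(ensemble)
    labels = consensus_labels(cm, best)
    s, per_cluster, mean_s = silhouette_scores(labels, cm.distance())
    return SubtypeModel(
        k=best,
        sample_ids=list(fm.sample_ids),
        labels=labels,
        consensus=cm,
        silhouette_per_sample=s,
        silhouette_per_cluster=per_cluster,
        silhouette_mean=mean_s,
        cpi_curve=cpi_curve,
        gap_curve=gap_curve,
        seed=seed,
        algorithms=tuple(algorithms),
    )
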