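"""Clustering diagnostics, cluster extraction and per-cluster statistics.

The workflow mirrors a standard hierarchical-clustering study of a species
similarity matrix:

1. clustering tendency of the data (Hopkins statistic, ~0.5 for structure-
   free data, approaching 1 for strongly clustered data);
2. choice of cluster number (average silhouette width and the within-
   cluster sum-of-squares "elbow", swept over a range of cluster counts);
3. extraction of clusters by cutting the agglomerative tree
   (average / Ward / single linkage on d = 1 - similarity);
4. per-cluster summary: min / mean / max / sd of within-cluster pairwise
   similarity and a one-sided p-value comparing within-cluster pairs to
   pairs straddling the cluster boundary (Welch t-test by default,
   Mann-Whitney U as a nonparametric alternative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, ttest_ind
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from .compare import CorrelationMatrix
from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "ClusterReport",
    "DiagnosticsReport",
    "Linkage",
    "PValueTest",
    "hopkins_statistic",
    "silhouette_sweep",
    "wss_sweep",
    "cut_clusters",
    "cluster_pvalue",
    "cluster_table",
    "kmeans_clusters",
    "pam_clusters",
]

Linkage = Literal["average", "ward", "single", "complete"]
PValueTest = Literal["welch_t", "mann_whitney"]

_LINKAGE_METHODS = {"average", "ward", "single", "complete"}
_P_FLOOR = np.nextafter(0.0, 1.0)  # p-values are reported in (0, 1]


@dataclass(frozen=True)
class ClusterReport:
    """One row of the per-cluster statistics table.

    Similarity summaries and the p-value are NaN when undefined: the sd
    needs >= 3 members (>= 2 within pairs), the similarity summaries and
    p-value need >= 2 members, and the Welch p-value additionally needs
    >= 2 within pairs.
    """

    cluster_id: int
    members: tuple[str, ...]
    min: float = math.nan
    mean: float = math.nan
    max: float = math.nan
    stdev: float = math.nan
    p_value: float = math.nan

    def __post_init__(self):
        if not self.members:
            raise InvalidInputError("cluster has no members")
        if not (math.isnan(self.min) or self.min <= self.mean <= self.max):
            raise InvalidInputError("cluster summaries must satisfy min <= mean <= max")

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class DiagnosticsReport:
    """Pre-clustering diagnostics: Hopkins plus per-k silhouette/WSS sweeps."""

    hopkins: float
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    wss_by_k: dict[int, float] = field(default_factory=dict)

    @property
    def best_k(self) -> int:
        """Cluster count with the maximum average silhouette width."""
        if not self.silhouette_by_k:
            raise InvalidInputError("no silhouette sweep available")
        return max(self.silhouette_by_k, key=lambda k: (self.silhouette_by_k[k], -k))


def _as_points(data) -> np.ndarray:
    if isinstance(data, CorrelationMatrix):
        return np.asarray(data.values, dtype=np.float64)
    X = np.asarray(data, dtype=np.float64)
    if X.ndim != 2:
        raise InvalidInputError("expected a 2-D point array or a CorrelationMatrix")
    return X


def hopkins_statistic(data, sample_fraction: float = 0.1, seed: int = 0) -> float:
    """Hopkins clustering-tendency statistic in (0, 1).

    Each matrix row is treated as a point in R^n. m = max(3,
    round(sample_fraction * n)) data points are sampled without
    replacement; the same number of reference points is drawn uniformly
    from the per-dimension bounding box of the data. With u_i the
    nearest-data distances of the reference points and w_i the
    nearest-other-data distances of the sampled points,

        H = sum(u) / (sum(u) + sum(w)).

    H ~ 0.5 for structure-free (uniform) data and approaches 1 when the
    data are strongly clustered. Deterministic given ``seed``.
    """
    X = _as_points(data)
    n = X.shape[0]
    if n < 4:
        raise InvalidInputError(f"Hopkins statistic needs >= 4 points, got {n}")
    if not 0.0 < sample_fraction <= 0.5:
        raise InvalidParameterError(f"sample_fraction must be in (0, 0.5], got {sample_fraction}")
    m = min(max(3, int(round(sample_fraction * n))), n - 1)
    rng = np.random.default_rng(seed)
    sample_idx = rng.choice(n, size=m, replace=False)
    lo, hi = X.min(axis=0), X.max(axis=0)
    ref = rng.uniform(lo, hi, size=(m, X.shape[1]))
    nn = NearestNeighbors(n_neighbors=2).fit(X)
    u = nn.kneighbors(ref, n_neighbors=1)[0][:, 0]
    w = nn.kneighbors(X[sample_idx], n_neighbors=2)[0][:, 1]
    total = u.sum() + w.sum()
    if total == 0.0:
        raise InvalidInputError("all points coincide; clustering tendency undefined")
    return float(u.sum() / total)


def linkage_matrix(matrix: CorrelationMatrix, method: Linkage = "average") -> np.ndarray:
    """SciPy linkage over d = 1 - similarity. 'average' is UPGMA."""
    if method not in _LINKAGE_METHODS:
        raise InvalidParameterError(f"unknown linkage {method!r}")
    condensed = squareform(matrix.distances(), checks=False)
    return scipy_linkage(condensed, method=method)


def cut_clusters(
    matrix: CorrelationMatrix, n_clusters: int, linkage: Linkage = "average"
) -> list[ClusterReport]:
    """Cut the agglomerative tree into exactly ``n_clusters`` groups.

    Returns membership-only reports (statistics NaN); clusters are numbered
    1..n in order of first appearance of a member in the matrix labels. The
    result is a partition: every species belongs to exactly one cluster.
    """
    n = matrix.n
    if not 1 <= n_clusters <= n:
        raise InvalidParameterError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    if n_clusters == n:
        assignment = np.arange(1, n + 1)
    elif n_clusters == 1:
        assignment = np.ones(n, dtype=int)
    else:
        Z = linkage_matrix(matrix, linkage)
        assignment = fcluster(Z, t=n_clusters, criterion="maxclust")
    # renumber by first appearance so output order is deterministic
    order: dict[int, int] = {}
    for a in assignment:
        if a not in order:
            order[a] = len(order) + 1
    reports = []
    for raw_id, new_id in sorted(order.items(), key=lambda kv: kv[1]):
        members = tuple(l for l, a in zip(matrix.labels, assignment) if a == raw_id)
        reports.append(ClusterReport(cluster_id=new_id, members=members))
    return reports


def silhouette_sweep(
    matrix: CorrelationMatrix,
    k_min: int = 2,
    k_max: int = 7,
    linkage: Linkage = "average",
) -> dict[int, float]:
    """Average silhouette width for each cluster count in [k_min, k_max].

    Clusters come from cutting the hierarchical tree; silhouettes use the
    precomputed distance d = 1 - similarity. Widths lie in [-1, 1].
    """
    n = matrix.n
    if not 2 <= k_min <= k_max:
        raise InvalidParameterError(f"need 2 <= k_min <= k_max, got ({k_min}, {k_max})")
    if k_max >= n:
        raise InvalidParameterError(f"k_max={k_max} must be < n={n}")
    D = matrix.distances()
    out: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        reports = cut_clusters(matrix, k, linkage)
        membership = {l: c.cluster_id for c in reports for l in c.members}
        labels = np.array([membership[l] for l in matrix.labels])
        out[k] = float(silhouette_score(D, labels, metric="precomputed"))
    return out


def wss_sweep(
    matrix: CorrelationMatrix,
    k_min: int = 2,
    k_max: int = 7,
    linkage: Linkage = "average",
) -> dict[int, float]:
    """Total within-cluster sum of squared distances to the cluster centroid
    (rows of the similarity matrix as points), per cluster count — the
    'elbow' diagnostic."""
    if k_max >= matrix.n:
        raise InvalidParameterError(f"k_max={k_max} must be < n={matrix.n}")
    X = matrix.values
    out: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        total = 0.0
        for rep in cut_clusters(matrix, k, linkage):
            idx = [matrix.labels.index(l) for l in rep.members]
            pts = X[idx]
            total += float(((pts - pts.mean(axis=0)) ** 2).sum())
        out[k] = total
    return out


def _pair_values(matrix: CorrelationMatrix, cluster: Sequence[str]):
    labels = matrix.labels
    members = [l for l in labels if l in set(cluster)]
    outside = [l for l in labels if l not in set(cluster)]
    mi = [labels.index(l) for l in members]
    oi = [labels.index(l) for l in outside]
    within = np.array(
        [matrix.values[a, b] for x, a in enumerate(mi) for b in mi[x + 1:]]
    )
    cross = np.array([matrix.values[a, b] for a in mi for b in oi])
    return members, within, cross


def cluster_pvalue(
    matrix: CorrelationMatrix,
    cluster: Sequence[str],
    cluster_id: int = 1,
    test: PValueTest = "welch_t",
) -> ClusterReport:
    """Summaries and significance of one cluster's internal similarity.

    The p-value is one-sided, testing that within-cluster pairwise
    similarities exceed similarities of pairs with exactly one member in
    the cluster. ``welch_t`` (default) is an unequal-variance two-sample
    t-test; ``mann_whitney`` the corresponding rank test. Singleton
    clusters have no within pairs: summaries and p are reported missing.
    """
    cluster = list(cluster)
    if not cluster:
        raise InvalidInputError("empty cluster")
    unknown = [l for l in cluster if l not in matrix.labels]
    if unknown:
        raise InvalidInputError(f"cluster members not in matrix: {unknown}")
    if len(cluster) >= matrix.n:
        raise InvalidInputError("cluster must be a proper subset of the species")
    if test not in ("welch_t", "mann_whitney"):
        raise InvalidParameterError(f"unknown test {test!r}")

    members, within, cross = _pair_values(matrix, cluster)
    if within.size == 0:
        return ClusterReport(cluster_id=cluster_id, members=tuple(members))

    sd = float(np.std(within, ddof=1)) if within.size >= 2 else math.nan
    p = math.nan
    if cross.size >= 1:
        if test == "welch_t":
            if within.size >= 2 and cross.size >= 2:
                p = float(ttest_ind(within, cross, equal_var=False, alternative="greater").pvalue)
        else:
            p = float(mannwhitneyu(within, cross, alternative="greater").pvalue)
    if not math.isnan(p):
        p = max(p, _P_FLOOR)
    return ClusterReport(
        cluster_id=cluster_id,
        members=tuple(members),
        min=float(within.min()),
        mean=float(within.mean()),
        max=float(within.max()),
        stdev=sd,
        p_value=p,
    )


def cluster_table(
    matrix: CorrelationMatrix,
    n_clusters: int,
    linkage: Linkage = "average",
    test: PValueTest = "welch_t",
) -> tuple[list[ClusterReport], pd.DataFrame]:
    """Cut into clusters and build the per-cluster statistics table.

    The DataFrame has one row per cluster with columns cluster, n_species,
    min, mean, max, stdev, p_value (NaN where undefined).
    """
    membership = cut_clusters(matrix, n_clusters, linkage)
    reports = []
    for rep in membership:
        if rep.n == matrix.n:  # single all-species cluster: no cross pairs
            _, within, _ = _pair_values(matrix, rep.members)
            reports.append(
                ClusterReport(
                    cluster_id=rep.cluster_id,
                    members=rep.members,
                    min=float(within.min()),
                    mean=float(within.mean()),
                    max=float(within.max()),
                    stdev=float(np.std(within, ddof=1)) if within.size >= 2 else math.nan,
                )
            )
        else:
            reports.append(
                cluster_pvalue(matrix, rep.members, cluster_id=rep.cluster_id, test=test)
            )
    df = pd.DataFrame(
        {
            "cluster": [r.cluster_id for r in reports],
            "n_species": [r.n for r in reports],
            "min": [r.min for r in reports],
            "mean": [r.mean for r in reports],
            "max": [r.max for r in reports],
            "stdev": [r.stdev for r in reports],
            "p_value": [r.p_value for r in reports],
        }
    )
    return reports, df


def kmeans_clusters(matrix: CorrelationMatrix, n_clusters: int, seed: int = 0) -> list[ClusterReport]:
    """Alternative extractor: k-means on the matrix rows (fixed seed)."""
    from sklearn.cluster import KMeans

    if not 1 <= n_clusters <= matrix.n:
        raise InvalidParameterError(f"n_clusters must be in [1, {matrix.n}]")
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(matrix.values)
    return _reports_from_assignment(matrix, km.labels_)


def pam_clusters(matrix: CorrelationMatrix, n_clusters: int, seed: int = 0) -> list[ClusterReport]:
    """Alternative extractor: Partitioning Around Medoids on d = 1 - similarity.

    Classic BUILD + SWAP with a deterministic seed for tie-breaking.
    """
    if not 1 <= n_clusters <= matrix.n:
        raise InvalidParameterError(f"n_clusters must be in [1, {matrix.n}]")
    D = matrix.distances()
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < n_clusters:  # BUILD: greedily add best medoid
        best_gain, best_j = -np.inf, -1
        current = D[:, medoids].min(axis=1)
        for j in range(n):
            if j in medoids:
                continue
            gain = np.maximum(current - D[:, j], 0.0).sum()
            if gain > best_gain:
                best_gain, best_j = gain, j
        medoids.append(best_j)
    improved = True
    while improved:  # SWAP until no single exchange lowers total cost
        improved = False
        assign = np.argmin(D[:, medoids], axis=1)
        cost = D[np.arange(n), [medoids[a] for a in assign]].sum()
        for mi in range(len(medoids)):
            for h in range(n):
                if h in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                tcost = D[:, trial].min(axis=1).sum()
                if tcost < cost - 1e-12:
                    medoids, cost, improved = trial, tcost, True
    assignment = np.argmin(D[:, medoids], axis=1) + 1
    return _reports_from_assignment(matrix, assignment)


def _reports_from_assignment(matrix: CorrelationMatrix, assignment) -> list[ClusterReport]:
    order: dict[int, int] = {}
    for a in assignment:
        if a not in order:
            order[int(a)] = len(order) + 1
    out = []
    for raw_id, new_id in sorted(order.items(), key=lambda kv: kv[1]):
        members = tuple(l for l, a in zip(matrix.labels, assignment) if int(a) == raw_id)
        out.append(ClusterReport(cluster_id=new_id, members=members))
    return out
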