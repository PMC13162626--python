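"""Clustering of binary omics profiles: Jaccard distance, Ward hierarchy,
silhouette widths, mutation burden, label cross-tabulation and t-SNE.

The Jaccard similarity between two binary profiles is
SJ = N11 / (N01 + N10 + N11), where Nij counts positions equal to i in the
first vector and j in the second; the distance is DJ = 1 − SJ.  Joint
absences (0-0 matches) are ignored, which suits rare events such as
mutations.  Two all-zero profiles are assigned DJ = 0 (identical emptiness),
so samples with no events cluster together rather than being undefined.

Ward agglomeration is run directly on the precomputed dissimilarities via
the Lance–Williams recurrence.  Two dialects are supported: "squared"
applies the Ward update to squared dissimilarities and reports square-root
heights (the hclust ward.D2 convention), "raw" applies it to the
dissimilarities as given (ward.D).  Ties in the merge criterion are broken
deterministically by the lexicographically smallest pair of cluster ids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "jaccard_distance",
    "Linkage",
    "ward_linkage",
    "ClusterAssignment",
    "cut_clusters",
    "SilhouetteReport",
    "silhouette",
    "BurdenSummary",
    "mutation_burden",
    "cross_tabulate",
    "tsne_embed",
]

_TIE_RTOL = 1e-8  # near-tie band for deterministic merge-pair selection


def jaccard_distance(calls: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard distances between the sample columns of a 0/1 matrix.

    Returns a symmetric sample × sample DataFrame with zero diagonal and
    entries in [0, 1].  Pairs of all-zero profiles get distance 0.
    """
    if calls.shape[1] < 2:
        raise ValidationError("at least 2 samples are required")
    b = calls.to_numpy().astype(np.float64)
    if not np.isin(b, (0.0, 1.0)).all():
        raise ValidationError("calls matrix must be binary (0/1)")
    n11 = b.T @ b
    ones = b.sum(axis=0)
    union = ones[:, None] + ones[None, :] - n11
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - n11 / union
    d[union == 0] = 0.0  # both profiles all-zero: identical emptiness
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(d, index=calls.columns, columns=calls.columns)


def _check_distance(d: pd.DataFrame) -> np.ndarray:
    arr = np.asarray(d, float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValidationError("distance matrix must be square")
    if not np.allclose(arr, arr.T, atol=1e-12):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(arr), 0.0, atol=1e-12):
        raise ValidationError("distance matrix must have a zero diagonal")
    return arr


@dataclass
class Linkage:
    """Agglomerative merge tree in scipy linkage format.

    ``merges`` has one row per merge: (id_a, id_b, height, new_size); the
    original samples are ids 0..n−1 and merge i creates id n+i.
    """

    sample_ids: pd.Index
    merges: np.ndarray
    dialect: str

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def ward_linkage(d: pd.DataFrame, dialect: str = "squared") -> Linkage:
    """Ward hierarchical clustering of a precomputed dissimilarity matrix."""
    if dialect not in ("squared", "raw"):
        raise ValidationError("dialect must be 'squared' or 'raw'")
    arr = _check_distance(d)
    n = arr.shape[0]
    if n < 2:
        raise ValidationError("at least 2 samples are required")
    # merge criterion on the working scale: squared or raw dissimilarity
    W = arr.astype(float) ** 2 if dialect == "squared" else arr.astype(float).copy()
    np.fill_diagonal(W, np.inf)
    size = np.ones(n)
    ids = np.arange(n)  # cluster id occupying each active slot
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 4))
    for step in range(n - 1):
        sub = np.where(active)[0]
        block = W[np.ix_(sub, sub)]
        m = block.min()
        cand = np.argwhere(block <= m * (1 + _TIE_RTOL) + 1e-300)
        # lexicographically smallest (id_i, id_j) among near-minimal pairs
        pairs = sorted(
            (tuple(sorted((ids[sub[i]], ids[sub[j]]))), sub[i], sub[j])
            for i, j in cand
            if i < j
        )
        _, si, sj = pairs[0]
        id_i, id_j = sorted((ids[si], ids[sj]))
        crit = W[si, sj]
        height = np.sqrt(crit) if dialect == "squared" else crit
        new_size = size[si] + size[sj]
        merges[step] = (id_i, id_j, height, new_size)
        # Lance–Williams Ward update against every other active cluster
        others = sub[(sub != si) & (sub != sj)]
        if others.size:
            sk = size[others]
            upd = (
                (size[si] + sk) * W[si, others]
                + (size[sj] + sk) * W[sj, others]
                - sk * crit
            ) / (new_size + sk)
            W[si, others] = upd
            W[others, si] = upd
        active[sj] = False
        size[si] = new_size
        ids[si] = n + step
    return Linkage(sample_ids=pd.Index(d.index), merges=merges, dialect=dialect)


@dataclass
class ClusterAssignment:
    """k-cluster cut of a dendrogram; labels 1..k by first-appearance order."""

    sample_ids: pd.Index
    labels: np.ndarray
    k: int
    linkage_heights: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValidationError(
                f"labels must cover 1..{self.k} with every cluster non-empty"
            )

    @property
    def series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.sample_ids, name="cluster")

    def members(self, label: int) -> pd.Index:
        return self.sample_ids[self.labels == label]


def cut_clusters(linkage: Linkage, k: int) -> ClusterAssignment:
    """Cut the merge tree into k clusters."""
    n = len(linkage.sample_ids)
    if not 2 <= k <= n:
        raise ValidationError(f"k must be in [2, {n}], got {k}")
    groups: dict[int, list[int]] = {i: [i] for i in range(n)}
    for step in range(n - k):
        a, b, _, _ = linkage.merges[step]
        groups[n + step] = groups.pop(int(a)) + groups.pop(int(b))
    raw = np.empty(n, int)
    for gid, members in groups.items():
        raw[members] = gid
    labels = np.zeros(n, int)
    nxt = 1
    seen: dict[int, int] = {}
    for i in range(n):  # renumber 1..k by first appearance in sample order
        if raw[i] not in seen:
            seen[raw[i]] = nxt
            nxt += 1
        labels[i] = seen[raw[i]]
    return ClusterAssignment(
        sample_ids=linkage.sample_ids,
        labels=labels,
        k=k,
        linkage_heights=linkage.heights.copy(),
    )


@dataclass
class SilhouetteReport:
    """Per-sample a(i), b(i), sw(i) plus per-cluster and overall means."""

    per_sample: pd.DataFrame  # columns: cluster, a, b, sw
    cluster_means: pd.Series
    overall_mean: float


def silhouette(d: pd.DataFrame, assignment: ClusterAssignment) -> SilhouetteReport:
    """Silhouette widths from a precomputed distance matrix.

    a(i) is the mean distance from sample i to the other members of its own
    cluster (0 for singletons), b(i) the minimum over other clusters of the
    mean distance to that cluster, and sw(i) = (b − a)/max(a, b) in [−1, 1]
    (0 when a = b or for singletons).
    """
    arr = _check_distance(d)
    if assignment.k < 2:
        raise ValidationError("silhouette needs at least 2 clusters")
    if list(d.index) != list(assignment.sample_ids):
        raise ValidationError("distance matrix and assignment sample IDs differ")
    labels = assignment.labels
    k = assignment.k
    onehot = np.equal.outer(labels, np.arange(1, k + 1)).astype(float)
    counts = onehot.sum(axis=0)
    sums = arr @ onehot  # (n, k) summed distance to each cluster
    own = labels - 1
    n = arr.shape[0]
    own_count = counts[own]
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[np.arange(n), own] / (own_count - 1)
    a[own_count == 1] = 0.0
    means = sums / counts
    means[np.arange(n), own] = np.inf
    b = means.min(axis=1)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        sw = (b - a) / denom
    sw[(denom == 0) | (own_count == 1)] = 0.0
    per_sample = pd.DataFrame(
        {"cluster": labels, "a": a, "b": b, "sw": sw}, index=assignment.sample_ids
    )
    cluster_means = per_sample.groupby("cluster")["sw"].mean()
    return SilhouetteReport(
        per_sample=per_sample,
        cluster_means=cluster_means,
        overall_mean=float(sw.mean()),
    )


@dataclass
class BurdenSummary:
    """Events (call = 1) per sample, grouped by cluster."""

    per_sample: pd.Series
    by_cluster: pd.DataFrame  # n, median, q1, q3 per cluster


def mutation_burden(calls: pd.DataFrame, assignment: ClusterAssignment) -> BurdenSummary:
    """Number of features with call 1 per sample, summarized by cluster."""
    if set(calls.columns) != set(assignment.sample_ids):
        raise ValidationError("calls matrix and assignment sample sets differ")
    counts = calls.loc[:, assignment.sample_ids].sum(axis=0).astype(int)
    counts.name = "burden"
    grouped = counts.groupby(assignment.series)
    by_cluster = grouped.agg(
        n="size",
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
    )
    return BurdenSummary(per_sample=counts, by_cluster=by_cluster)


def cross_tabulate(assignment: ClusterAssignment, labels: pd.Series) -> pd.DataFrame:
    """Cluster × annotation contingency table.

    Samples with a missing annotation are dropped; the dropped count is
    reported in the table's ``attrs["n_dropped"]`` and via a warning.
    """
    ann = labels.reindex(assignment.sample_ids)
    keep = ann.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} sample(s) without annotation")
    table = pd.crosstab(assignment.series[keep], ann[keep])
    table.attrs["n_dropped"] = n_dropped
    return table


def tsne_embed(
    d: pd.DataFrame,
    seed: int,
    perplexity: float = 30.0,
    n_iter: int = 1000,
) -> pd.DataFrame:
    """2-D t-SNE embedding of a precomputed distance matrix (visual aid only).

    Deterministic for a fixed seed.  Coordinates are arbitrary (columns T1,
    T2) and must not be used in downstream statistics.
    """
    from sklearn.manifold import TSNE

    arr = _check_distance(d)
    n = arr.shape[0]
    if n <= perplexity:
        raise ValidationError(
            f"perplexity ({perplexity}) must be smaller than the number of "
            f"samples ({n}); lower it, e.g. perplexity={(max(n - 2, 1)) / 3:.0f}"
        )
    method = "exact" if n - 1 < 3 * perplexity else "barnes_hut"
    emb = TSNE(
        n_components=2,
        metric="precomputed",
        init="random",
        random_state=int(seed),
        perplexity=perplexity,
        max_iter=n_iter,
        method=method,
    ).fit_transform(arr)
    return pd.DataFrame(emb, index=d.index, columns=["T1", "T2"])
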