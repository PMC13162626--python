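"""Cluster characterization: event frequencies, chi-squared tests, gene-wise
ANOVA on ν-values, FDR control, the joint gene-selection filter, cluster
allocation, pairwise contrast selection and gene-list export.

Two chi-squared views are provided.  The one-vs-rest test puts each
(feature, cluster) pair into a 2×2 table {in-cluster, rest} × {present,
absent} and is used for per-cluster enrichment listings.  The across-cluster
test uses the full 2×k table per feature and, together with a one-way ANOVA
on the continuous ν-values, drives the joint selection filter: a gene is
selected when both tests give p < 0.01 and the gene is abnormal in at least
10% of all samples; each selected gene is then allocated to the cluster
contributing the largest share of its abnormal samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterAssignment
from .io import ValidationError

__all__ = [
    "FeatureFrequencyTable",
    "feature_frequencies",
    "chisq_one_vs_rest",
    "chisq_across_clusters",
    "anova_nu",
    "fdr_adjust",
    "GeneSelectionResult",
    "select_cluster_genes",
    "contrast_select",
    "export_gene_lists",
]


def _cluster_counts(calls: pd.DataFrame, assignment: ClusterAssignment):
    """Per-feature per-cluster counts of call == 1 plus totals."""
    if list(calls.columns) != list(assignment.sample_ids):
        calls = calls.loc[:, assignment.sample_ids]
    x = calls.to_numpy().astype(float)
    k = assignment.k
    onehot = np.equal.outer(assignment.labels, np.arange(1, k + 1)).astype(float)
    x1 = x @ onehot  # (features, k)
    n_c = onehot.sum(axis=0)
    tot1 = x.sum(axis=1)
    return x1, n_c, tot1, x.shape[1]


@dataclass
class FeatureFrequencyTable:
    """Presence fractions (%) per feature, overall and per cluster."""

    frequencies: pd.DataFrame  # columns: overall, cluster_1..cluster_k (%)
    top: pd.DataFrame  # columns: cluster, rank, feature, pct
    cluster_sizes: pd.Series


def feature_frequencies(
    calls: pd.DataFrame, assignment: ClusterAssignment, top_k: int = 5
) -> FeatureFrequencyTable:
    """Per-cluster presence fractions and the top features of each cluster.

    Ties in the per-cluster ranking are broken alphabetically by feature ID.
    """
    x1, n_c, tot1, n = _cluster_counts(calls, assignment)
    k = assignment.k
    freq = pd.DataFrame(
        100.0 * x1 / n_c, index=calls.index, columns=[f"cluster_{c}" for c in range(1, k + 1)]
    )
    freq.insert(0, "overall", 100.0 * tot1 / n)
    rows = []
    for c in range(1, k + 1):
        col = freq[f"cluster_{c}"].sort_index()  # alphabetical tie-break
        top = col.sort_values(ascending=False, kind="stable").head(top_k)
        for rank, (feat, pct) in enumerate(top.items(), start=1):
            rows.append((c, rank, feat, pct))
    top = pd.DataFrame(rows, columns=["cluster", "rank", "feature", "pct"])
    sizes = pd.Series(n_c.astype(int), index=range(1, k + 1), name="n")
    return FeatureFrequencyTable(frequencies=freq, top=top, cluster_sizes=sizes)


def chisq_one_vs_rest(
    calls: pd.DataFrame,
    assignment: ClusterAssignment,
    correction: bool = False,
) -> pd.DataFrame:
    """Pearson chi-squared on the 2×2 {in-cluster, rest} × {1, 0} table for
    every (feature, cluster) pair.

    No continuity correction by default.  A feature with zero variance
    overall yields statistic 0 and p = 1.  ``enriched`` flags pairs whose
    in-cluster frequency exceeds the overall frequency.

    Returns a long-form DataFrame with columns feature, cluster, n11, n10,
    n01, n00, chi2, p, enriched.
    """
    x1, n_c, tot1, n = _cluster_counts(calls, assignment)
    k = assignment.k
    a = x1  # present, in cluster
    b = n_c[None, :] - x1  # absent, in cluster
    c = tot1[:, None] - x1  # present, rest
    dd = (n - n_c)[None, :] - c  # absent, rest
    r1 = tot1[:, None]
    r2 = n - r1
    c1 = np.broadcast_to(n_c[None, :], a.shape)
    c2 = n - c1
    num = np.abs(a * dd - b * c)
    if correction:
        num = np.maximum(num - n / 2.0, 0.0)
    denom = r1 * r2 * c1 * c2
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = n * num**2 / denom
    degenerate = (r1 == 0) | (r2 == 0)
    chi2 = np.where(np.broadcast_to(degenerate, chi2.shape), 0.0, chi2)
    p = stats.chi2.sf(chi2, df=1)
    p = np.where(chi2 == 0.0, 1.0, p)
    enriched = (a / c1) > (r1 / n)
    idx = pd.MultiIndex.from_product(
        [calls.index, range(1, k + 1)], names=["feature", "cluster"]
    )
    out = pd.DataFrame(
        {
            "n11": a.ravel().astype(int),
            "n10": b.ravel().astype(int),
            "n01": c.ravel().astype(int),
            "n00": dd.ravel().astype(int),
            "chi2": chi2.ravel(),
            "p": p.ravel(),
            "enriched": enriched.ravel(),
        },
        index=idx,
    ).reset_index()
    return out


def chisq_across_clusters(
    calls: pd.DataFrame, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Per-feature Pearson chi-squared on the 2×k {1, 0} × clusters table
    (df = k − 1); degenerate features (all 0 or all 1) get statistic 0, p = 1.
    """
    x1, n_c, tot1, n = _cluster_counts(calls, assignment)
    k = assignment.k
    e1 = tot1[:, None] * n_c[None, :] / n
    e0 = (n - tot1)[:, None] * n_c[None, :] / n
    o0 = n_c[None, :] - x1
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = ((x1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0).sum(axis=1)
    degenerate = (tot1 == 0) | (tot1 == n)
    chi2 = np.where(degenerate, 0.0, chi2)
    p = stats.chi2.sf(chi2, df=k - 1)
    p = np.where(degenerate, 1.0, p)
    return pd.DataFrame({"chi2": chi2, "p": p, "df": k - 1}, index=calls.index)


def anova_nu(nu: pd.DataFrame, assignment: ClusterAssignment) -> pd.DataFrame:
    """Gene-by-gene one-way fixed-effects ANOVA of ν-values across clusters.

    F = MS_between / MS_within with (k − 1, n − k) degrees of freedom.  Genes
    with zero within-cluster variance but unequal cluster means are flagged
    degenerate and reported with p = 0.
    """
    if list(nu.columns) != list(assignment.sample_ids):
        nu = nu.loc[:, assignment.sample_ids]
    x = nu.to_numpy(float)
    k = assignment.k
    n = x.shape[1]
    if k < 2:
        raise ValidationError("ANOVA needs at least 2 clusters")
    if n <= k:
        raise ValidationError("ANOVA needs more samples than clusters")
    onehot = np.equal.outer(assignment.labels, np.arange(1, k + 1)).astype(float)
    n_c = onehot.sum(axis=0)
    group_mean = (x @ onehot) / n_c
    grand = x.mean(axis=1)
    ssb = (n_c[None, :] * (group_mean - grand[:, None]) ** 2).sum(axis=1)
    ssw = ((x - group_mean[:, assignment.labels - 1]) ** 2).sum(axis=1)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = msb / msw
    degenerate = (msw == 0) & (msb > 0)
    f = np.where((msw == 0) & (msb == 0), 0.0, f)
    p = np.where(
        degenerate, 0.0, stats.f.sf(np.where(degenerate, np.inf, f), k - 1, n - k)
    )
    p = np.where((msw == 0) & (msb == 0), 1.0, p)
    return pd.DataFrame(
        {"F": f, "p": p, "degenerate": degenerate}, index=nu.index
    )


def fdr_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values (capped at 1)."""
    p = np.asarray(p, float)
    if p.size and ((p < 0).any() or (p > 1).any() or ~np.isfinite(p).all()):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeneSelectionResult:
    """Joint-filter selection with per-gene cluster allocation."""

    table: pd.DataFrame  # per selected gene: p-values, overall_frac, cluster, tie
    per_cluster: dict[int, list[str]] = field(default_factory=dict)
    p_cut: float = 0.01
    min_frac: float = 0.10

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def select_cluster_genes(
    chisq: pd.DataFrame,
    anova: pd.DataFrame,
    calls: pd.DataFrame,
    assignment: ClusterAssignment,
    p_cut: float = 0.01,
    min_frac: float = 0.10,
) -> GeneSelectionResult:
    """Select genes strongly associated with individual clusters.

    A gene is selected iff its across-cluster chi-squared p < ``p_cut`` AND
    its ANOVA p < ``p_cut`` AND it is abnormal (call 1) in at least
    ``min_frac`` of all samples.  Each selected gene is allocated to the
    cluster contributing the largest share of its abnormal samples; ties go
    to the lowest cluster index and are flagged.

    ``chisq`` and ``anova`` are the outputs of :func:`chisq_across_clusters`
    and :func:`anova_nu` on the same genes.
    """
    genes = calls.index
    if not (genes.equals(chisq.index) and genes.equals(anova.index)):
        raise ValidationError("chisq, anova and calls must cover the same genes")
    x1, n_c, tot1, n = _cluster_counts(calls, assignment)
    overall_frac = tot1 / n
    selected = (
        (chisq["p"].to_numpy() < p_cut)
        & (anova["p"].to_numpy() < p_cut)
        & (overall_frac >= min_frac)
    )
    counts = x1[selected]
    best = counts.max(axis=1, initial=0.0)
    alloc = counts.argmax(axis=1) + 1  # lowest cluster index on ties
    tie = (counts == best[:, None]).sum(axis=1) > 1
    table = pd.DataFrame(
        {
            "chisq_p": chisq["p"].to_numpy()[selected],
            "anova_p": anova["p"].to_numpy()[selected],
            "overall_frac": overall_frac[selected],
            "cluster": alloc,
            "tie": tie,
        },
        index=genes[selected],
    )
    per_cluster = {
        c: sorted(table.index[table["cluster"] == c]) for c in range(1, assignment.k + 1)
    }
    return GeneSelectionResult(
        table=table, per_cluster=per_cluster, p_cut=p_cut, min_frac=min_frac
    )


def contrast_select(
    selection: GeneSelectionResult,
    nu: pd.DataFrame,
    assignment: ClusterAssignment,
    pair: tuple[int, int],
) -> list[str]:
    """Genes distinguishing a pair of clusters.

    Keeps the selected genes allocated to either cluster of the pair whose
    per-cluster mean ν attains its maximum or its minimum (over all k
    clusters) in one of the two clusters.
    """
    c1, c2 = pair
    for c in pair:
        if not 1 <= c <= assignment.k:
            raise ValidationError(f"cluster {c} does not exist (k={assignment.k})")
    if not len(selection.table):
        return []
    sub = selection.table[selection.table["cluster"].isin(pair)]
    if not len(sub):
        return []
    x = nu.loc[sub.index, assignment.sample_ids].to_numpy(float)
    k = assignment.k
    onehot = np.equal.outer(assignment.labels, np.arange(1, k + 1)).astype(float)
    means = (x @ onehot) / onehot.sum(axis=0)
    hi = means.argmax(axis=1) + 1
    lo = means.argmin(axis=1) + 1
    keep = np.isin(hi, pair) | np.isin(lo, pair)
    return list(sub.index[keep])


def export_gene_lists(selection: GeneSelectionResult, out_dir: str | Path) -> list[Path]:
    """Write one plain-text file per cluster (one gene symbol per line, sorted).

    Suitable for upload to external enrichment services.  An empty selection
    writes nothing and warns.
    """
    if not len(selection.table):
        warnings.warn("empty gene selection; no files written")
        return []
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for c, genes in selection.per_cluster.items():
        if not genes:
            continue
        path = out_dir / f"cluster_{c}.txt"
        path.write_text("\n".join(genes) + "\n")
        paths.append(path)
    return paths
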