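"""Synthetic expression and mutation cohorts with known ground truth.

The generator realizes exactly the structure the bank-standardization method
assumes, so every pipeline stage can be tested without external data:

* a smooth SD-vs-mean relationship in normal samples,
  σ(m) = σ0 + σ1·exp(−m/τ), on a log-like expression scale;
* tissue-specific baseline expression (each cohort draws its own per-gene
  means), which per-cohort bank standardization is designed to remove;
* planted sample clusters that cross cohort boundaries, each marked by its
  own set of outlier genes shifted by ±δ bank-SD units (random but
  cluster-consistent sign per gene);
* cluster-specific driver mutations over a Bernoulli passenger background;
* a hypermutated (MSI-like) subgroup with a greatly elevated per-gene
  mutation rate, and a subgroup with no mutations at all.

Dimensions default to a desk-scale study: 5,000 expression genes, 563
mutation genes, 2 cohorts × 200 tumors with banks of 20 normals, 4 planted
clusters of 100 tumors with 100 outlier genes each at δ = 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import ValidationError

__all__ = [
    "CohortSpec",
    "ClusterSpec",
    "HypermutatorSpec",
    "MutationConfig",
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_mutations",
    "null_cohort",
]


@dataclass
class CohortSpec:
    name: str
    n_tumor: int = 200
    n_normal: int = 20


@dataclass
class ClusterSpec:
    """One planted cluster: its outlier gene set size and shift in SD units."""

    cluster_id: int
    n_outlier_genes: int = 100
    delta: float = 5.0


@dataclass
class HypermutatorSpec:
    n_samples: int = 40
    rate: float = 0.18  # per-gene mutation probability


@dataclass
class MutationConfig:
    n_genes: int = 563
    drivers_per_cluster: int = 10
    p_driver: float = 0.7
    p_background: float = 0.02
    hypermutator: HypermutatorSpec = field(default_factory=HypermutatorSpec)
    n_zero_mutation_samples: int = 25
    n_shared_drivers: int = 0  # drivers deliberately shared by all clusters


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohorts (see module docstring)."""

    n_genes: int = 5000
    cohorts: list[CohortSpec] = field(
        default_factory=lambda: [CohortSpec("tissueA"), CohortSpec("tissueB")]
    )
    sd_sigma0: float = 0.1
    sd_sigma1: float = 0.5
    sd_tau: float = 4.0
    mean_range: tuple[float, float] = (2.0, 12.0)
    planted_clusters: list[ClusterSpec] = field(
        default_factory=lambda: [ClusterSpec(c) for c in range(1, 5)]
    )
    mutation: MutationConfig = field(default_factory=MutationConfig)

    def sd_curve(self, m):
        """True generating SD as a function of the mean."""
        return self.sd_sigma0 + self.sd_sigma1 * np.exp(-np.asarray(m, float) / self.sd_tau)

    def validate(self) -> None:
        mut = self.mutation
        for rate in (mut.p_driver, mut.p_background, mut.hypermutator.rate):
            if not 0 <= rate <= 1:
                raise ValidationError("mutation rates must lie in [0, 1]")
        for cl in self.planted_clusters:
            if cl.delta <= 0:
                raise ValidationError("outlier shift delta must be > 0")
            if cl.n_outlier_genes <= 0:
                raise ValidationError("outlier gene set size must be positive")
        if sum(c.n_outlier_genes for c in self.planted_clusters) > self.n_genes:
            raise ValidationError("outlier gene sets exceed the gene pool")
        if any(c.n_tumor <= 0 or c.n_normal < 0 for c in self.cohorts):
            raise ValidationError("cohort sizes must be positive")
        lo, hi = self.mean_range
        if not np.all(self.sd_curve(np.linspace(lo, hi, 64)) > 0):
            raise ValidationError("sd curve must be positive over mean_range")
        n_driver_genes = mut.n_shared_drivers + len(self.planted_clusters) * (
            mut.drivers_per_cluster - mut.n_shared_drivers
        )
        if mut.drivers_per_cluster < mut.n_shared_drivers:
            raise ValidationError("n_shared_drivers exceeds drivers_per_cluster")
        if n_driver_genes > mut.n_genes:
            raise ValidationError("driver gene assignments exceed the mutation gene pool")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["cohorts"] = [CohortSpec(**c) for c in data.get("cohorts", [])]
        data["planted_clusters"] = [
            ClusterSpec(**c) for c in data.get("planted_clusters", [])
        ]
        mut = data.get("mutation", {})
        if "hypermutator" in mut:
            mut["hypermutator"] = HypermutatorSpec(**mut["hypermutator"])
        data["mutation"] = MutationConfig(**mut)
        if "mean_range" in data:
            data["mean_range"] = tuple(data["mean_range"])
        return cls(**data)


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    clusters: pd.Series  # tumor sample -> planted cluster id (0 = none)
    outlier_genes: dict[int, list[str]] = field(default_factory=dict)
    driver_genes: dict[int, list[str]] = field(default_factory=dict)
    hypermutators: list[str] = field(default_factory=list)
    zero_mutation: list[str] = field(default_factory=list)


def _gene_ids(n: int, prefix: str = "G") -> pd.Index:
    width = len(str(n))
    return pd.Index([f"{prefix}{i:0{width}d}" for i in range(1, n + 1)], name="gene_id")


def _plan(config: SimulationConfig):
    """Deterministic sample naming and planted-cluster membership.

    Tumors of each cohort are split as evenly as possible across the planted
    clusters in contiguous blocks, so clusters span cohorts by construction.
    """
    tumor_ids, normal_ids, cohort_of = [], [], {}
    cluster_of: dict[str, int] = {}
    n_cl = len(config.planted_clusters)
    for spec in config.cohorts:
        bounds = np.linspace(0, spec.n_tumor, n_cl + 1).astype(int) if n_cl else None
        for i in range(spec.n_tumor):
            sid = f"{spec.name}-T{i + 1:03d}"
            tumor_ids.append(sid)
            cohort_of[sid] = spec.name
            if n_cl:
                block = int(np.searchsorted(bounds[1:], i, side="right"))
                cluster_of[sid] = config.planted_clusters[block].cluster_id
            else:
                cluster_of[sid] = 0
        for i in range(spec.n_normal):
            sid = f"{spec.name}-N{i + 1:03d}"
            normal_ids.append(sid)
            cohort_of[sid] = spec.name
    return tumor_ids, normal_ids, cohort_of, cluster_of


def _streams(seed: int):
    expr_ss, mut_ss, grp_ss = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(expr_ss),
        np.random.default_rng(mut_ss),
        np.random.default_rng(grp_ss),
    )


def simulate_expression(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a gene × sample expression matrix, its manifest and truth.

    Normal samples are Gaussian around cohort-specific per-gene means with
    SD σ(mean); tumors are drawn from the same distribution except that the
    genes in their planted cluster's outlier set are shifted by ±δ·σ.
    """
    config.validate()
    rng, _, _ = _streams(seed)
    genes = _gene_ids(config.n_genes)
    tumor_ids, normal_ids, cohort_of, cluster_of = _plan(config)

    # disjoint outlier gene sets per planted cluster, with cluster-consistent
    # random shift signs per gene
    perm = rng.permutation(config.n_genes)
    outlier_idx: dict[int, np.ndarray] = {}
    signs: dict[int, np.ndarray] = {}
    pos = 0
    for spec in config.planted_clusters:
        outlier_idx[spec.cluster_id] = perm[pos : pos + spec.n_outlier_genes]
        signs[spec.cluster_id] = rng.choice([-1.0, 1.0], spec.n_outlier_genes)
        pos += spec.n_outlier_genes
    deltas = {s.cluster_id: s.delta for s in config.planted_clusters}

    lo, hi = config.mean_range
    columns: dict[str, np.ndarray] = {}
    for spec in config.cohorts:
        mu = rng.uniform(lo, hi, config.n_genes)
        sd = config.sd_curve(mu)
        coh_normals = [s for s in normal_ids if cohort_of[s] == spec.name]
        coh_tumors = [s for s in tumor_ids if cohort_of[s] == spec.name]
        draws = rng.normal(
            mu[:, None], sd[:, None], (config.n_genes, len(coh_normals) + len(coh_tumors))
        )
        for j, sid in enumerate(coh_normals):
            columns[sid] = draws[:, j]
        for j, sid in enumerate(coh_tumors):
            col = draws[:, len(coh_normals) + j]
            c = cluster_of[sid]
            if c in outlier_idx:
                gi = outlier_idx[c]
                col = col.copy()
                col[gi] += signs[c] * deltas[c] * sd[gi]
            columns[sid] = col

    order = normal_ids + tumor_ids
    matrix = pd.DataFrame(
        np.column_stack([columns[s] for s in order]), index=genes, columns=order
    )
    manifest = pd.DataFrame(
        {
            "cohort": [cohort_of[s] for s in order],
            "status": ["normal"] * len(normal_ids) + ["tumor"] * len(tumor_ids),
            "histology": pd.NA,
        },
        index=pd.Index(order, name="sample_id"),
    )
    truth = GroundTruth(
        clusters=pd.Series({s: cluster_of[s] for s in tumor_ids}, name="cluster"),
        outlier_genes={c: list(genes[idx]) for c, idx in outlier_idx.items()},
    )
    return matrix, manifest, truth


def simulate_mutations(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the binary mutation matrix for the same tumor samples.

    Background calls are Bernoulli(p_background); each planted cluster's
    driver genes are Bernoulli(p_driver) within that cluster; hypermutator
    samples replace all their calls with the elevated rate; zero-mutation
    samples are entirely wild-type.  With the same seed the sample naming,
    cluster membership and subgroup lists match :func:`simulate_expression`.
    """
    config.validate()
    _, rng, grng = _streams(seed)
    mut = config.mutation
    genes = _gene_ids(mut.n_genes, prefix="MG")
    tumor_ids, _, _, cluster_of = _plan(config)
    n = len(tumor_ids)
    labels = np.array([cluster_of[s] for s in tumor_ids])

    # driver gene assignment: an optional block shared by every cluster,
    # then disjoint cluster-private blocks
    perm = rng.permutation(mut.n_genes)
    shared = perm[: mut.n_shared_drivers]
    pos = mut.n_shared_drivers
    driver_idx: dict[int, np.ndarray] = {}
    for spec in config.planted_clusters:
        private = perm[pos : pos + mut.drivers_per_cluster - mut.n_shared_drivers]
        pos += mut.drivers_per_cluster - mut.n_shared_drivers
        driver_idx[spec.cluster_id] = np.concatenate([shared, private])

    calls = (rng.random((mut.n_genes, n)) < mut.p_background).astype(np.int8)
    for c, gi in driver_idx.items():
        cols = np.where(labels == c)[0]
        if cols.size and gi.size:
            calls[np.ix_(gi, cols)] = (
                rng.random((gi.size, cols.size)) < mut.p_driver
            ).astype(np.int8)

    n_hyper = min(mut.hypermutator.n_samples, n)
    hyper = list(grng.choice(tumor_ids, n_hyper, replace=False)) if n_hyper else []
    rest = [s for s in tumor_ids if s not in set(hyper)]
    n_zero = min(mut.n_zero_mutation_samples, len(rest))
    zero = list(grng.choice(rest, n_zero, replace=False)) if n_zero else []

    col_of = {s: j for j, s in enumerate(tumor_ids)}
    if hyper:
        hi = [col_of[s] for s in hyper]
        calls[:, hi] = (
            rng.random((mut.n_genes, len(hi))) < mut.hypermutator.rate
        ).astype(np.int8)
    if zero:
        calls[:, [col_of[s] for s in zero]] = 0

    frame = pd.DataFrame(calls, index=genes, columns=tumor_ids)
    frame.attrs["origin"] = "mutation"
    truth = GroundTruth(
        clusters=pd.Series({s: cluster_of[s] for s in tumor_ids}, name="cluster"),
        driver_genes={c: list(genes[gi]) for c, gi in driver_idx.items()},
        hypermutators=hyper,
        zero_mutation=zero,
    )
    return frame, truth


def null_cohort(
    config: SimulationConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression cohort with no planted structure: tumors are drawn from
    exactly the banks' generating distributions (3-SD calibration harness)."""
    import dataclasses

    null_cfg = dataclasses.replace(config, planted_clusters=[])
    matrix, manifest, _ = simulate_expression(null_cfg, seed)
    return matrix, manifest
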