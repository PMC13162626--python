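import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import newmanbank as nb

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# Tumor/normal sample counts per digestive-tract cohort of the reference
# study (colon, esophagus, head-and-neck, pancreas, rectum, stomach).
COHORT_COUNTS = {
    "COAD": (279, 41),
    "ESCA": (183, 11),
    "HNSC": (500, 44),
    "PAAD": (171, 4),
    "READ": (92, 10),
    "STAD": (410, 35),
}


def build_cohort_manifest(counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Manifest frame with the given per-cohort (tumor, normal) counts."""
    rows = []
    for cohort, (n_tumor, n_normal) in counts.items():
        rows += [(f"{cohort}-T{i:04d}", cohort, "tumor") for i in range(n_tumor)]
        rows += [(f"{cohort}-N{i:04d}", cohort, "normal") for i in range(n_normal)]
    df = pd.DataFrame(rows, columns=["sample_id", "cohort", "status"])
    df["histology"] = pd.NA
    return df


@pytest.fixture(scope="session")
def small_config() -> nb.SimulationConfig:
    """Desk-scale study conditions shared by unit tests."""
    return nb.SimulationConfig(
        n_genes=800,
        cohorts=[nb.CohortSpec("tisA", 60, 15), nb.CohortSpec("tisB", 60, 15)],
        planted_clusters=[nb.ClusterSpec(c, n_outlier_genes=40, delta=5.0) for c in (1, 2, 3)],
        mutation=nb.MutationConfig(
            n_genes=120,
            drivers_per_cluster=6,
            hypermutator=nb.HypermutatorSpec(n_samples=12, rate=0.18),
            n_zero_mutation_samples=8,
        ),
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    expr, manifest, truth = nb.simulate_expression(small_config, seed=11)
    return expr, manifest, truth


@pytest.fixture(scope="session")
def small_mutations(small_config):
    return nb.simulate_mutations(small_config, seed=11)


def random_assignment(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Random labels 1..k with every cluster guaranteed non-empty."""
    labels = rng.integers(1, k + 1, size=n)
    labels[:k] = np.arange(1, k + 1)
    return labels


def silhouette_bruteforce(d: np.ndarray, labels: np.ndarray):
    """Double-loop silhouette oracle: a(i), b(i), sw(i) from first principles."""
    n = len(labels)
    a = np.zeros(n)
    b = np.zeros(n)
    sw = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        a[i] = np.mean([d[i, j] for j in own]) if own else 0.0
        others = []
        for c in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == c]
            others.append(np.mean([d[i, j] for j in members]))
        b[i] = min(others)
        denom = max(a[i], b[i])
        sw[i] = 0.0 if (denom == 0 or not own) else (b[i] - a[i]) / denom
    return a, b, sw


def jaccard_bruteforce(calls: np.ndarray) -> np.ndarray:
    """Direct N11/N10/N01 counting oracle over sample columns."""
    n = calls.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            u = calls[:, i].astype(bool)
            v = calls[:, j].astype(bool)
            n11 = int((u & v).sum())
            n10 = int((u & ~v).sum())
            n01 = int((~u & v).sum())
            tot = n11 + n10 + n01
            d[i, j] = 0.0 if tot == 0 else 1.0 - n11 / tot
    return d


def ward_bruteforce(d: np.ndarray, dialect: str) -> np.ndarray:
    """Exhaustive greedy Ward oracle.

    At every step, the merge cost of two clusters is recomputed from scratch
    from the original dissimilarities via the within-cluster dispersion
    identity ESS(C) = (1/|C|) * sum of pairwise dissimilarities inside C
    (on the squared scale for the "squared" dialect); the pair minimizing
    the dispersion increase is merged, near-ties broken by smallest ids.
    """
    D = d.astype(float) ** 2 if dialect == "squared" else d.astype(float).copy()
    n = D.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}

    def ess(members: list[int]) -> float:
        return D[np.ix_(members, members)].sum() / (2 * len(members))

    merges = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        ids = sorted(clusters)
        costs = {}
        for x in range(len(ids)):
            for y in range(x + 1, len(ids)):
                i, j = ids[x], ids[y]
                costs[(i, j)] = (
                    ess(clusters[i] + clusters[j]) - ess(clusters[i]) - ess(clusters[j])
                )
        m = min(costs.values())
        band = m * (1 + 1e-8) + 1e-300
        i, j = sorted(k for k, v in costs.items() if v <= band)[0]
        crit = 2.0 * costs[(i, j)]
        height = np.sqrt(max(crit, 0.0)) if dialect == "squared" else crit
        members = clusters.pop(i) + clusters.pop(j)
        merges[step] = (i, j, height, len(members))
        clusters[next_id] = members
        next_id += 1
    return merges
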