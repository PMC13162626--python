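# newmanbank

Pan-cancer clustering of tumor transcriptomes is notoriously dominated by
the cell or tissue of origin: clusters recapitulate anatomy rather than the
driver biology one hopes to target. `newmanbank` implements the *Newman
bank test* approach to removing that signal. Tumor gene expression is
standardized against a "bank" of tissue-matched normal samples, using an
**independent** per-gene estimate of the standard deviation obtained by
loess-smoothing the bank's SD-vs-mean relationship, so that even very small
banks (a handful of normals) give usable SD estimates by borrowing strength
across genes with similar means. For gene *g* in tumor sample *s*:

```
nu(g, s) = (x(g, s) − MeanBank(g)) / SDBank(g)
```

ν is measured in normal-SD units. Dichotomizing at a threshold (default 3:
|ν| ≤ 3 → 0 "within the normal range", |ν| > 3 → 1 "outside it") yields a
binary outlier matrix — "Newmanization". Binary profiles (Newmanized
expression or mutation calls) are then clustered with the **Jaccard
distance** D_J = 1 − N11/(N01 + N10 + N11), which ignores uninformative 0-0
matches, under **Ward hierarchical clustering**, and the clusterings are
characterized with silhouette widths sw(i) = (b(i) − a(i))/max(a(i), b(i)),
per-feature chi-squared tests, gene-wise ANOVA on the ν-values,
Benjamini–Hochberg FDR control and a joint gene-selection filter
(both p < 0.01 and ≥ 10% of samples abnormal).

The package is aimed at computational biologists analyzing tumor cohorts
with matched normals (e.g. TCGA-style expression plus binarized mutation
matrices). It ships a first-class synthetic-cohort generator with planted
ground truth — tissue-specific baselines, a smooth SD-vs-mean noise law,
tissue-crossing outlier clusters, driver/passenger mutations, an MSI-like
hypermutated subgroup and a zero-mutation subgroup — so every stage of the
pipeline is testable end to end.

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
import newmanbank as nb

config = nb.SimulationConfig()          # 5000 genes, 2 tissues x 200 tumors,
expr, manifest, truth = nb.simulate_expression(config, seed=1)  # 4 clusters

nu, calls, banks = nb.newmanize_cohorts(expr, manifest)
print(calls.to_numpy().mean())          # 0.0232

d = nb.jaccard_distance(calls)
assignment = nb.cut_clusters(nb.ward_linkage(d), k=4)
print(adjusted_rand_score(truth.clusters.loc[assignment.sample_ids],
                          assignment.labels))   # 1.0
print(nb.silhouette(d, assignment).overall_mean)  # 0.700
```

The flagged fraction 0.0232 is the planted outlier signal on top of the
Gaussian 3-SD chance rate 2·(1−Φ(3)) ≈ 0.0027; the adjusted Rand index of
1.0 says the planted tissue-crossing clusters are recovered exactly, and
the mean silhouette width 0.70 says the binary profiles form tight,
well-separated clusters. The `examples/` directory has one short script
per capability (simulation, standardize-and-cluster, mutation burden, gene
selection); each prints the numbers above and explains them. A thin CLI
(`newmanbank simulate|fit-bank|transform|dichotomize|newmanize|cluster|
silhouette|embed|associate`) wraps the same functions for shell use; all
files are plain TSV.

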