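# Methods

## Model and procedure

### Bank standardization (the Newman bank test)

For each tissue cohort, the *bank* is the set of that cohort's normal
samples. The bank supplies, per gene *g*:

* `MeanBank(g)` — the sample mean over bank samples;
* `SDBank(g)` — an *independent* SD estimate: the per-gene raw sample SDs
  (ddof = 1) are regressed on the per-gene means with a loess smoother, and
  `SDBank(g)` is the fitted curve evaluated at gene *g*'s own bank mean.

The smoothing exploits the empirical regularity that, on a log-like
(roughly variance-stabilized) expression scale, the SD of gene expression
is a smooth function of the mean. Because the curve pools thousands of
genes, the SD estimate is far more stable than the raw per-gene SD when the
bank is small (banks of 4–20 normals are realistic), and it is nearly
independent of any single gene's own sampling noise — the property the
studentized-range logic behind the statistic requires. A tumor value
standardizes to ν(g, s) = (x(g, s) − MeanBank(g)) / SDBank(g), and the
binary call is 1 iff |ν| > threshold. Per-cohort standardization removes
exactly the average normal-tissue expression signal and nothing else, which
is what lets clusters cross tissue boundaries downstream.

Input expression must already be on a log-like scale; the package does not
transform units, and missing values are rejected rather than imputed.

### Clustering of binary profiles

Sample–sample distances are Jaccard: D_J = 1 − N11/(N01 + N10 + N11),
ignoring 0-0 matches. Two all-zero profiles get D_J = 0 ("identical
emptiness"): the formula itself gives such samples distance 1 to every
sample with events, so a cohort's no-mutation samples form a tight group
rather than an undefined one. With this convention the triangle inequality
still holds (verified exhaustively for short vectors).

Ward agglomeration runs directly on the precomputed dissimilarities via the
Lance–Williams recurrence. Because "Ward on a dissimilarity matrix" has two
common dialects in the field's software, both are provided:

* `squared` (default) — the update is applied to squared dissimilarities
  and heights are reported on the square-root scale (the hclust `ward.D2`
  convention, also what scipy's `ward` computes);
* `raw` — the update is applied to the dissimilarities as given
  (`ward.D`).

Merge ties are broken deterministically by the lexicographically smallest
pair of cluster ids; near-ties within a 1e-8 relative band of the step
minimum are treated as exact ties so that mathematically equal criteria are
resolved identically regardless of floating-point evaluation order. Cutting
the tree at *k* renumbers clusters 1..k by first appearance in sample
order. *k* is a visible parameter (default 6, one per disease category in
the motivating design); no automatic selection is attempted beyond
reporting mean silhouette widths.

Silhouette widths use the standard definitions on the precomputed
distances, with sw = 0 for singleton clusters. t-SNE (perplexity 30, 1000
iterations, seeded) is strictly a visualization aid; its coordinates never
feed any statistic.

### Cluster characterization

* Per-feature presence frequencies per cluster, with top-*k* listings
  (ties broken alphabetically).
* One-vs-rest chi-squared: Pearson statistic on the 2×2
  {in-cluster, rest} × {present, absent} table, 1 df, no continuity
  correction by default (the motivating cohort sizes are in the hundreds;
  Yates correction is available as a flag). Enrichment is flagged only when
  the in-cluster frequency exceeds the overall frequency.
* Across-cluster chi-squared: Pearson statistic on the 2×k table, k−1 df.
  Degenerate features (all-0 or all-1) get statistic 0, p = 1 in both
  tests.
* Gene-wise one-way fixed-effects ANOVA on the ν-values across cluster
  labels; zero within-cluster variance with unequal means is reported as
  p = 0 with a degeneracy flag.
* FDR control is Benjamini–Hochberg.
* Joint selection filter: a gene is selected iff the across-cluster
  chi-squared p < 0.01 AND the ANOVA p < 0.01 AND the gene is abnormal in
  ≥ 10% of all samples. Each selected gene is allocated to the cluster
  contributing the largest share of its abnormal samples; ties go to the
  lowest cluster index and are flagged. The across-cluster (2×k) test is
  the one used for selection; the one-vs-rest test serves the per-cluster
  enrichment listings.
* Pairwise contrast: for a cluster pair, keep the selected genes allocated
  to either cluster whose per-cluster mean ν attains its overall maximum or
  minimum in one of the two.
* Gene lists are exported one file per cluster, sorted, one symbol per
  line, for external enrichment services; no enrichment is computed here.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `threshold` | 3 | bank-SD units | two-sided normal-range cutoff; boundary counts as normal (|ν| ≤ t → 0) |
| `k` | 6 | clusters | one per disease category in the motivating design; always explicit |
| `loess_span` | 0.5 | fraction of genes | mean–SD trends are low-curvature; wide windows stabilize small banks |
| `loess_degree` | 2 | — | local quadratic tracks gentle curvature without edge bias |
| `log_scale_fit` | off | — | optional loess on log SD for strictly positive fits |
| `sd_floor` | 1e-6 | expression units | clamps flat/negative fitted SD so ν stays finite |
| `ward_dialect` | squared | — | matches the `ward.D2`/scipy convention; `raw` selectable |
| selection `p_cut` / `min_frac` | 0.01 / 0.10 | — | joint filter thresholds |

The loess response is the raw SD (not variance or log SD) regressed on the
mean, since the smoothness assumption is stated for the SD itself;
predictions are made only at observed bank means, and queries outside the
fitted range clamp to the boundary value (no extrapolation).

## Synthetic cohorts: what they emulate and what they do not

`simulate_expression` draws per-cohort gene means uniformly on [2, 12]
(log-like units) and Gaussian noise with SD σ(m) = 0.1 + 0.5·exp(−m/4) —
decreasing in the mean, as on a log scale. Planted clusters split each
cohort's tumors into contiguous blocks that span all cohorts; each cluster
owns a disjoint set of 100 outlier genes shifted by ±5 σ with a random but
cluster-consistent sign per gene (binarization is two-sided, so both
directions are informative). Defaults: 5,000 genes, 2 cohorts × 200 tumors
with 20 normals each, 4 clusters. `simulate_mutations` uses 563 mutation
genes (mirroring the motivating feature space): Bernoulli(0.02) passengers,
10 drivers per cluster at rate 0.7 (optionally with a block of drivers
shared across all clusters, to emulate ubiquitous drivers blurring mutation
clusters), 40 hypermutator samples redrawn entirely at rate 0.18
(≈ 100 events/sample, MSI-like), and 25 all-zero samples. Expression and
mutation arms generated with the same seed share sample naming, cluster
membership and subgroup lists.

The generator encodes only the assumptions the method itself relies on. It
does **not** simulate count-level RNA-seq distributions (negative
binomial/RSEM), library-size or batch effects, correlated gene modules,
copy-number or methylation layers, or mutational signatures. Passing tests
therefore demonstrate that the implementation is correct under the model's
own assumptions and recovers planted structure at realistic sizes — not
that the method is robust to real-data artifacts it never models.

Problem sizes in the test suite and the acceptance script are desk-scale
(5,000 of a typical 20,531 genes, 400 of 1,635 tumors), chosen so the full
multi-seed pipeline runs in seconds while keeping per-cohort bank sizes,
the 563-gene mutation space and all rates at their study-condition values.

## Numerical choices and degenerate inputs

* Loess is evaluated on a 201-point grid with linear interpolation between
  grid points; windows are the `span`-fraction nearest neighbors with
  tricube weights, and local fits are solved by centered weighted least
  squares for conditioning. A constant-predictor bank degenerates to the
  mean response; an all-constant bank yields `sd_smooth = sd_floor`
  everywhere.
* Banks need ≥ 2 samples (an SD exists) and ≥ 30 genes (loess support);
  cohorts violating this are rejected by name rather than silently skipped.
* Chi-squared/ANOVA degeneracies are returned as explicit (0, p = 1) or
  flagged (p = 0) results, never NaN.
* TSV floats are written with 6 significant digits; matrices are
  genes-in-rows, and transposed input surfaces as an ID mismatch error
  rather than being silently fixed.
* All simulation randomness flows from a single seed through named
  substreams (expression / mutation / subgroup selection), so individual
  stages are reproducible in isolation.

## Known limitations

* No FDR model for single-gene outlier calls at a given threshold; the
  3-SD cutoff is a fixed convention, not a calibrated error rate.
* No paired tumor–normal (two-sample) variant of the statistic.
* The two Ward dialects genuinely produce different trees on some inputs;
  results should state which was used (the default is logged in outputs).
* Selection allocates each gene to exactly one cluster even when its
  abnormal samples are spread broadly; the tie flag marks the ambiguous
  cases but multi-cluster membership is not modeled.
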