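# urfclust

Unsupervised random forests for patient stratification and multi-omics
clustering, with a federated mode in which collaborating sites share
**trees, never data**.

## The problem

Disease subtyping asks for a partition of patients from one or more
numeric feature matrices (expression, methylation, ...) without labels.
Euclidean distances handle compact, equally scaled, convex clusters but
degrade under outliers, unequal cluster spreads and non-convex shapes.
Clinical cohorts are additionally small and scattered across hospitals
that cannot pool raw records.

## The method

**Splitting rule.** A binary decision tree is grown without a response.
At each node a random subset *M* of `mtry` features is drawn and every
midpoint threshold of every candidate feature *x* is scored by

```
         ( D□(t_left) + D□(t_right) ) / 2
ΔF  =    --------------------------------- ,
                    D∇(t)
```

where `D□(t) = Σ_{i≠j} (x_i − x_j)² / (N(t)(N(t)−1))` is the mean
squared pairwise difference of *x* within a child and
`D∇(t) = Σ_{i,j} (x_i − x_j)² / (N_left · N_right)` the mean squared
difference across the two children.  The split minimising ΔF is taken —
ΔF contrasts within- against between-group spread the way the fixation
index F_ST contrasts within- against between-population variance, and
ΔF = 0 is perfect separation.  Trees are grown on bootstrap resamples
with every child holding at least `min_leaf_size` samples.

**Affinity.** All samples are dropped through all `T` trees; entry
(j, k) of the count matrix is the number of trees in which j and k
share a leaf, and the affinity is `Â = C / max(C)` ∈ [0, 1].  Several
omics layers over the same samples are fused by summing their count
matrices before normalising.  Ward linkage on `D = 1 − Â` yields the
clusters.

**Federated model.** Each client fits a forest locally and shares only
the serialised split rules; the global model is the concatenation of
all clients' trees.  A client propagates its own samples through the
global model to get an n_local × n_local affinity — no sample pair ever
spans two clients.

**Interpretation.** Given a cluster solution, the already-grown splits
are scored one-vs-all: for each cluster the decrease in Gini impurity
of the binarised labels along each existing split, weighted by the
fraction of samples reaching the node, is accumulated per feature.
Pearson correlation of the per-cluster importance vectors shows which
clusters are driven by the same features.

## Worked example

Three Gaussian clusters (100 points each, sd 0.25) with 10% far-out
contamination — a setting where Euclidean Ward clustering breaks:

```python
import urfclust as u
ds = u.make_outlier_scenario(10, seed=7)     # 330 x 2 matrix + labels
u.write_feature_matrix(ds.X, "outliers.csv")
```

```console
$ urf fit outliers.csv --trees 500 --seed 7 --out model.json
wrote model.json (500 trees, 330 samples)
$ urf affinity model.json outliers.csv --out affinity.csv
wrote affinity.csv
$ urf cluster affinity.csv --k 3 --out labels.csv
wrote labels.csv (k=3)
$ urf importance model.json outliers.csv labels.csv --out importance.csv --corr-out corr.csv
wrote importance.csv
```

Comparing `labels.csv` against the generating labels gives an Adjusted
Rand Index of **0.688** for this replicate (the replicated median
across the 2–10% outlier grid stays above 0.7, while Euclidean Ward
drops below ~0.5 beyond 4% outliers).  The importance table splits the
signal per cluster — e.g. here cluster 0 is separated mostly along the
`y` axis, cluster 2 along `x`:

```
              x      y
cluster0  0.162  0.838
cluster1  0.580  0.420
cluster2  0.791  0.209
```

Other entry points: `urf pipeline --input rna.csv --input methyl.csv`
(multi-omics late fusion), `urf federate --clients 3 data.csv`
(federation simulation), `urf simulate --scenario rings --reps 30`
(synthetic benchmark comparison).  The same functionality is available
as a library (`fit_forest`, `forest_counts`, `normalize_affinity`,
`ward_cluster`, `simulate_federation`, `cluster_importance`, ...).

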