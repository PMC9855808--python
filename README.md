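# iegnet

Correlation-based functional connectivity networks from regional
immediate-early-gene (IEG) expression density.

## The problem

Brain-wide expression of IEGs such as c-Fos is a post hoc proxy of neuronal
activity: after a behavioural task, each animal yields one density value
(labelled cells per µm², optionally derived by Cavalieri point counting) for
every atlas region. Cross-correlating those densities **across the animals of
a group** — instead of across a time series, as fMRI would — gives a
functional-connectivity matrix for freely behaving animals. `iegnet`
implements that pipeline end to end for experimentalists and methodologists:

1. **Ingest** a region × animal density table (or raw counts plus grid-point
   counts, density = count / (grid_points · spacing²)).
2. **Correlate**: Pearson r for every unordered region pair, with two-tailed
   p-values from the exact t-transform `t = r·√(n−2)/√(1−r²)` on `n−2`
   degrees of freedom.
3. **Threshold** into a binary, symmetric, hollow adjacency matrix:
   `p ≤ α`, Benjamini–Hochberg FDR at rate `q` over the C(N,2)-pair family,
   optional minimum |r|, and a sign policy for anticorrelations
   (excluded by default, or kept absolute/signed).
4. **Characterise** with graph theory: degree, clustering, local efficiency,
   betweenness; density, global efficiency, characteristic path length, and
   small-world σ = (C/C_rand)/(L/L_rand) against ER or degree-preserving
   null ensembles.
5. **Stress-test**: because group-level correlations from small cohorts are
   fragile, an exhaustive subsample scan recomputes the network on *every*
   combination of k animals (k = 3…n), reporting per-edge significance-flip
   rates (false-negative / false-positive occurrences), per-edge p-value
   variances, and the median-variance network at a chosen group size.

A synthetic-cohort generator with an explicit ground-truth network (latent
multivariate Gaussian, nearest-positive-definite repair, softplus
non-negativity) makes recovery, calibration and stability quantifiable
without any animal data.

## Worked example

```python
from iegnet import (ConnectivityModel, CohortSpec, make_ground_truth,
                    simulate_cohort)

truth = make_ground_truth(n_regions=60, edge_density=0.1, seed=0, effect_r=0.7)
table = simulate_cohort(truth, CohortSpec(n_animals=100), seed=1)
res = ConnectivityModel(table.to_dataframe()).fit(alpha=0.05, fdr_q=0.05)
print(res.summary())
```

```
Functional connectivity network
==============================================
regions (nodes):        60
animals (group size):   100
threshold:              alpha <= 0.05, BH-FDR q = 0.05, positive_only
edges:                  172 of 1770 pairs
----------------------------------------------
network density:        0.0972
global efficiency:      0.4474
mean clustering:        0.1900
char. path length:      2.5689 (component coverage 1.00)
degree: mean 5.73, max 12 (R30)
```

The fitted network retains 172 of 1770 region pairs; against the 177-edge
ground truth this run recovers edges with sensitivity 0.904 and specificity
0.992. Group-size stability hangs off the same results object:

```python
report = res.stability(sizes=range(3, 12))   # every combination of 3..11 animals
report.to_size_frame()                        # mean p-variance per group size
net5, members = res.median_variance_network(report, k=5)
```

The same stages are scriptable from a shell (`iegnet simulate | correlate |
threshold | metrics | stability | pipeline`); every run writes a JSON
provenance sidecar (config echo, input checksums, seeds) sufficient to
reproduce it bit-exactly.

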