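# Methods

## Statistical model

For a cohort of `n` animals scored over `N` brain regions, the input is a
matrix `X` (regions × animals) of non-negative IEG expression densities.
Functional connectivity between regions `i` and `j` is the Pearson
product-moment correlation `r_ij` of their density vectors across animals.
Significance uses the exact transform

    t = r · sqrt(n − 2) / sqrt(1 − r²),   t ~ Student-t(n − 2),

two-tailed. This transform reproduces published (r, p) pairs at n = 12
(r = 0.6193 → p = 0.0318; r = 0.2539 → p = 0.4258), which is why it is used
instead of permutation or critical-value tables; p = 0 is returned at
|r| = 1. The minimum meaningful group size is 3 (one residual degree of
freedom), and the package enforces it everywhere.

Edges of the binary network are the pairs satisfying **all** configured
conditions of a `ThresholdSpec`:

* `p ≤ α` (comparison is `≤`, matching the "α ≤ 0.05" convention);
* Benjamini–Hochberg step-up retention at rate `q` (optional). The family is
  the C(N,2) upper-triangle p-values of the current node set, re-applied
  within every subsample during stability scans so each subsample is judged
  exactly as a cohort of that size would be;
* `|r| ≥ r_min` (optional critical-value floor);
* the sign condition. Default `positive_only` excludes anticorrelations —
  the common practice in this literature, exposed as an explicit choice with
  `absolute` and `signed` as first-class alternatives because the exclusion
  is debated.

Whether α-filtering is combined with FDR is a user decision: `fdr_q=None`
gives raw-p thresholding; the provenance sidecar records which was used.

Degenerate data policy: a region with zero variance (constant density) has
undefined correlations; every pair involving it is assigned r = 0, p = 1 and
a warning/tally is emitted. A constant region can therefore never gain
edges, and subsample scans never abort mid-enumeration. Pairwise-complete
handling of missing cells is deliberately not offered: the cross-animal
design has no defined behaviour for missing entries, so tables with gaps are
rejected at ingest with the offending cell named.

Units are labels/µm² internally (Cavalieri density: count divided by
grid_points · spacing², default spacing 22 µm; zero grid points is an
error, never a zero or infinite density). Pearson correlation is invariant
to per-region affine rescaling, so unit conventions cannot change any
network.

## Graph metrics

Nodal: degree (row sums); clustering coefficient (triangles through a node
over k(k−1)/2, defined 0 for k < 2 so per-region vectors stay alignable
across thresholds); local efficiency (Latora–Marchiori: global efficiency of
the neighbour-induced subgraph, 0 for k < 2); betweenness centrality
normalized by (N−1)(N−2)/2.

Global: density 2E/(N(N−1)); global efficiency (mean inverse shortest-path
length over ordered pairs, 0 for disconnected pairs — preferred for
cross-threshold comparison precisely because it handles disconnection
natively); mean clustering; characteristic path length on the largest
connected component with the component's node coverage reported alongside
(the treatment of disconnected nodes is otherwise a silent choice);
small-world σ = (C/⟨C_rand⟩)/(L/⟨L_rand⟩) on the largest component against
either Erdős–Rényi nulls with matched N and E or Maslov–Sneppen
degree-preserving rewiring (default 10·E successful swaps, configurable and
logged). A null ensemble with zero mean clustering raises an explicit
undefined-σ error rather than dividing by zero. Computations are delegated
to networkx; the test suite verifies every metric against independent
brute-force implementations (exhaustive BFS, triangle and geodesic counts)
on hundreds of random graphs.

## Group-size stability

For each subgroup size k, all C(n,k) animal combinations are enumerated
lexicographically and the full correlate→threshold pipeline is recomputed on
each. Reported per edge and size:

* **flip rate** — the fraction of subsamples whose significance verdict
  differs from the full-cohort verdict. Edges significant in the full cohort
  produce false-negative-type flips; the rest, false-positive-type. The
  full-cohort verdict is the reference; for synthetic cohorts the ground
  truth is additionally available to the caller.
* **p-value variance** — population variance of the (raw) p-value across the
  same-size subsamples. The per-size aggregate for trend summaries is the
  mean over edges (median also reported).

Median-network selection at size k ranks combinations by the variance of
their own p-values across edges (the within-network p variance — the
package's reading of "the network with the median p-value variance", which
is ambiguous between within- and across-subsample variance); the
median-ranked combination is taken with the lower median for even counts and
lexicographic tie-breaking, both logged.

Exhaustive enumeration is the default. A seeded Monte-Carlo mode caps
combinations per size for cohorts where C(n,k) explodes (n > ~14); the
report flags when a scan was not exhaustive.

On a 60-region, 12-animal cohort the scan over k = 3..11 computes 4,016
networks (the sum of the binomial coefficients) in a few seconds.

## Synthetic cohorts

No generative model for inter-animal density variation is established in
this literature, so the generator is built for exactness of ground truth
rather than biological realism:

* **Structure**: `make_ground_truth(N, edge_density, seed)` samples
  round(edge_density · C(N,2)) edges uniformly without replacement.
  `make_clique_ground_truth` builds disjoint cliques instead (see
  calibration below). One seed governs structure, a second governs sampling,
  so one truth can back many cohorts.
* **Target correlation**: `C₀ = I + effect_r·A`. When `C₀` is positive
  definite it is used as-is (e.g. any disjoint-clique truth: compound
  symmetry gives eigenvalues 1+(k−1)ρ and 1−ρ > 0). Otherwise the nearest
  valid correlation matrix is found by alternating projection (statsmodels
  `corr_nearest`, eigenvalue floor 1e−6); the repair *shrinks* on-edge
  correlations and *leaks* small off-edge correlations, and both magnitudes
  are reported (`return_info=True`). At N = 60, density 0.1, effect 0.7 the
  shrinkage takes true edges to ≈0.30–0.55 and leaks off-edge values up to
  ≈0.28 — consumers of ground-truth comparisons must remember that the
  sampling distribution is the *projected* matrix.
* **Sampling**: animals are i.i.d. draws from N(0, C); values are scaled by
  `noise_sd` (default 1.0), shifted by `baseline` (default 5.0, arbitrary
  density units) and mapped through a non-negativity transform. Default
  `softplus` is numerically near-identity at the default baseline
  (softplus(5) ≈ 5.007) while guaranteeing positivity; `none` keeps exact
  Gaussian values (Pearson calibration exact, negatives allowed);
  `exponential` gives log-normal-like skew. Cohort default n = 12 animals,
  the typical IEG study size.
* **Outliers**: optionally, a chosen number of animals has its latent vector
  replaced by a random unit direction scaled to a given magnitude in SD
  units — the simplest mechanism that reproduces the outlier vulnerability
  of small-cohort correlations.

What the generator does **not** emulate: count noise and its
density-dependent variance, hierarchical (litter/batch) structure,
registration and segmentation error, region-size effects, or skewed
empirical density distributions beyond the chosen transform. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated latent-Gaussian model, not robustness to all failure modes of real
histological data.

## Calibration and recovery protocols

* **Type-I error**: with `effect_r = 0` and transform `none` the t-test is
  exact, so the pooled fraction of pairs with p ≤ 0.05 over 200 cohorts
  (12 animals, 60 regions) must lie inside the binomial 95% band around
  0.05. The `none` transform is used because a nonlinear transform would
  perturb exactness.
* **Realized FDR**: measured on signal-bearing cohorts against a
  disjoint-clique truth (10 cliques of 6, effect 0.7, n = 100), where
  off-clique population correlations are *exactly* zero. FDP = share of
  BH-declared edges absent from the truth, averaged over 200 cohorts;
  expectation q·m₀/m ≈ 0.046 < q. A projected random truth is deliberately
  not used here: projection leakage creates genuinely correlated off-truth
  pairs that BH correctly declares, which measures the generator's repair,
  not the error control.
* **Recovery**: random truth at density 0.1, effect 0.7, n = 100, α = 0.05
  with BH q = 0.05; sensitivity and specificity against the ground-truth
  edge set both exceed 0.9 even though the projected targets are shrunk.

## Numerical and design choices

* Correlations are computed vectorised (`np.corrcoef`) with symmetrisation
  and clipping to [−1, 1]; p matrices carry NaN on the diagonal
  (self-correlation is meaningless) and the adjacency diagonal is always 0.
* BH step-up is implemented directly (sort, largest k with
  p(k) ≤ k·q/m, retain p ≤ p(k)) and cross-checked in tests against both a
  literal brute-force definition and statsmodels' `fdr_bh`.
* CSV round-trips use pandas `float_precision="round_trip"` so
  load → write → load is bit-identical.
* Problem sizes in tests and the acceptance script (60 regions, 12 animals,
  200-cohort calibration batches, 200 oracle graphs ≤ 12 nodes) match the
  motivating study scale while keeping a full run in the low minutes on one
  CPU.
* The Model/Results surface (`ConnectivityModel.fit()` →
  `ConnectivityResults` with `summary()`, `stability()`, plots) is a thin
  presentation layer; all computation lives in the stage modules
  (`ingest`, `synthetic`, `network`, `metrics`, `stability`), which are
  importable directly and mirrored 1:1 by the CLI subcommands.

## Known limitations

* Weighted-network analysis, partial correlations and time-resolved
  connectivity are out of scope; the pipeline is strictly the
  binary-network, cross-animal design.
* The atlas hierarchy is not modelled: regions are free-form labels, and
  restriction to a documented node set is the caller's responsibility.
* Exhaustive stability scanning is factorial in spirit; beyond n ≈ 14 use
  the Monte-Carlo cap.
* Small-world σ is sensitive to the null model and to component
  fragmentation at strict thresholds; σ is reported only when a null
  ensemble is requested and the largest component is non-trivial.
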