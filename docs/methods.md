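# Methods

## Model and null hypothesis

The test treats the input as an n × p numeric matrix of observations
(cells) by features (principal-component scores or expression values) and
asks whether the point cloud contains a *trajectory*: a connected,
predominantly one-dimensional — possibly branching — structure along
which the observations are ordered. The alternative leaves the trajectory
shape unspecified; the null hypothesis is "no multivariate dependence
structure", operationalized by independently permuting each feature
column across rows. Column-wise shuffling preserves every marginal
distribution exactly while destroying all inter-feature dependence, which
is what any trajectory — linear, branching, or looping — is made of. It
is the canonical exchangeable null for structure-detection in point
clouds. A flag (`permute_before_pca`) permutes the raw matrix and re-runs
PCA inside every replicate instead; the default permutes the matrix that
enters clustering (post-PCA), which is far cheaper and tests the same
independence hypothesis in the tested coordinates.

The trajectory signal is read from the shape of the minimum spanning tree
built on k-means cluster centers. A clean trajectory gives a path-like
tree; structureless data give a branched, compact tree. Because no single
k is privileged — too few clusters make any cloud look linear, too many
make any cloud look branched — the test sweeps k and reports the median
of the per-k p-values per statistic. The median is a conservative summary
of strongly dependent tests, not a calibrated p-value, and no
multiplicity correction is applied across k or across the three
statistics.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k_min`, `k_max` | 5, 35 | cluster sweep bounds (31 values); the window in which tree shape is informative |
| `n_permutations` (B) | 1000 | permutation replicates per k; resolves p ≥ 1/(B+1) ≈ 0.001 |
| `pca_dims` | `"auto"` | PCA components before testing: 2 when p > 10, otherwise the data are used as-is; any integer or `none` overrides |
| `statistics` | D1, D2, Lmax | subset of the three tree statistics to run |
| `n_restarts` | 10 | k-means restarts; best within-cluster SS kept |
| `seed` | 0 | master seed; every cell of the sweep derives its own stream |

PCA centers columns but does **not** scale them to unit variance: the MST
lives in Euclidean coordinate geometry, and per-feature scaling would
distort it. Component signs are fixed so each component's
largest-magnitude loading is positive, making output reproducible across
SVD implementations.

## Algorithmic conventions

**k-means.** Lloyd iterations with k-means++ (D²-sampling) seeding,
`n_restarts` independent starts, convergence when assignments stop
changing (cap 300 iterations). Assignment ties break to the lowest center
index. A cluster that empties is re-seeded at the point farthest from its
assigned center, guaranteeing k non-empty clusters — the MST needs
exactly k nodes. Rows are processed in a canonical lexicographic order
internally, so the result is invariant under row shuffling of the input.
Restart r of the (seed, k, replicate) cell draws from its own
`SeedSequence` child stream, making every cell independently
reproducible, bit-for-bit. The implementation is in-package rather than
delegated to a library because these determinism and non-emptiness
contracts are load-bearing for the permutation test; a library k-means is
used as an independent quality cross-check in the test suite.

**MST.** Prim's algorithm on the complete Euclidean graph over the k
centers, O(k²). Equal-weight candidate edges are resolved to the
lexicographically smallest (min id, max id) pair. This matters: tie
topology changes all three statistics, so determinism here is part of the
contract, not cosmetics. Duplicate centers (zero-weight edges) are legal.

**Longest path.** Two BFS sweeps (farthest node from an arbitrary start,
then farthest from that): the standard linear-time tree-diameter
algorithm, counted in edges, never in weight.

**p-values.** Add-one empirical formula, one-tailed:
p = (1 + #extreme) / (1 + B), with ties counting as extreme. This
guarantees p ∈ (0, 1] and validity (P(p ≤ t) ≤ t under the null). D1 is
lower-tailed; D2 and Lmax are upper-tailed. The statistics are small
integers with heavy ties, so the p-values are noticeably *conservative*
(super-uniform) on structureless data — the calibration test in the suite
therefore checks the one-sided property (no excess of small p-values)
rather than exact uniformity, which the tie-handling makes impossible.
The smallest resolvable p is 1/(B+1); `n_permutations ≥ 19` is enforced
so that 0.05 is resolvable at all.

**Medians.** An even-length sweep takes the midpoint of the two central
values (the default 31-value sweep is odd, so this only triggers for
custom ranges).

**Degenerate inputs.** k < 3 is rejected (a tree on fewer than 3 nodes
has no shape signal); fewer than k distinct rows raises a degenerate-data
error, which permutation replicates propagate. At k = 3 the star tree and
the path graph coincide, so the star extremes (D2 = 0, Lmax = 2 with
D1 = k−1 branching) are meaningful only from k = 4.

## Synthetic data

The generators produce the geometry the test consumes — 2-D (or
higher-dimensional) point clouds — not expression counts. Five
topologies: `none` (i.i.d. uniform on the unit square), `linear` (a
smooth sine arc), `multifurcating` (a root segment splitting into three
children), `converging_diverging` (two branches merging into a middle
segment then re-splitting), and `disconnected_looping` (an open circular
arc covering 280°, plus a disjoint short segment). Points are sampled
uniformly by arc length, with isotropic Gaussian noise of standard
deviation `noise_sd` added in every coordinate; per-kind presets (0.04 to
0.05 in unit-square coordinates) put the clouds in the regime the test
targets: backbone visible, clusters overlapping along it. Ground truth
(branch label, pseudotime, noiseless coordinates) is returned as a
sidecar table. `lift_to_genes` optionally embeds the coordinates in a
wide noisy linear "expression" matrix for end-to-end I/O tests.

What the generators do **not** emulate: count noise, library-size
variation, dropout, batch effects, or any transcriptomic preprocessing.
Passing tests on these clouds show that the statistics respond to
low-dimensional geometry as designed; they do not certify behavior on
raw single-cell data, whose preprocessing (normalization, feature
selection, PCA) is the caller's responsibility and materially affects
the geometry the test sees.

## Problem sizes used by the test suite

The stochastic suite checks two properties end-to-end. Calibration: 200
i.i.d. Gaussian datasets (n = 200, k = 10, B = 99), one-sided KS test at
level 0.01 per statistic. Power ordering: 50 paired replicates of a
linear-trajectory versus a structureless cloud (n = 200, sweep k = 5..11,
B = 99, 5 k-means restarts), requiring the trajectory's median p to be
smaller in at least 95% of replicates for every statistic. These sizes
are the package's chosen verification conditions; the pipeline itself has
no built-in size limits.

## Known limitations

- k-means is a pragmatic, not ideal, partitioner of trajectory-shaped
  data; density-aware or model-based partitions are a natural extension
  point behind the same `CenterSet` interface.
- The null distributions are purely empirical; no analytical forms are
  provided, so runtime scales linearly in B and in the sweep width.
- The median-p summary has no finite-sample guarantee; it is an evidence
  score, and thresholding it at 0.05 is a convention, not a test level.
- The three statistics are strongly dependent (they are computed from the
  same trees), and their p-values frequently coincide on small sweeps.
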