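# Methods

This note records the model underlying `coincide`, the conventions chosen
where the procedure admits more than one reading, and what the simulation
benchmark does and does not establish.

## Model and assumptions

The object of inference is a *meta-cluster*: a set of per-dataset clusters,
drawn from at least three independent datasets, whose expression profiles
are mutually similar enough that they plausibly represent one recurring
patient subtype. The method deliberately avoids any between-dataset
normalization: each dataset is assumed to arrive already
intra-dataset-normalized and log-scale, and all cross-dataset statements are
made through correlation-based statistics that are invariant to per-sample
location/scale. This keeps genuine between-cohort biology (e.g. different
trial populations) from being smoothed away by batch correction, at the cost
that systematic platform effects must be absorbed by the
similarity-significance machinery rather than removed up front.

Clusters are compared only across datasets, never within one, and a pair of
clusters that both come from single-cluster datasets is never compared (such
a comparison would be unfalsifiable — every sample trivially lands on the
only centroid in both directions).

## Within-dataset clustering

Consensus clustering uses k-means (scikit-learn's Lloyd implementation, one
random start per resample) on 90 % subsamples drawn without replacement,
100 resamples per candidate k by default. The consensus entry for a sample
pair is (# times co-clustered) / (# times co-drawn). PAC is the fraction of
strictly-upper-triangle entries in (0.1, 0.9); both interval bounds are
configurable. The chosen k minimizes PAC *rounded to two decimals*, ties
going to the smaller k — rounding prevents meaningless third-decimal
differences from dictating k. Final labels cut an average-linkage dendrogram
of (1 − consensus) at the chosen k. An optional `allow_k1` mode declares a
dataset single-cluster when even k = 2 is mostly ambiguous (PAC at k = 2
above 0.5); it is off by default and is the right setting for collections
whose datasets may contain a single condition.

The k-means variant (Lloyd vs Hartigan–Wong, R's default) is a documented
convention; consensus frequencies are driven by the subsampling, not by
which local-search heuristic polishes each run.

## Cross-dataset similarity and the rotation null

Centroids are arithmetic per-gene means of a cluster's samples, computed on
the gene intersection of the two datasets involved (minimum 10 shared genes,
configurable). Assignment is by Pearson correlation; ties and degenerate
(constant) vectors resolve to the lowest centroid index and are logged,
constant vectors being treated as never-nearest.

The null model replaces the reference centroid configuration with a
uniformly random rigid rotation of itself about the reference data's overall
mean point. This preserves the full internal geometry of the centroid set
(pairwise distances and norms about the center, asserted to 1e-8 in tests)
while destroying its alignment with the data, which is exactly the
"structure-preserving, position-randomizing" null needed for a
reproducibility statistic. Implementation detail: a Haar rotation acts on
the centered centroid matrix only through its column space, so the package
draws a uniform random orthonormal r-frame (QR of a genes × r Gaussian
matrix, r = centroid-space rank ≤ k) and attaches the SVD coordinates to it
— distributionally identical to a full rotation and two orders of magnitude
cheaper at 200 genes. Within one `all_pairs` run the null sets are drawn
once per reference dataset and shared by all query clusters facing that
reference; each p-value remains marginally exact.

The reported p is the fraction of null sets whose recomputed best-fit mean
similarity AND nearest-neighbor fraction both *strictly* exceed the observed
values (count-based, no pseudocount; p = 0 is reportable). Two properties of
this definition are worth knowing:

* For a perfect match (NNF = similarity = 1) p is exactly 0, since nothing
  can strictly exceed it.
* The joint two-statistic exceedance is **not uniformly distributed under
  the null**. The package's own calibration experiments (isotropic query
  clusters against rotated reference centroids) show the similarity-only
  exceedance p is exactly uniform — the rotation null itself is sound — but
  the joint AND count is systematically sub-uniform (mean ≈ 0.3) because
  the two statistics are imperfectly dependent and NNF is discrete under
  strict inequality. The joint p should therefore be read as a conservative
  *screening* score at small thresholds such as 0.01, not as a calibrated
  tail probability. The test suite asserts the uniformity of the
  single-statistic p and documents the joint behaviour.

Both directional p-values must individually pass the threshold (they are
never averaged); NNF and mean similarity are averaged across the two
directions once reciprocity holds.

## Threshold selection and community detection

The similarity threshold is chosen from a Gaussian KDE (Silverman bandwidth)
of all cluster-vs-centroid mean similarities, including non-best-fit ones,
renormalized on [−1, 1]. Qualifying peaks must sit at similarity above the
0.1 baseline and have density height above it; the smallest qualifying peak
is the primary suggestion, because aggressive pruning near similarity 1
demonstrably removes genuinely replicable clusters. All qualifying peaks are
reported so a second analysis can be run at an alternate maximum.

Edges are inclusive at every threshold (≥ for NNF and similarity, ≤ for p).
Girvan–Newman removes, iteratively, the edge with the highest betweenness
computed on distances 1/weight; the partition kept is the one maximizing
modularity with the similarity weights (evaluated over the whole removal
dendrogram, including the initial connected components). The igraph C
implementation backs the betweenness loop. Communities spanning fewer than
three unique datasets are pruned; their samples receive no subtype.

## Gene ranking, markers

Per-dataset gene variability is the mean absolute deviation about the
gene's within-dataset mean ("mean absolute difference"); ranks break ties
alphabetically. The collection-level meta-rank score is the mean rank across
datasets, a gene absent from a dataset receiving that dataset's worst rank
plus one — a Borda-style aggregation that is scale-free across platforms and
penalizes platform-sparse genes. The final list is the global top `n_global`
unioned with every dataset's top `n_intra`.

Marker scoring uses Hedges' g (statsmodels' bias-corrected SMD) of a gene
between a dataset's meta-cluster member samples and its other *clustered*
samples, pooled across datasets by fixed-effect inverse-variance weighting;
a DerSimonian–Laird random-effects option is provided (with tau² truncated
at zero, computed in-package). Conventional filters: summary effect ≥ 0.5
(enrichment input), strictly > 0.75 (druggable-target nomination).

## The simulation generator

Ground truth is four archetype mean-expression vectors in a 200-gene space,
drawn once per seed from a standard Gaussian and rescaled so the mean
pairwise archetype separation is 4 log-units (configurable). This parametric
generator stands in for deriving archetypes from a real multi-tissue
dataset; it reproduces the statistical structure that matters for the
benchmark — four distinct profiles, shared across 10 datasets, observed
through per-gene Gaussian noise of sd 0 to 2.4 — while being fully
self-contained. Scenario families: (1) four clusters of 50 samples per
dataset; (2) random cluster sizes 1–100; (3)/(4) random 2–4 / 1–4 clusters
per dataset; (5)/(6) both randomized; (7) as (1) but half the clusters are
"mixed" (each sample's archetype drawn uniformly), a negative control that
should acquire no edges.

With this scaling, within-cluster sample–centroid correlation falls from 1
at zero noise through ≈ 0.45 (sd 0.4) and ≈ 0.24 (sd 0.8) to ≈ 0.08 (sd
2.4), so the noise grid spans trivial to hopeless; true-positive rates
consequently collapse at high thresholds or high noise, while false-positive
rates stay near zero throughout — the behaviour the benchmark is designed to
measure. Because evaluation takes truth clusterings as given (re-clustering
is optional), the benchmark isolates steps 2–4; it says nothing about
consensus-clustering quality on real data, about non-Gaussian noise, or
about platform-specific gene dropout, all of which real collections add.

Edge-level scoring: over all cross-dataset cluster pairs (excluding pairs of
single-cluster datasets), an edge between same-archetype clusters is a true
positive; any edge touching a different archetype or a mixed cluster is a
false positive; scoring is applied to the network after community pruning.
One mechanism deserves note: at zero noise a cluster whose archetype is
absent from the reference dataset has NNF = 1 on its nearest *wrong*
centroid, and NNF = 1 yields p = 0 under strict exceedance, so weakly
correlated archetype pairs (correlations of order 1/√200) can occasionally
form false edges just above low similarity thresholds in the
missing-archetype scenarios. Averaged over replicates this stays well inside
the benchmark's error bounds, but it illustrates why the similarity
threshold — not the p-value — is the binding filter at low noise.

## Reproducibility and scale

All randomness flows from a single integer seed through named
`SeedSequence` streams (per dataset, per reference, per replicate), so
reruns are bit-identical. The shipped benchmark (`scripts/acceptance.py` and
the corresponding test) uses scenarios 1–7 × noise {0, 0.4, …, 2.4} ×
thresholds {0, 0.15, 0.3, 0.5, 0.7}, 10 replicates per cell and 100 null
iterations per comparison (~2 500 pipeline runs, about 3 minutes on one
CPU); 50 replicates and 500 nulls reproduce the same qualitative picture and
are the recommended settings for publication-grade runs.

## Known limitations

* The joint p-value is conservative-by-construction, as described above.
* Girvan–Newman recomputes betweenness after every edge removal; networks
  beyond a few hundred clusters would need the plug-in community hook.
* Gene matching is exact string equality; symbol harmonization across
  platforms must happen upstream.
* The density-based threshold suggestion places the cut *at* the dominant
  similarity mode; when good-edge similarities are symmetric around that
  mode (as in heavy-noise simulations) this prunes half of them, and an
  explicit threshold is the better choice.
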