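# Methods

## The ensemble model

Cluster analysis of omics matrices (samples × features) is sensitive to the
choice of algorithm, distance metric and cluster count, and a single
partition is hard to validate. `dce` treats every base clustering run as an
"expert" and builds a consensus across three axes of diversity:

- **algorithms** — ten built-ins spanning centroid (k-means, fuzzy c-means),
  medoid (PAM), model-based (Gaussian mixture), graph/spectral, prototype
  (SOM + k-means on the codebook) and hierarchical families (average,
  complete and Ward linkage agglomerative, plus DIANA-style divisive);
- **cluster sizes** — every k in a user-chosen grid;
- **data subsamples** — each (algorithm, k) combination is repeated on
  random subsets containing `round(0.8 · n)` observations drawn without
  replacement (fraction configurable; 0.8 is the default).

The result is a 4-D integer label array indexed (sample, repetition,
algorithm, k) with a missing marker for unsampled cells. Runs that raise are
marked *failed* and excluded downstream rather than aborting the ensemble —
an ensemble should tolerate individual expert failure.

### Completion

Samples missing from a repetition's subsample are assigned the majority
label among their `knn_k = 5` nearest neighbours (Euclidean distance in the
prepared feature space, regardless of the base algorithm's metric) that are
labelled in the same slice; vote ties go to the smallest label. Completion
is idempotent and is the identity when the subsample fraction is 1.

## Consensus formation

Four combiners turn one k-slice (n samples × runs) into a partition:

- **majority voting** — every run is relabelled against a reference run
  (the first, configurable) by solving the linear assignment problem on the
  contingency table (padded square when cluster counts differ); the
  per-sample modal label wins, ties to the smallest label.
- **k-modes** — each sample's run-label vector is categorical data;
  k-modes with simple-matching dissimilarity and per-position majority mode
  updates, 10 seeded restarts, lowest total cost kept. Runs are first
  aligned to a canonical labelling and candidate initial rows ordered by a
  presentation-invariant key (frequency, then the sorted profile of
  distances to all samples) so the result does not depend on sample order
  or on the runs' arbitrary cluster IDs.
- **CSPA** — average-linkage hierarchical clustering on `1 − M` (M the
  co-association matrix), cut at k. The original formulation partitions a
  similarity hypergraph with METIS; the hierarchical cut is deterministic
  and dependency-free, at the cost of bit-compatibility with graph-partition
  implementations.
- **LCE** — binary sample × cluster membership over all runs' clusters;
  cluster–cluster similarity by shared membership (Jaccard), refined by the
  weighted connected-triple rule (summed min-similarity through common
  neighbour clusters, normalised to the maximum triple weight); the refined
  association matrix has entry 1 where the sample belongs to the cluster
  and otherwise `dc ×` the refined similarity between that cluster and the
  sample's own cluster *in the same run*; samples are partitioned by
  average-linkage clustering of the association rows. The per-run anchor
  (rather than the best over all owned clusters) keeps a single erroneous
  run from contaminating a sample's entire association row. Decay constant
  `dc = 0.8` by default (0 reduces LCE to clustering the raw binary
  membership rows).

Solutions with fewer than two non-empty clusters at k ≥ 2 are returned with
a `degenerate` flag, not as errors, so the pipeline can skip them.

All four methods are invariant to per-run cluster relabelling and to sample
order **whenever the underlying optimum is unique**. On unstructured inputs
with exactly tied contingency tables or tied dendrogram heights, any
implementation's deterministic tie-breaking necessarily depends on
presentation order; the property tests therefore use structured ensembles.

## Evaluation and model selection

- **Co-association matrix**: entry (i, j) = runs co-clustering i and j over
  runs assigning both. With subsampling provenance (pre-completion) the
  denominator varies per pair and never-co-sampled pairs are flagged
  undefined and excluded from the CDF and PAC.
- **Consensus CDF and ΔAUC**: empirical CDF over the defined off-diagonal
  upper-triangle entries; the area under a step CDF on [0, 1] is
  `1 − mean(entries)`. ΔAUC reports A(k_min) at the smallest k and the
  relative change `(A(k) − A(k_prev)) / A(k_prev)` afterwards.
- **PAC**: fraction of entries strictly inside the open interval
  `(0.05, 0.95)` by default; boundary values count as unambiguous. The
  bounds are configurable — published usage varies and the open-interval
  convention is a documented dialect choice. `select_k` takes the argmin of
  PAC, ties to the smallest k.
- **Internal indices** (13, standard definitions): silhouette,
  Calinski–Harabasz and Davies–Bouldin via scikit-learn; Dunn, PBM, tau,
  gamma, G+, C-index, McClain–Rao, SD-dis, Ray–Turi and compactness
  implemented directly on Euclidean distances. Each index carries an
  optimisation direction. Indices undefined for an input (single cluster,
  zero denominators) propagate as flagged non-values (NaN) and are skipped
  by rank aggregation and weighting; zero-diameter degeneracies surface as
  ±inf (e.g. Dunn on singleton clusters).
- **External indices**: adjusted Rand index (permutation-model expectation
  correction), NMI (arithmetic-mean entropy normalisation) and accuracy
  after Hungarian matching of cluster IDs to reference classes.

## Algorithm selection, trimming, weighting

Per index, algorithms receive average ranks honouring the index's direction;
each algorithm is represented by its best score across k for that index
(trimming is decided once across all k, not per k). Aggregation is Borda
(mean rank, ties alphabetical) by default; the `footrule_mc` alternative
minimises the total Spearman footrule distance to the per-index rank lists
by a seeded Monte-Carlo search (random candidate orderings plus pairwise-
swap hill climbing) and matches the exhaustive optimum on small instances.
Trimming restricts the clustering array to the top-N ranked algorithms
without touching label values. Weights rescale every index column to [0, 1]
(minimise-direction columns flipped), average over defined indices per
algorithm and normalise to sum 1; the weighted co-association matrix weighs
each run by its algorithm's weight. Weights derive from internal indices
only.

## Significance testing

The cluster index of a 2-way split, `CI = within-SS / total-SS`, is compared
with its Monte-Carlo distribution under a single-Gaussian null: the null
covariance is diagonal with eigenvalues `λ̃_j = max(λ_j, σ̂²)`, where λ are
the sample covariance eigenvalues and `σ̂ = MAD(centred data) / 0.6745` is
the robust background-noise scale (hard flooring; soft thresholding is out
of scope). Each of `n_sim` simulated datasets contributes its minimal
2-means CI (20 seeded restarts by default, vectorised across restarts), and
the add-one estimator `p = (1 + #{CI_null ≤ CI_obs}) / (1 + n_sim)` avoids
p = 0. When no split is supplied the observed split is the best seeded
2-means split of the data.

**Calibration.** CI is invariant to rotation, translation and scaling. In
the univariate case the null is therefore pivotal and the p-value is exactly
uniform under the null (measured Kolmogorov–Smirnov statistic 0.06 over 200
replicates). With multivariate data the covariance *shape* must be
estimated, and hard flooring plus eigenvalue sampling error make the test
mildly **conservative** (null p-values skew high: at n=100, p=5 the null
rejection rate at the 0.05 level is ≈1%, never inflated). The pipeline's
sequential use — test the root split, then each selected-k cluster's own
best split — reports raw p-values without multiplicity correction; with the
conservative null this errs on the side of fewer clusters.

## Synthetic fixtures

`simulate_mixture` draws spherical Gaussian blobs whose centres sit on a
scaled simplex, so all pairwise centre distances equal
`separation × cluster_sd`; optional pure-noise features are standard normal.
`simulate_null` draws a single mean-zero Gaussian (isotropic or diagonal).
These fixtures emulate well-separated, spherical, equal-variance clusters —
the regime where every internal index agrees on the right answer. Real
expression data violate all three assumptions (correlated features, unequal
cluster shapes and sizes, batch structure), so passing tests demonstrate the
correctness of the machinery, not expected field performance; no
platform-specific normalisation (log-CPM, batch correction) is included by
design.

## Defaults and problem sizes

| parameter | default | rationale |
|---|---|---|
| subsample fraction | 0.8 | the framework's stated resampling scheme |
| repetitions per (algorithm, k) | 5 | enough for PAC resolution 1/(5·n_alg) per k with the full registry; configurable |
| knn_k (completion) | 5 | odd-vote majority over a local neighbourhood |
| PAC bounds | (0.05, 0.95) | common ambiguity window, open interval |
| LCE decay dc | 0.8 | cited method's customary value |
| k-modes / 2-means restarts | 10 / 20 | local-optimum insurance at negligible cost |
| SigClust n_sim | 1000 (library), 100 (pipeline default) | p resolution vs runtime |
| trim top_n | None (keep all) | trimming is an opt-in analysis decision |

Test and acceptance runs use n = 60–150 samples, p = 4–10 features and k
ranges up to 6; these sizes are where the brute-force oracles (exhaustive
permutations, pair counting) remain exact, and the full pipeline completes
in seconds per run.

## Known limitations

- CSPA uses a hierarchical cut, not graph partitioning; results need not
  match METIS-based implementations.
- The multivariate significance test is conservative at small n (see
  Calibration above).
- Rank aggregation's Monte-Carlo footrule search is a heuristic; it is exact
  only where exhaustive enumeration is feasible (verified for 3–4
  algorithms).
- Distance-matrix algorithms (PAM, linkages, DIANA) default to Euclidean
  distances; correlation dissimilarities are available but Ward linkage is
  restricted to Euclidean geometry.
- No feature-space subsampling; observations only.
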