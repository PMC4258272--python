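# Methods

## Model

`ccadiff` implements constrained correspondence analysis of a non-negative
gene × sample expression matrix. Genes play the role of sites at which
transcript "mass" is observed; samples are the observed phenotypes. The
chi-square standardisation

S = D_r^(−1/2) (X/n − r cᵀ) D_c^(−1/2)

removes the independence expectation and weights by the margins, so that
‖S‖²_F equals the total inertia I_T = χ²/n. Explanatory profiles Z (one
column per differentiation programme) act through the row-mass-weighted
least-squares projector Q onto span(D_r^(1/2) Z); the SVD of S* = QS gives
the constrained axes. All score types (LC and WA gene scores, sample
scores, standard and principal coordinates) follow the standard transition
formulae of correspondence analysis; biplot scores are D_r-weighted Pearson
correlations between Z columns and the standard LC gene scores, hence
always in [−1, 1].

Assumptions inherited from the method: the resource data must have large
between-class and small within-class variance (within-class variation is
discarded — only class means enter Z); explanatory columns must not be
collinear, because they are used for regression; both matrices must share
an identical, ordered gene universe and be non-negative.

### WA gene scores

The weighted-average gene scores are defined here as D_r^(−1/2) S V
(standard) and D_r^(−1/2) S V D_α (principal). The D_r^(−1/2) factor is
required for the classical transition identity to hold — in the
unconstrained limit the standard WA scores coincide with the principal LC
coordinates D_r^(−1/2) U D_α — and the package asserts that identity
numerically. Formulations that omit the factor differ only by a row-wise
rescaling and break that identity.

### Full-span limit and collinearity

Standardising Z to weighted mean 0 makes D_r^(1/2)Z orthogonal to
D_r^(1/2)1, so q columns span at most min(q, k−1) dimensions and the Gram
matrix ZᵀD_rZ is singular by construction when q = k. Q is therefore
computed from an SVD-derived orthonormal basis of the column space (rank
tolerance 1e-10 relative), not from the Gram inverse. Because D_r^(1/2)1 is
a left null vector of S, the projection still reproduces plain
correspondence analysis exactly in the full-span limit; this CA limit is
verified to 1e-10 in the tests and cross-checked against an independent R
implementation (vegan) on random instances. A collinearity error is raised
only when the effective rank falls below min(q, k−1) — a genuine linear
dependence among the variables, reported with the offending column names
found by pivoted QR.

### Axis orientation

SVD signs are arbitrary; for determinism each axis is oriented so that the
largest-magnitude biplot score on it is positive (for unconstrained CA: the
largest-magnitude standard sample score). For a single differentiation
variable d = μ_y − μ_x this orients the axis toward the *y* programme, so
higher sample scores always mean "more like y". Writing the contrast the
other way round mirrors the scores exactly and leaves the induced two-group
partition unchanged (only the group labels swap); near-degenerate singular
values make the axis *order* unstable under permutation, which is
documented rather than patched. Axes with α < 1e-10·α₁ are dropped.

## Differentiation variables and gene filters

d = μ_y − μ_x uses per-class arithmetic means over replicate columns. The
one-vs-rest contrast uses the unweighted mean of the other classes' class
means (not a pooled-sample mean), so unequal replicate counts do not skew
the "rest" profile. Feature selection for classification ranks genes by
|d| of the one-vs-rest contrast, with lexicographic gene-id tie-breaks so
the top-n list is prefix-monotone in n; how features "should" be chosen is
genuinely open, and this choice uses only quantities the method itself
defines.

The differential-expression filter combines a two-sample Welch t-test with
Benjamini–Hochberg FDR control and a fold-change cut (mean difference in
the top/bottom percentile over genes); both conditions must hold. A
moderated/shrinkage variance estimator was deliberately not used — the
filter is peripheral to the ordination and the plain Welch test keeps it
self-contained; with very few replicates (duplicates) the Welch p-values
cannot clear stringent FDR thresholds, in which case callers are directed
to the fold-change-only filters. A linear-scale lineage-specificity filter
(mean ≥ 5 expression units in the target class and ≥ 2-fold above every
other class) is provided for RNA-seq resource data.

## Classification

Two-group 1-D k-means is solved exactly: the optimal k=2 partition of
scalar scores is a threshold in the sorted order, found by scanning all
cuts with prefix sums (O(n log n)), so no initialisation or seed enters and
the result provably minimises within-cluster sum of squares. (Lloyd
iteration from extreme-point starts — a natural alternative — converges to
a local optimum on roughly 1% of random score vectors, which the exhaustive
oracle in the test suite exposes; exactness is the property the classifier
needs.) The higher-mean cluster is predicted positive. Sensitivity is
TP/(TP+FN), reported as undefined (None) rather than 0 when there are no
condition positives. The jackknife 95% interval is θ̄ ± 1.96·SE with
SE² = ((m−1)/m)·Σ(θᵢ − θ̄)² over leave-one-out replicates; replicates on
which the metric is undefined are dropped with a warning.

## Preprocessing

Gene matching across platforms is by case-folded gene symbol;
probe-to-symbol mapping is assumed done upstream. Duplicate gene rows are
collapsed by mean (order-independent), NA rows dropped, zero-margin rows
and columns dropped with logged counts. Negative values (possible in
log-scale microarray exports) are clipped to 0 by default because the
chi-square metric requires non-negative mass; a strict mode raises instead.
The log2 transform for RPKM requires pseudocount ≥ 1 so outputs stay
non-negative. Cross-platform rank normalisation maps each sample column
onto the mean sorted profile pooled over both datasets (quantile-
normalisation style, average ranks on ties); only ranks enter, so any
strictly increasing per-column distortion — the dominant cross-platform
artefact — is removed exactly.

## Synthetic data generator

The generator emulates the data shape the method assumes rather than raw
sequencing: k = 1000 genes, four classes with disjoint blocks of 25 marker
genes each, duplicate samples per class, expression = baseline 8 +
effect 4·[marker of own class] + N(0, 1), clipped at 0 — i.e. log2-like
units, between-class effect four times the noise SD, within-class variance
small. The optional knockout construct adds test samples of one class with
a chosen fraction of its markers silenced, emulating a mutant that fails to
execute its programme. What passing tests on this fixture show: the
pipeline recovers planted class structure and detects silenced programmes
under the assumed variance structure. What they do not show: robustness to
batch effects, correlated genes, count noise, mismatched platforms beyond
monotone distortions, or classes that are not well separated — real
mutant-versus-reference analyses must still be judged by the triplot and
inertia fractions, not by the synthetic benchmarks.

## Problem sizes and numerical choices

The test suite and the acceptance script run entirely on generated data:
50 synthetic pairs (1000 × 8/10) for recovery and knockout checks, 100–200
random small matrices for the algebraic identities, 1000 random score
vectors for the partition oracle, 200 null simulations (500 genes, 3 + 3
samples) for FDR calibration. These sizes make every property
non-trivially exercised while the whole suite completes in well under a
minute. Tolerances: 1e-10 for the CA limit and orthonormality, 1e-12 for
the standardisation formula, exact equality for partitions and
determinism. Degenerate inputs are errors, not silent results: constant
explanatory columns, identical class means, all-equal score vectors,
constant columns under rank normalisation, empty gene intersections.

## Known limitations

- Probe-to-symbol mapping is out of scope; analyses across platforms are
  only as good as the shared symbol universe.
- No partial (covariate-adjusted) variant, no permutation test on the
  constrained inertia, no detrending.
- The DE filter's Welch test is underpowered at duplicate-level replication
  (by design of the data the method targets); it is a gene *filter*, not an
  inference procedure.
- Percent-explained is undefined (NaN) for a matrix with zero total
  inertia (all rows proportional to the margins).
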