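# Methods

## The series-to-network mapping

For a series {x(i), i = 1…N}, coarse-graining at integer scale s produces
y^s(j) = (1/s) Σ_{i=(j−1)s+1}^{js} x(i), j = 1…⌊N/s⌋.  Trailing samples
beyond s⌊N/s⌋ are discarded, the standard convention of multiscale entropy
analysis; s = 1 reproduces the series exactly.

The horizontal visibility graph (HVG) links samples i < j when every
in-between sample is *strictly* below min(y(i), y(j)).  The limited
penetrable HVG (LPHVG) with penetrable distance L links i and j when the
number of in-between samples at or above min(y(i), y(j)) — the blockers —
is at most L.  L = 0 reduces exactly to the HVG, and the HVG edge set is a
subset of every LPHVG edge set.  The multiscale LPHVG (MLPHVG) is the map
s ↦ LPHVG(coarse-grain(x, s), L).

Tie rule.  The criterion is strict, so an in-between sample *equal* to the
lower endpoint blocks visibility, while two equal-height endpoints may
still connect if everything between them is strictly lower.  A constant
series at L = 0 therefore maps to the path graph.  This choice is applied
uniformly; any other convention would change edge sets only on series with
exact ties (probability zero for continuous signals).

Consequences used as test invariants: adjacent samples always connect
(vacuously), so every graph is connected; edge sets are invariant under
x ↦ a·x + b with a > 0; strictly monotone series map to the path graph;
the HVG of an uncorrelated continuous series has asymptotic mean degree 4,
a known exact result, which the test suite checks at N = 100,000 within
±0.05.

## Construction algorithm

Pair (i, j) is linked iff the (L+1)-th largest in-between value is
strictly below min(y(i), y(j)) (or fewer than L+1 samples lie between).
The implementation scans rightward from each node, maintaining the L+1
largest in-between values seen so far in a small sorted buffer, and stops
as soon as the buffer minimum can block every remaining pair — future
thresholds never exceed min(y(i), suffix-max beyond j), with the
suffix-max array precomputed once.  For irregular signals the scan
terminates after a few steps, giving near-linear behaviour; the worst case
(long monotone stretches) remains quadratic but terminates after O(L)
steps per node thanks to the suffix-max bound.  Correctness is defined by
`mlphvg.oracle.build_lphvg_oracle`, the literal count-all-blockers triple
loop, against which the fast construction is checked edge-for-edge on
random series in the test suite.

## Network statistics

Per node, C_i = τ_{i,Δ}/τ_i where τ_i = deg_i(deg_i−1)/2 counts triplets
centered on i and τ_{i,Δ} the closed ones; C_i = 0 when deg_i < 2 (only
possible for graphs not produced by the visibility construction, which the
metric layer does not assume).  The two per-graph features are the
arithmetic mean C̄ (zeros included) and the clustering coefficient entropy
E_C = −Σ p_i ln p_i, p_i = C_i / Σ_j C_j taken over nodes with C_i > 0.
The natural logarithm is used; the base only rescales E_C and cannot
affect classification.  Normalizing over strictly positive coefficients
avoids 0/0 on sparse profiles; an all-zero profile is assigned E_C = 0,
the continuous limit of the one-positive-node case.  E_C is bounded by
ln K, K the number of nodes with positive C_i.  The entropy normalization
is a single module-level choice (`mlphvg.metrics.clustering_entropy`); a
degree-weighted variant could be swapped in there without touching any
other layer.

## Classification protocol

Features are the (C̄, E_C) pair of one chosen scale.  The classifier is a
support-vector machine (scikit-learn SVC), by default an RBF kernel with
C = 1 and `gamma="scale"` on standardized features; all settings are
surfaced in `ClassifierConfig`.  For well-separated 2-D clusters the
kernel choice is immaterial, which the separable-data tests confirm.
Standardization statistics are computed on the training portion of each
fold only, so no test information leaks into the fit; a decision value of
exactly 0 is assigned to class 0 for determinism; training folds with zero
variance in both feature dimensions fall back to majority-class prediction
with a warning.

Two protocols are implemented exactly as used for the EEG-style
experiment: leave-one-out (n fits, one per held-out sample; accuracy =
fraction correct over all samples) and k-fold repeated R times (default
k = 10, R = 10) with an independent random stratified partition per
repeat, per-repeat accuracy over all samples, and the final accuracy the
mean of the R per-repeat values.  Partitions are stratified by default so
every fold contains both classes; on balanced data plain and stratified
partitions coincide in expectation, and `stratified=False` restores plain
partitioning.  All partitions derive from an explicit seed (repeat r uses
seed + r), making every reported accuracy bit-reproducible.

## Synthetic data

The generators provide signals whose graph-level behaviour is known:
i.i.d. uniform noise (mean-degree-4 limit), exactly periodic sinusoids
(periodic degree sequence; phase is computed modulo the period so repeated
values are bitwise equal), stationary AR(1) with Gaussian innovations, and
logistic-map trajectories x_{t+1} = r·x_t(1−x_t) (chaotic at r = 4,
period-2 at r = 3.2; burn-in discarded).

The two-class dataset stands in for the healthy-vs-ictal EEG benchmark
(100 surface-EEG segments per class, 4097 samples at 173.61 Hz): class 0
is AR(1) noise with coefficient 0.9 emulating short-memory background
activity, class 1 is fully chaotic logistic dynamics emulating strongly
nonlinear ictal structure.  Defaults are 100 signals per class of length
4096, matching the benchmark's scale.  Every signal is standardized to
zero mean and unit variance, so the classes differ in temporal structure
only — the graph mapping is amplitude-invariant anyway, so no amplitude
cue can leak into the features.  What passing the surrogate experiment
shows: the complete pipeline (coarse-grain → LPHVG → clustering features →
SVM cross-validation) discriminates signals that differ in nonlinear
temporal structure.  What it does not show: performance on real EEG, whose
nonstationarity, artifacts, spectral content and between-subject
variability the surrogate does not emulate.

## Numerical choices and limitations

- Scale factors are a user parameter with default 1–5; the penetrable
  distance defaults to L = 1.  Graph construction requires ⌊N/s⌋ ≥ 2.
- Node indices are 0-based internally and 1-based in all serialized
  outputs (edge lists, GraphML node attribute `t`).
- Edge lists are written 1-based, i < j, lexicographically sorted, no
  header — byte-stable across runs for regression diffing.
- Non-finite samples are rejected at load time with the offending line
  number rather than silently dropped, since dropping would silently
  change the graph topology.
- The acceptance script uses 100 random series (lengths 10–500) for the
  oracle comparison, 100,000 samples for the mean-degree limit, and the
  full 100 + 100 × 4096 surrogate experiment; these sizes keep the whole
  run under a minute while leaving the stochastic checks well inside their
  tolerances.
- Only undirected, unweighted horizontal visibility variants are
  implemented; natural (non-horizontal) visibility, weighted or directed
  variants, and streaming updates are out of scope.
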