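# Methods

## Contact model

The package models the intra-chromosomal Hi-C contact frequency of bins
`i < j` as a product of three effects:

```
H'_ij = exp((α_i + α_j)/2) · (j − i)^β / exp( Σ_{i<k≤j} r_k )
```

* **Distance decay** `(j−i)^β`: contact frequency falls as a power law of
  genomic distance, the dominant feature of every Hi-C map. `β` is boxed to
  `[−2, −1]`, the range reported across Hi-C studies; the box is a hard LP
  constraint, not a post-hoc clamp.
* **Bin bias** `α_i` (log scale, free sign): absorbs coverage, GC and
  mappability effects, so raw counts can be modelled without prior matrix
  balancing. Only the pair mean `(α_i+α_j)/2` enters, mirroring how
  multiplicative bin biases factorise.
* **Insulation** `r_k ≥ 0`: every contact spanning bin `k` is attenuated by
  `e^{−r_k}`. A TAD boundary shows up as an isolated bin with large `r_k`.
  The sum runs over `i < k ≤ j` — half-open on the left, so a boundary at
  the left endpoint of a pair does not attenuate it. This convention is
  applied identically in fitting, prediction and scoring.

The model has no loop/peak term and no A/B-compartment term; it captures
decay plus block structure only.

## Fitting

Because contact counts span orders of magnitude, residuals are taken on the
log-ratio scale: the fit minimises `Σ |log H_ij − log H'_ij|` over observed
pairs. With one slack variable per pair this L1 problem is an exact linear
program, solved with the HiGHS solver through `scipy.optimize.linprog`
(deterministic: same input, same solution). The reported objective is
re-evaluated from the returned parameters and must agree with the solver's
optimum to within `lp_tolerance` (default 1e-6), guarding against indexing
errors in the LP construction.

Practical reductions, all configurable:

* **Pair distance cutoff** (`max_pair_distance`, default 50 bins): only
  pairs with `1 ≤ j−i ≤` cutoff enter the objective. 10 bins suits
  fine-grained insulation profiling, 100 bins suits fits that feed deletion
  scoring with a 100-bin flank.
* **Segmentation** (600-bin segments, 50-bin overlap): each segment is an
  independent LP. The overlap between consecutive segments is split at its
  midpoint into disjoint *cores*; every bin takes its `α`, `r` and `β` from
  the one segment whose core owns it. Stitching by ownership rather than
  averaging keeps boundary spikes in `r` sharp. `β` is per segment; a pair
  spanning a seam uses the mean of its two bins' `β`, which is continuous
  across seams and reduces to the segment value inside one.
* **Zero counts** are excluded from the objective (no pseudocounts): a zero
  has no finite log ratio, and imputing zeros is an open normalisation
  problem in its own right.

L1 fits can have alternate optima; only the objective value and downstream
scores are contractual. Parameter-level tests use synthetic instances built
to be identifiable (isolated insulators, multiple distances). The
restricted-parameterisation options (`fix_alpha`, `r_support`) exist so
that small LP instances can be compared against exhaustive grid search on
the same parameter space; the standard fit never uses them.

## Post-deletion prediction

A homozygous deletion of bins `x..y` is assumed to change no parameter: it
shortens distances and removes the deleted bins' insulation. For `i < x`
and `j > y`:

```
G_ij = exp((α_i + α_j)/2) · d_new^β / exp( Σ_{i<k≤x−1} r_k + Σ_{y<k≤j} r_k ),
d_new = (j − i) − (y − x + 1) ≥ 1.
```

Pairs on one side of the deletion keep their fitted value by assumption.
Since `d_new < j − i` with `β ≤ −1`, and the surviving insulation is a
subset of the original, `G_ij ≥ H'_ij` on every cross pair: under this
model a deletion can only create interactions, never destroy them. (This
direction is what makes the score non-negative; it is enforced and tested.)

## Scoring

A pair is deemed to interact when its bias-normalised frequency
`v = H'_ij / exp((α_i+α_j)/2)` satisfies `f(v) = 1{v ≥ δ}`. The threshold
`δ` is calibrated from a chromatin-loop call set: loop anchors are assumed
to interact, so `δ` is the minimum normalised model frequency over loop
anchor pairs (a quantile mode is available for robustness to outlier
loops; a raw-count mode uses matrix entries instead of model values). By
default the fitted values are thresholded, never raw counts — raw counts
are noisy.

The score of a deletion sums `w_ij (f(G_norm) − f(H'_norm))` over
`i ∈ [max(1, x−flank), x−1]`, `j ∈ [y+1, min(n, y+flank)]` with
`flank = 100` bins (500 kbp at 5-kbp resolution) and `w ≡ 1`, so the score
is the integer count of pairs whose interaction status flips on. `δ` is
calibrated once per matrix/loop-set and reused for every deletion and
permutation. Deletions touching a chromosome end such that one flank is
empty score 0 with a warning. Normalisation cancels `α` exactly, so the
score depends only on distances and insulation — comparable across
datasets with different bias profiles.

## Permutation null

To test whether high-scoring deletions are depleted in an observed set,
each permutation re-places the same deletions uniformly at random on the
chromosome, preserving the per-chromosome count and the exact multiset of
bp lengths. Permuted deletions may overlap one another (the simplest null
consistent with length/count preservation; a rejection-sampling
non-overlap mode exists). Each permuted set is scored with the same fitted
parameters and the same `δ` — no refitting. For each score cutoff the
report gives the observed exceedance count, the per-permutation null
counts, the depletion-sided empirical p-value
`(1 + #{null ≤ observed}) / (1 + n_perm)`, and a normal-approximation
z-score as a convenience. A permuted interval that happens to cover no
whole bin removes nothing at matrix resolution and scores 0.

Because the exceedance count is integer-valued, the empirical p-value is
discrete; its null distribution approaches uniformity only when the count
has wide support. The calibration test therefore uses 250 mixed-length
deletions, where the Kolmogorov–Smirnov check against uniformity is
well-behaved.

## Synthetic data

The generator draws matrices from the model itself:
`H_ij = count_scale · H'_ij(truth) · exp(ε_ij)`, `ε ~ N(0, σ²)` i.i.d.
Noise is multiplicative log-normal because the fit is L1 on the log scale
(a Poisson count mode is not provided; at the count scales used the
log-normal dominates). `σ = 0` reproduces the model exactly, so noiseless
fixtures must fit to objective zero — a strong end-to-end check on the LP.
Ground-truth parameters are always emitted beside the data; tests never
re-derive them.

`generate_benchmark` adds matched deletion sets — boundary-*covering*
(centred on insulator bins) and boundary-*sparing* (equal bin length,
placed ≥ 2 bins clear of every insulator) — plus a calibration loop set.
Loop anchors are the highest-frequency pairs per anchor distance over
2–10 bins, interleaved across distances. Spanning the distance range
matters: it puts `δ` near the 10-bin decay level, so removing a boundary
flips mid-range pairs; with only adjacent-bin anchors `δ` would sit so
high that only distance shortening could flip pairs and the two deletion
sets would not separate.

What the generator does **not** emulate: loop peaks, compartment
checkerboards, nested sub-TAD hierarchy, mappability dropout, and
integer-count sparsity with true zeros. Passing tests therefore
demonstrate correctness of the estimator and score under the model's own
assumptions plus multiplicative noise — not robustness to every artefact
of experimental Hi-C.

## Problem sizes and numerical choices

Tests and the acceptance script run chromosomes of 200–600 bins with pair
distance cutoffs of 10–15 bins, segment LPs of a few thousand variables —
sizes chosen so the full pipeline (fit, calibrate, score, 200-permutation
null) completes in seconds to a few minutes on one CPU while leaving every
code path identical to larger runs. Scoring one deletion with the full
100-bin flank takes well under a millisecond after fitting, so
population-scale scoring (thousands of deletions × 1000 permutations) is
dominated entirely by the one-off model fit.

Known limitations: heterozygous and overlapping deletions are out of scope
(scores assume homozygous, independent events); same-side contact changes
are assumed absent; inversions/translocations are not modelled; `r` is
inferred from Hi-C alone (no CTCF ChIP-seq input); raw counts are expected
— balanced matrices will push bias into `α` harmlessly but change the
meaning of `count_scale`.
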