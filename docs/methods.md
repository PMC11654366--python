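# Methods

## Problem and model

A doublet is the pooled transcriptome of two physically attached cells
captured and sequenced together — here an intentional observation (as in
paired-cell RNA sequencing of hepatocyte–endothelial clumps), not an
artifact to remove.  scduet decomposes a doublet into the two reference
single cells that compose it, and then asks which genes distinguish the
reference cells that participate in doublets from those that do not
(neighboring-cell-dependent expression).

The decomposition model is a pair of fully connected softmax classifiers,
one per cell type.  Training data are artificial doublets built from the
two reference panels by convex mixing of raw UMI count vectors,

    mix = α · umi_A + (1 − α) · umi_B,   α ∈ {0.1, 0.2, …, 0.9},

with the recipe (index_A, index_B, α) kept as ground truth.  Each network
receives the counts-per-million (CPM) profile of a mixture and is trained
with categorical cross-entropy and Adam to output the index of the
contributing cell of its own type; the output layer is a softmax over the
K reference cells of that type, so every score vector is a probability
distribution.  At inference the highest-scoring cell per type is the
predicted component, and any reference cell scoring above a small cutoff
(default 0.01) in at least one real doublet is "selected" as having
participated in an interaction.

Assumptions worth making explicit: the doublet transcriptome is a linear
combination of its components (no clump-specific capture efficiency or
cross-contamination); the reference panels contain the actual component
cells (the label space is the panel, so the model memorizes reference
profiles by design — generalization is over mixtures and mixing factors,
not over unseen cells); and exactly two cells contribute.

## Architecture and training defaults

* Hidden layers 2048 / 1024 / 512 rectified-linear units; output softmax
  of width K (the reference panel size).  Scaled-down panels use smaller
  hidden stacks (the benchmark below uses 256/128/64 for 200-cell panels).
* Loss: categorical cross-entropy.  Optimizer: Adam, learning rate 1e-3,
  decay coefficients (0.9, 0.999), batch size 256, 20 epochs.  No dropout
  or weight decay.  Weights start uniform on ±sqrt(1/fan_in); biases at 0.
* Inputs are CPM vectors multiplied by a fixed constant 1e-4 (so each
  profile sums to 100).  The constant is a pure units choice — scores are
  invariant to any rescaling of the raw counts — but it matters
  numerically: raw CPM entries reach 1e4–1e5, which saturates the first
  layer under fan-in initialization and stalls optimization at the
  uniform-prediction plateau.  An optional log1p(CPM) input transform
  exists but is off by default.
* All randomness (initialization, shuffling, recipe sampling) flows from
  explicit seeds; identical seed, data, and backend reproduce identical
  parameters and scores.  Bit-reproducibility across BLAS backends is not
  promised.

The engine is a compact numpy implementation (`scduet._nn`) of exactly
these pieces — dense layers, ReLU, softmax, cross-entropy, Adam — in
single precision.

## Gene filtering and normalization

Genes are kept when at least `min_umi` (1) UMI appears in at least
`min_cell_frac` (4%) of cells of *every* cell type (conjunctive reading;
a disjunctive "any type" mode is available as a flag).  Normalizations:

* `cpm` — per-cell scaling to 1e6 (model input);
* `lognorm10k` — per-cell scaling to 1e4 then ln(x+1) (differential
  expression input);
* `residual` — per-gene ordinary least squares of lognorm10k expression
  on the per-cell total UMI count (with intercept), residuals returned;
* `scaled` — per-gene z-score across cells using the population (1/n)
  standard deviation, without clipping; zero-variance genes map to zeros
  rather than raising, since they carry no information for a rank test.

Doublet inputs whose gene list differs from the model's are aligned by
gene id, zero-filling absent genes; fewer than 50% overlap is an error
(a wrong-species/wrong-panel guard).

## Differential expression

The selected cells of one type are compared with the unselected cells of
the same type, per gene, with the two-sided Wilcoxon–Mann–Whitney test on
the fully processed values (lognorm10k → residual → scaled).  P-values
use exact enumeration when the product of group sizes is ≤ 200 and the
pooled sample is tie-free, and the tie-corrected normal approximation
with continuity correction otherwise.  Benjamini–Hochberg controls the
FDR.  Effect size is log2((mean₁+b)/(mean₂+b)) with b = 1, where the
means are taken on the 10,000-normalized *linear* scale: a pseudo-count
is only meaningful for non-negative means, which the regressed/scaled
values are not.  Both the test scale and the mean scale are configurable
(`DEConfig`).  A gene is flagged when adjusted p < 0.05 and
|logFC| > 0.5; the sign of logFC assigns the up/down direction.

## Evaluation

Doublets are split into five shuffled folds; the reference single cells
are shared across folds (only mixtures are held out), which mirrors how
the task is posed — the panel is the label space — and is documented here
as a deliberate leakage rather than "fixed".  Reported per method and
cell type:

* exact-cell accuracy — correct argmax predictions / all predictions
  (the headline metric);
* micro-averaged one-vs-rest confusion counts over all (doublet,
  reference cell) decisions.  A correct argmax contributes 1 TP and K−1
  TN; a wrong one contributes 1 FP, 1 FN, and K−2 TN.  From these:
  accuracy, FNR = FN/(TP+FN), and *two* false-positive rates —
  `fpr_printed` = FP/(FP+FN), reproducing the formula as printed in the
  method description this package implements, and `fpr_standard` =
  FP/(FP+TN), since the printed denominator is a probable typo.  Metrics
  with zero denominators are reported as NaN, never as 0;
* cell-type-level accuracy — whether the predicted reference cell carries
  the same type label as the true component.  With pure per-type panels
  this is structurally 1; it becomes informative only for mixed panels.

The logistic-regression comparator is scikit-learn's multinomial fit with
pinned "defaults" (L2 penalty, C = 1.0, tolerance 1e-4, lbfgs, up to
1000 iterations) so the benchmark survives library-default drift.  Naive
Bayes defaults to the multinomial variant on CPM values rounded to
integer pseudo-counts (count-like data), with a Gaussian-on-CPM option.
Both baselines consume the same CPM inputs, folds, and evaluation code as
the networks.

## Synthetic data generator

The generator emulates the regime the method was designed for: two cell
types with distinct programs, strong per-cell depth asymmetry, and an
interacting subpopulation.  Counts are gamma-Poisson (negative binomial,
variance μ + φμ²) with a single shared dispersion φ.  Per-type rate
vectors share a lognormal base program; a `marker_frac` fraction of genes
is made type-exclusive (rate ×0.01 in the other type, split evenly
between the types); rates are renormalized so expected per-cell totals
equal `depth_a` / `depth_b`.

Defaults — chosen once as a realistic desk-scale analogue of the
hepatocyte/LEC setting — are 200+200 cells, 2,000 genes, mean depths
20,000 vs 2,000 UMI (the order-of-magnitude UMI gap observed between
hepatocytes and liver endothelial cells), dispersion 0.3, 10% marker
genes, 20 signature genes spiked 4-fold in a random half of the type-A
cells.  The spike adds an independent negative-binomial component with
expectation (fc−1)·μ, so the expected fold change is exactly `fc` and
fc = 1 is a byte-identical no-op.  Signature genes are drawn from the
non-marker (shared) genes, and only type-A cells are spiked, matching the
one-sided (hepatocyte-side) expression response the method was built to
detect.  Paired-cell doublets pair interacting type-A cells with random
type-B cells through the same α-mixing equation.

What the generator does *not* model: ambient RNA, batch effects,
cross-contamination, gene–gene correlation beyond the shared program, or
clumps of more than two cells.  Passing tests therefore certify the
pipeline's statistical machinery and its behavior under depth asymmetry,
not performance on any particular tissue.

## Problem sizes used in the checks

The cross-validated benchmark in the acceptance checks runs the default
generator conditions (200+200 cells, 2,000 genes, depths 20,000/2,000),
20,000 artificial doublets, hidden layers 256/128/64, 20 epochs, five
folds.  At these conditions the deep type is recovered essentially
perfectly, both types sit far above the 1/K = 0.005 chance level, and
the shallow type is the harder one for every method — most severely for
logistic regression, reproducing the qualitative depth-asymmetry pattern
the full-scale method reports.  Unit tests use smaller instances (tens
of cells, hundreds of genes) sized for sub-second runs.

## Numerical choices and degenerate inputs

* CPM of an all-zero vector, zero-total cells in lognorm10k, regression
  with fewer than two cells, and empty selected/unselected DE groups all
  raise explicit errors.
* Argmax ties resolve to the lowest reference index, deterministically.
* Selection uses a strict inequality (score > cutoff), so a uniform
  1/K score vector selects nothing at cutoff 1/K.  Selection aggregates
  as a union over doublets by default (the differential test compares
  reference cells, not doublets); a per-doublet mode exists.  Note that
  the 0.01 default cutoff is calibrated to panels of hundreds-to-
  thousands of cells; for toy panels with K ≲ 100 the uniform score 1/K
  already exceeds it.
* Mixtures are kept real-valued; an optional flag rounds them.  CPM
  downstream makes rounding immaterial.
* Constant genes under the vectorized rank test receive p = 1 (no
  evidence) instead of NaN.

## Known limitations

* The decomposer cannot identify cells absent from its reference panels,
  and panels must be large enough that the 0.01 selection cutoff is
  meaningfully sparse.
* Exactly two components are assumed; larger clumps would need a third
  network and are out of scope.
* Cross-validation shares reference cells between folds (see above), so
  reported accuracies measure mixture-level, not cell-level,
  generalization.
* The differential test inherits the usual caveat of selection-based
  group definitions: selection noise propagates into the DE contrast.
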