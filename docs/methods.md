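# Methods

## Model

A sample (patient) is a bag of cells.  Cell *j* of annotated type *i* has a
feature vector x_ij ∈ R^m — log-normalized expression or a precomputed
embedding; the model is agnostic to which.  An encoder of one or two dense
ReLU layers maps each cell to h_ij ∈ R^d.  Aggregation is hierarchical:

- within type *i*: h_i = Σ_j α_ij h_ij, with α_ij = 1/n_i (CTA) or
  α_ij = softmax_j(wᵀh_ij + b) (HA);
- across the types present in the sample: h = Σ_i β_i h_i, with
  β_i = softmax_i(vᵀh_i + b′).

A linear head gives probabilities: sigmoid(w̄ᵀh + b̄) for two classes,
softmax(Wh + b) otherwise (a flag forces the softmax head at C = 2 when a
per-class decomposition is wanted).  Training minimizes summed cross-entropy.

Assumptions worth stating explicitly:

- **Cell-type annotations are inputs**, not estimated; noisy annotations
  degrade the hierarchical models (measured by the annotation-noise
  experiment) and novel types at prediction time are an error by design.
- **Absent types carry no weight.** A type with n_si = 0 has no
  representation and is excluded from the type softmax (equivalently masked
  with −∞ logits); it is never imputed.
- **Type attention is composition-blind.** β depends on the type
  *representations*, which are count-normalized means, so the relative
  abundance of a type influences the model only through presence/absence
  (and, in HA, through which cells dominate α).  A label signal carried
  purely by type proportions is largely invisible to CTA/HA while a
  mean-pooling model sees it; this is a property of the architecture, not a
  bug, and it shapes what the synthetic generator injects (expression
  shifts by default, a separately switchable composition tilt for exactly
  this reason).
- The biases b and b′ inside the two attention softmaxes cancel and are
  unidentifiable; they are kept for fidelity to the model definition and
  excluded from equivalence reasoning.

Two ablations drop the hierarchy: `mean_pool` (h = mean over all cells,
a pseudo-bulk representation) and `cell_att` (one softmax over all N cells,
ignoring types).  Useful identities, all enforced by tests: HA with w = 0
equals CTA; `cell_att` with w = 0 equals `mean_pool`; `cell_att` equals HA
on samples with a single cell type; Σ_j α_ij = Σ_i β_i = Σ_ij γ_ij = 1 with
γ_ij = β_i α_ij.

## Interpretability

Linear pooling + linear head make the logit decomposition exact:
z + bias = Σ_ij γ_ij (W h_ij) + bias = Σ_i β_i (W h_i) + bias.  The
cell-type importance score κ_i contrasts the mean type-level logit
ℓ_si = β_si w̄ᵀh_si between classes; samples lacking type *i* enter their
class average with ℓ_si = 0, which preserves Σ_i ℓ_si = z.  For C > 2 a
one-vs-rest generalization (target-class logit component, target class vs
all others) is provided; it reduces to the binary score at C = 2 and is this
package's own construction, flagged as such.

Significance: the model is refit on label-permuted cohorts (same
hyperparameters as the observed fit — re-tuning per permutation would be
computationally prohibitive and the fixed-hyperparameter null is the common
approximation); empirical p-values use the add-one estimator
p_i = (1 + #{|κ_perm| ≥ |κ_obs|}) / (n_perm + 1), two-sided on |κ| by
default (a type can drive either class; a one-sided switch exists).
Benjamini–Hochberg FDR is the default correction (Holm and Bonferroni
selectable); n_perm defaults to 99.  Under a label-independent generator
the raw p-values are uniform — the calibration check below measures this
rather than assumes it.

## Optimization

Gradients of the loss with respect to every parameter are derived
analytically (backpropagation through the head, both softmax stages and the
encoder) and implemented as one vectorized pass over the concatenated cells
of a batch using segment reductions, so ragged bags need no padding and
padding can never leak into a softmax.  The batch path is tested for
bitwise agreement with a per-sample reference implementation and against
finite differences.  The optimizer is Adam (default learning rate 1e-3,
mini-batches of 8 samples, optional L2 weight decay on weights but not
biases, optional early stopping on training loss).  Encoder and head
weights use fan-in-scaled Gaussian initialization; the attention vectors w
and v start at scale 0.01 so the initial model is near mean pooling — the
least-committal prior, letting early training decide where attention is
warranted.  All randomness flows from explicit integer seeds; identical
seeds give identical parameter trajectories.

Degenerate inputs: softmaxes subtract the maximum logit before
exponentiation; probabilities are clamped at 1e-12 inside the log; a
non-finite training loss aborts with diagnostics (and inside model
selection scores that grid point as AUC 0.5 with a logged warning).

## Evaluation protocol

Repeated, stratified, nested k-fold cross-validation: outer folds (default
10) estimate generalization; per outer fold, each hyperparameter grid point
is scored by the AUC of its stacked inner-fold predictions (default 5 inner
folds; at cohort sizes of 40–60 samples, 10 inner folds would leave
3-sample test sets), the winner is refit on the full outer-train split, and
metrics (AUC, F1, accuracy, precision, recall) are computed once per repeat
on the stacked out-of-fold predictions.  Binary F1/precision/recall use the
positive class at threshold 0.5; multi-class uses argmax, macro averaging
and one-vs-rest macro AUC.  Stratification by class label avoids degenerate
folds at small S.  The default grid spans hidden_dim {32, 64}, depth {1, 2},
learning rate {1e-3, 1e-4} and weight decay {0, 1e-4}, and is fully
config-driven.

Three robustness experiments: training-size curves (stratified random
splits at 25/50/75% train fraction, 100 splits each), per-sample cell
subsampling (ceil, at least one cell kept), and annotation randomization
(a ceil-fraction of cells per sample relabeled uniformly over all I types —
the redrawn label may coincide with the original).  Noise level 0 applies
no perturbation and no random draws, so it reproduces the baseline CV
bitwise under shared seeds.

## Synthetic cohorts

The generator emulates the hierarchical structure the models assume.  Per
cohort: type centroids drawn N(0, between_type_sd²) per feature.  Per
sample: cell count uniform on a range; type proportions Dirichlet; each
type absent with probability dropout_rate (at least one type kept);
cells multinomial across types; features = centroid + N(0, within_type_sd²).
Positive samples add the effect size δ to every feature of (a configurable
fraction of) driver-type cells, and/or tilt the driver proportions
(composition channel).  A fraction of annotations can be corrupted
uniformly.  Everything is deterministic given the seed, and the
subset-selection draws are made independently of δ so signal and null
cohorts with equal seeds share the same noise stream.

Defaults define the reference study conditions: 30 + 30 samples, I = 5
types at Dirichlet concentration 5 (driver ≈ 20% abundance), m = 50
features, 50–150 cells per sample (desk-scale, comparable to a downsampled
immunotherapy cohort), within/between SD 1.0, dropout 0.1, δ = 2 on driver
type 0.  The generator produces Gaussian features in the space the models
consume; an optional negative-binomial count mode (log-link around the
Gaussian field) feeds the count-preprocessing path
(scale-to-10⁴-then-log1p, with an optional cohort-wide filter removing
genes expressed in fewer than five cells).  What it does **not** emulate:
library-size variation, batch effects, dropout-induced zero inflation,
gene–gene correlation.  Passing tests therefore demonstrate correctness of
the machinery and qualitative behavior under the assumed structure, not
performance on real scRNA-seq data.

The *hierarchical-signal* condition used by the ablation comparison spreads
a weak shift (δ = 0.5, half the within-type noise) over all driver-type
cells with between-type SD 1.5: no individual cell is informative, only the
annotated type's mean, which is precisely the regime where pooling within
annotated types should pay off.  A rare-driver variant (shift confined to a
small fraction of driver cells) exists for exploring the HA-vs-CTA
contrast; that comparison is exploratory, not a gate.

## Acceptance measurements

`scripts/acceptance.py --seed <s> --out <json>` recomputes, from scratch:
max decomposition error (100 random model × sample draws), max attention
normalization error, max mode-equivalence deviation, max deviation from a
straight-line pure-Python oracle on a hard-coded micro-cohort, the null
calibration of the permutation test (50 null cohorts of 10 + 10 samples,
m = 10, I = 5, hidden_dim 4, 12 epochs, n_perm = 99 → 250 p-values), the
driver recovery rate (20 default signal cohorts, hidden_dim 8, 15 epochs,
n_perm = 99), nested-CV AUC on the default signal and null cohorts (10
outer folds, 5 repeats, single-point grid), mean AUC per mode on 5
hierarchical-signal cohorts × 2 CV repeats, and the annotation-noise curve
(0 / 0.25 / 0.5, 5 repeats) with its bitwise noise-0 baseline check.  The
reduced model sizes and epoch counts are deliberate desk-scale choices;
the cohort-generating conditions are the defaults above.

## Known limitations

- Sensitivity to annotation quality is inherited from the model class.
- The permutation null holds hyperparameters fixed across refits.
- The multi-class importance score is a one-vs-rest construction, not a
  canonical definition.
- The numpy training loop targets desk-scale cohorts (tens of samples,
  10²–10⁴ cells per sample); it is not distributed and has no GPU path.
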