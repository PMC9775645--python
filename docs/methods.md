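# Methods

## Problem

Given a protein sequence and a candidate serine, threonine or tyrosine
position, predict whether the site is phosphorylated. Each candidate is
represented by the 33-residue window centred on it (16 residues of flank on
each side); windows that run past a protein terminus are padded with the gap
symbol `-`. Non-standard residues (B, J, O, U, X, Z) are mapped to the gap
symbol on input, with a warning.

## Dataset construction

Training sets follow the standard convention for this task: positives are
the annotated phosphosites; negatives are every *other* residue of the same
type (S, T or Y) on proteins that carry at least one confirmed positive
site. Proteins without any positive annotation contribute no negatives,
because their unannotated sites may simply be unmeasured. Prediction mode
has no such restriction: every S/T/Y position is a candidate. Exact
duplicate windows are collapsed (a window labelled both positive and
negative is kept as positive); homology reduction below an identity
threshold is expected upstream with a dedicated clustering tool.

Because negatives outnumber positives severalfold, training uses the
EasyEnsemble strategy: `k` balanced subsets, each containing all positives
and an independent without-replacement draw of negatives of equal size; one
model is trained per subset and prediction scores are averaged.

## Encodings

| Scheme  | Shape      | Description |
|---------|-----------|-------------|
| OneHot  | 33 × 21   | 20 amino acids + gap/null slot |
| AAindex | 33 × 10   | 9 physicochemical properties, min-max normalised over the 20 amino acids, + gap flag |
| AAPCA   | 33 × 6    | 5 principal-component property descriptors + gap flag |
| GloVe   | 33 × d    | subword (n-gram) embeddings trained on the dataset itself |
| AAglove | 33 × 10×2 | AAindex and 10-d GloVe as two channels, spliced along the feature axis for network input |

The AAindex properties (residue composition, flexibility, hydropathy, net
charge, side-chain hydrophobicity, volume, molecular weight, and two
solvent-accessibility scales) and the PCA descriptors ship as TSV data files
with the package; sources are referenced in the file headers.

GloVe embeddings are fit to a symmetric within-window co-occurrence matrix
by the weighted least-squares objective
`Σ f(X_ij)(w_i·w̃_j + b_i + b̃_j − log X_ij)²` with
`f(x) = min(1, (x/x_max)^0.75)`, optimised full-batch with AdaGrad; the
final embedding is `w + w̃`. Gap-containing and out-of-vocabulary subwords
encode as zero vectors.

## Network

Input: the encoded window, `(33, D)`. Defaults in parentheses.

1. **Convolutional stack** — width-1 convolution (300 filters), ReLU,
   dropout (0.5), batch normalisation; width-9 convolution (100 filters),
   ReLU, dropout, batch normalisation.
2. **Residual shortcut** — two width-9 convolutions with a ReLU between,
   added to the block input (ablatable).
3. **Primary capsules** — depthwise width-9 convolution (stride 2, pad 2)
   followed by a pointwise convolution, reshaped to `n_primary` capsules of
   dimension `d_primary` (60 × 8) and squashed.
4. **Routing** to 2 class capsules of dimension 10.
5. **Decoder** — three fully connected layers (512, 1024, `33·D`)
   reconstructing the encoded input, either from both class capsules
   (unconditional) or with every capsule except the target/predicted one
   zeroed (mask mode).

**Self-attention routing** (single pass): votes `Û(i,j) = u_i·W(i,j)`;
pairwise vote agreement `A(i,i′,j) = ⟨Û_ij, Û_i′j⟩ / √d_next`; coupling
coefficients `C_i = softmax_j Σ_i′ A(i,i′,j)`; output
`V_j = squash(Σ_i Û_ij (C_ij + B_ij))` with a learned additive bias `B`.
Dynamic routing (3 iterations of routing-by-agreement) is retained as the
ablation baseline.

**Squash variants**: `exp` scales `s` by `(1 − e^{−‖s‖})/‖s‖`; `classic`
scales by `‖s‖/(1+‖s‖²)`. Both map zero to zero, preserve direction, and
compress lengths into [0, 1).

The positive-class probability is the softmax over the two class-capsule
lengths. Losses: cross-entropy over the capsule lengths (default) or the
margin loss with `m+ = 0.9`, `m− = 0.1`, `λ = 0.5`; plus the reconstruction
mean-squared error weighted by 0.0005.

## Training

Adam (learning rate 1e-3), batch size 128, up to 30 epochs, early stopping
on a stratified 10 % validation split with patience 5 and restoration of the
best-validation weights. All runs are seeded and reproduce byte for byte.

## Evaluation

Accuracy, sensitivity, specificity and MCC from the confusion matrix at
threshold 0.5 (a score equal to the threshold counts as a positive
prediction; MCC is defined as 0 when a marginal is empty). AUC is computed
from midranks (the normalised Mann-Whitney statistic), which equals the
trapezoid area under the ROC curve with tie handling. Cross-validation is
stratified, optionally protein-disjoint so that no protein's sites are split
across folds. A subsampling harness draws stratified fractions of the
training pool (fresh draw per repeat) against a fixed held-out test split to
trace learning curves.

## Synthetic benchmark

Real phosphoproteome corpora require large downloads and long multi-repeat
training runs, so the package ships a generator with known ground truth:
each sample is a random parent protein (length 60–200, residues drawn from a
uniform or database-wide background) with the centre residue fixed and, for
positives, a motif planted around it — by default lysine at offsets −3 and
+2 with probability 0.8 each. A configurable fraction of sites (default
0.1) is placed near a terminus to exercise gap padding.

Because each motif offset is an independent binary observation, the exact
Bayes-optimal AUC is computable by enumerating all motif-outcome patterns
and scoring them by likelihood ratio: for the default conditions it is
0.964. This ceiling turns "did the model learn?" into a quantitative
check — the network should approach but not exceed it (boundary truncation
makes it a slight over-bound), and a motif-free null benchmark must score at
chance.

## Numerical and engineering choices

- **Autodiff**: a small tape-based reverse-mode engine over NumPy arrays
  (`ecapsp.autodiff`). Every operation is validated against central finite
  differences. Stride-1 convolutions are computed as a single
  `(B·L, C) × (C, k·F)` GEMM followed by a banded diagonal sum, fused into
  one tape node so neither the `(B, L, k, F)` intermediate nor its gradient
  is materialised; backward runs one GEMM per kernel tap. Backward closures
  never capture their output tensor and tapes are released after
  `backward()`, so memory is reclaimed by reference counting (peak ≈ 0.4 GB
  for a batch-128 step of the reduced configuration).
- **Stability**: softmax and cross-entropy use a max-shifted log-sum-exp;
  capsule norms add 1e-9 inside the square root; non-finite values at any
  routing stage raise a dedicated `NumericalError`.
- **Problem sizes**: the acceptance computation uses a reduced network
  (conv filters 100/50, 30 × 8 primary capsules) that keeps every
  architectural component but fits a full training run in ~2 minutes on one
  CPU; the full-scale defaults (300/100, 60 × 8) remain the library
  defaults and train at ≈ 1.3 s per batch-128 step.

## Limitations

- The synthetic benchmark has position-specific, independent motif signal;
  it does not model residue-order dependencies, homology structure, or real
  kinase-motif diversity. Results on it are a sanity ceiling, not a claim
  about real phosphoproteomes.
- The closed-form Bayes AUC ignores boundary truncation of windows near
  protein termini, so it is a slight upper bound on what any classifier can
  reach on the generated data.
- Exact-duplicate filtering is no substitute for homology clustering of
  real sequence data.
- Training is single-threaded NumPy; the package targets desk-scale
  experiments, not GPU-scale corpora.
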