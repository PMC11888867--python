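# Methods

## Problem and model

`amylstm` classifies protein sequences as amyloid-forming or not from the
primary sequence alone. Amyloid proteins aggregate into insoluble,
β-sheet-rich fibrils (the Aβ plaques of Alzheimer's disease being the
best-known example); screening candidate sequences computationally is far
cheaper than Congo-red staining or LC-MS/MS assays.

The classifier is an attention-pooled bidirectional LSTM:

1. **Embedding.** Each residue is mapped through a 21-symbol vocabulary
   (20 canonical residues plus one combined pad/unknown symbol at index 0)
   into a 100-dimensional learned embedding. The pad/unknown row is frozen
   at zero so padding carries no signal.
2. **Bi-LSTM encoder.** A bidirectional LSTM with 64 hidden units per
   direction produces a 128-dimensional state per position. The gate
   equations are the standard ones,

       f_t = σ(W_f [h_{t−1}, x_t] + b_f)        (forget)
       i_t = σ(W_i [h_{t−1}, x_t] + b_i)        (input)
       o_t = σ(W_o [h_{t−1}, x_t] + b_o)        (output)
       L_t = tanh(W_c [h_{t−1}, x_t] + b_c)     (candidate cell)
       C_t = f_t ∘ C_{t−1} + i_t ∘ L_t
       h_t = o_t ∘ tanh(C_t),

   implemented both as a scalar single-step reference cell
   (`reference_lstm_step`) and as the vectorized training layer; the two
   are cross-checked in the tests. At padded positions the state is
   carried through unchanged, which makes predictions invariant to the
   amount of padding.
3. **Attention pooling.** Per-position states h_k are scored against a
   learned context vector u_s:

       u_k = tanh(W_k h_k + b_k),
       α_k = softmax_k(u_kᵀ u_s)    (masked to real positions),
       V   = Σ_k α_k h_k.

   The pooled vector V is 1 × 128. For the no-attention ablations the
   concatenated final forward/backward hidden states are used instead.
4. **Head.** FC(128 → 64) → 1-D batch normalization → ReLU → FC(64 → 1) →
   sigmoid, giving a probability of the amyloid class.

RNN (tanh) and GRU cells are drop-in alternatives for the ablation
variants. The whole network, including backpropagation and the Adam
optimizer, is implemented directly in NumPy; gradients of every layer are
verified against central finite differences in the test suite.

## Training protocol

Adam with learning rate 0.001 on mean binary cross-entropy, up to 40
epochs (library default); the weights from the epoch with minimum
validation loss are returned, rather than a hard-coded stopping epoch,
since convergence epoch varies with the data. Batch size defaults to 32
(a package choice for a ~400-sequence training set). Training batches are
formed from length-sorted records, with batch order shuffled each epoch:
this bounds padded computation while keeping the run fully seeded.
Validation loss is computed in evaluation mode (running batch-norm
statistics). Batch normalization is undefined at batch size 1, so
training requires batches of at least 2.

The benchmark split is stratified with exact per-class counts —
train/validation/test of 117/15/33 positives and 276/29/77 negatives
(totals 393/44/110) for a 165/382 input — and `SplitSpec.proportional`
scales those fractions to other dataset sizes. Splits, initialization and
shuffling all derive from explicit integer seeds; identical seeds
reproduce the evaluation report exactly.

## Metrics

AUROC is the primary metric (rank-based Mann–Whitney estimator, midrank
tie handling, via scikit-learn); balanced accuracy, Matthews correlation
and F1 are computed from the confusion matrix at threshold 0.5. MCC is
defined as 0 when any denominator factor vanishes (the standard
convention for degenerate predictions). The multi-trial robustness
protocol repeats split/init/train/evaluate with seeds `base + t` and
reports per-metric mean and standard deviation.

## Descriptors for the classical baselines

Five fixed-length feature sets feed the 25-model classical harness
(k-NN, logistic regression, random forest, RBF-SVM and XGBoost, each on
every descriptor):

- **AAC** (20): relative residue frequencies.
- **DDE** (400): per dipeptide, (Dc − Tm)/√Tv with Dc the observed
  fraction over the N−1 dipeptides, Tm the product of codon fractions
  over the 61 sense codons of the standard genetic code, and
  Tv = Tm(1 − Tm)/(N − 1).
- **CTDC** (39) / **CTDD** (195): 13 physicochemical attributes, each
  splitting the residues into 3 groups (iFeature group tables);
  composition gives per-group fractions, distribution the percent
  positions of the first/25%/50%/75%/100% occurrences (0 for an absent
  group, first occurrence used when a quantile index rounds to zero).
- **APAAC** (20 + 2λ): pseudo-amino-acid composition with sequence-
  correlation factors of standardized Tanford hydrophobicity and
  Hopp–Woods hydrophilicity at lags 1..λ. Defaults λ = 4, weight = 0.05;
  λ = 0 reduces exactly to AAC. λ is kept small so short sequences
  remain admissible (the sequence must be longer than λ).

Unknown residues carry no physicochemical assignment and are excluded
from all counts and normalizers. Baseline hyperparameters are selected on
the validation split by AUROC over small documented grids (k ∈ {3,5,7,9};
C ∈ {0.1,1,10}; trees ∈ {100,500}; boosting depth ∈ {3,6}); SVM scores
use decision-function values, which are monotone in probability and
avoid a calibration refit.

## Synthetic data generator

The generator emulates variable-length protein sequences (uniform lengths
over a configurable range, default 30–200) over a uniform residue
background. Positives optionally carry a planted heptapeptide motif
(default `QNNQQNY`, a polar-zipper-like segment reminiscent of real
amyloidogenic stretches) at a uniform random position in a fraction
`motif_prob` of sequences, and/or a compositional tilt toward hydrophobic
residues (`composition_shift` exponentially reweights A/V/L/I/M/F/W/C).
With `motif_prob = 0` and no shift the classes are exchangeable, so any
classifier's expected held-out AUROC is 0.5 — the null control.

What this does **not** emulate: real amino-acid background frequencies,
homology structure between sequences, length–class correlations, or any
biophysics of aggregation. Passing the planted-signal tests shows the
pipeline can recover a recoverable sequence signal, not that it matches
the published accuracy on curated amyloid data, which depends on that
dataset and its (unpublished) split seeds.

## Problem sizes used in the automated checks

- Planted-signal and null runs: 150 positives / 380 negatives, lengths
  30–200, default architecture, 12 training epochs with
  minimum-validation-loss selection (the planted signal converges well
  inside that horizon; the library default remains 40).
- Motif-strength sweep (`motif_prob` ∈ {0, 0.3, 0.6, 1.0}): a reduced
  configuration of 60/60 sequences, lengths 30–80, 32-unit hidden size,
  8 epochs, averaged over 5 seeds; the check asserts the 5-replicate
  mean AUROC is monotone in motif strength within a 0.02 simulation-
  error allowance.

## Numerical choices and edge cases

- Sigmoid computed in the numerically stable two-branch form; the
  training loss uses the logit formulation `softplus(z) − y·z`.
- Attention masking uses additive −∞-style scores before the softmax, so
  padded positions receive exactly zero weight.
- Float32 is the default parameter dtype (float64 available via
  `ModelConfig.dtype`, used by the gradient-check tests).
- Truncation of very long sequences keeps the N-terminal prefix
  (configurable `max_len`, default 1000).
- Non-canonical residue codes (B, J, O, U, Z, X, `*`) are replaced by the
  unknown token at parse time with a logged substitution count.
- Ties in baseline grid search are broken by declared grid order.

## Known limitations

- Sequence-only: no structural, evolutionary (PSSM) or interaction
  features.
- The NumPy implementation is single-threaded BLAS-bound; it is sized
  for hundreds-to-thousands of sequences, not proteome-scale training.
- The published benchmark's exact split and initialization seeds are
  unknown, so point reproduction of its test-set numbers is out of
  reach by construction; the package instead verifies the architecture,
  the protocol and signal recovery end to end.
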