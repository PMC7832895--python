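# Methods

## Problem and model

Given a protein chain, the task is per-residue binary classification:
does the residue contact ATP? The classifier never sees structure; its
inputs are three sequence-derived tracks per residue, gathered over a
sliding window of `window_size = 17` (8 residues of context on each side;
the value at which windowed predictors of this family perform best, and
configurable — only odd values are accepted). Windows overhanging a chain
terminus are padded with all-zero rows: zero is the identity under the
downstream convolutions and keeps every residue classifiable.

**Profile track.** The L×20 PSI-BLAST log-odds matrix, squashed
elementwise to (0,1) by the logistic function `1/(1+e^{-s})`. Only the
log-odds block of the ASCII matrix is consumed (both the 40-column and
bare 20-column dialects parse); the percentage block is ignored. The
logistic normalization is strictly monotone, so no profile information is
lost, only rescaled.

**Secondary-structure track.** The (C,H,E) confidences of a PSIPRED
`.ss2` file, renormalized row-wise to sum to 1. The default feeds the
three confidences; `ss_onehot` hardens the track to an indicator of the
argmax state. Both have shape L×3; the soft variant is the default
because it preserves the predictor's uncertainty.

**Physicochemical one-hot.** The 20 amino acids partition into 7
dipole/volume classes — {A,G,V}, {I,L,F,P}, {H,N,Q,W}, {Y,M,T,S}, {R,K},
{D,E}, {C}. One published listing of the second class contains "The",
which is not an amino-acid code; it is read here as Phe (Thr already sits
in the fourth class, and the underlying 7-class scheme places Phe there).
Unknown residues (X) encode as an all-zero row and are never dropped, so
label/profile row alignment is preserved.

## Subclassifiers

**Multi-IncepResNet.** The three windows enter as separate single-channel
2-D maps — mixing tracks with different meanings and scales into one
matrix measurably hurts this task, so each stream has its own
convolutional trunk. Profile and one-hot streams: two stacked Inception
blocks (branches 1×1, 1×1→3×3, 1×1→5×5, 3×3-maxpool→1×1, each at
`branch_filters` channels, outputs channel-concatenated), with a shortcut
that projects the stream input through a 1×1 convolution to the block
width and **concatenates** it with the block output (concatenation, not
addition, is the published variant of this design). The low-dimensional
SS stream gets one block. Batch normalization follows every convolution.

**Multi-Xception.** Profile and one-hot streams: an entry pointwise
convolution, then six depthwise-separable convolutions (3×3 depthwise +
1×1 pointwise, batch-normalized) grouped into three identity-residual
units; the SS stream gets two separable layers without residuals.

Both networks flatten their streams, concatenate, and classify through a
dense head (`head_units`, ReLU, dropout 0.4, 2-way softmax). **Flatten
vs global pooling:** global average pooling was evaluated for the
Xception trunk and rejected — with translation-equivariant convolutions
it makes the stream representation nearly position-invariant, discarding
*where* in the window a feature sits; per-residue classification keys on
the window centre, and held-out AUC stalled near 0.63 under pooling
versus ≈0.89 with flattening under identical training.

**Defaults.** `branch_filters = 8`, `head_units = 128`. The canonical
Inception width (32) is reachable through `NetworkSpec` but is slow on
the pure-numpy backend this package ships (no GPU framework is assumed);
8 keeps the default usable on one CPU. Tests and the acceptance script
use narrower stacks (2 filters/branch) — the planted synthetic signal is
recoverable at that width, and architecture behaviour, not capacity, is
what they check.

**Training regime.** Adam at learning rate 1e-4, batch 256, at most 60
epochs, dropout 0.4. Loss is class-weighted cross-entropy with
`W_c = N/(l·n_c)`, `l = 2` — the weights satisfy `Σ_c W_c n_c = N`, so
balanced data gives unit weights and a 25:1 imbalance up-weights binding
residues ≈13×. Early stopping watches the loss on a 10% stratified
validation split (stratified at residue level within the training
portion) with patience 8 and restores the best weights. All randomness —
initialization, shuffling, dropout, splits — flows from one seed;
bit-exact reproducibility is promised within this backend, not across
BLAS builds.

**Gradient-boosted trees.** The flattened 510-vector (profile window,
then SS, then one-hot, row-major) feeds scikit-learn's histogram-based
gradient-boosting classifier — the same histogram-GBDT family as the
dedicated boosting libraries; its sampling/bundling accelerations are
that library's internals and deliberately not reimplemented. Defaults:
31 leaves, learning rate 0.1, up to 500 rounds, early stopping after 50
stagnant rounds on a 10% split. The positive class is up-weighted by
`scale_pos_weight = n_neg/n_pos` (the ratio of the two cross-entropy
class weights), applied as per-sample weights — mathematically identical
for binary log-loss.

## Ensemble

Four combination rules over the three aligned tracks: elementwise max,
min, mean, and the convex weighted sum (which reduces to the mean at
equal weights). The weighted rule is the operating default; its weights
are grid-searched with w₁, w₂ ∈ {0.1,…,0.9}, w₃ = 1−w₁−w₂, keeping only
the 36 points with w₃ ≥ 0.1 so that every subclassifier contributes (a
flag widens to w₃ ≥ 0). The criterion is AUC pooled over the out-of-fold
predictions of five-fold cross-validation; pooling is stabler than
per-fold averaging at small fold sizes. Ties break toward larger w₃,
then larger w₁.

**Chain-level folds.** Residues of one chain share up to 16/17 of their
window content with neighbours; residue-level splitting would leak the
test set into training. Chains are shuffled under the seed and dealt
round-robin into k = 5 folds; no residue is ever predicted by a model
that saw its chain.

**Threshold.** The binary operating point is the probability cut
maximizing MCC, scanned at all midpoints between adjacent sorted unique
probabilities (plus cuts outside the observed range); ties take the
smallest cut. The chosen weights and threshold are persisted in the run
manifest, which suffices to reproduce `predict` byte-for-byte.

## Template transfer

Homologous chains tend to bind ATP at equivalent positions. Each query is
locally aligned against every labeled training chain — Smith–Waterman,
BLOSUM62, gap open 11 / extend 1 — and the raw score converts to bits via
the standard gapped Karlin–Altschul parameters (λ = 0.267, K = 0.041).
Hits at ≥ 50 bits transfer template labels across all matched (non-gap)
alignment columns; multiple qualifying templates contribute their union
(transfer is monotone: more hits never remove a call). The final call is
`(ensemble probability > threshold) OR template`. The template route is
precise but low-coverage, so OR-combination can only add positives. An
optional `psiblast` subprocess backend reproduces database-search bit
scores when the external tool exists; bit scales differ between backends,
the cutoff applies to whichever ran, and the manifest records which.

## Synthetic data

The generator emits the statistical world the pipeline assumes: residues
i.i.d. uniform over the 20 letters; binding positions in contiguous runs
(`motif_width = 5` — windows then have local structure to find) placed
uniformly without overlap to a `binding_fraction` of 1/26, matching the
≈25:1 imbalance of the real training sets; background profiles i.i.d.
integers in [−3, 3]; at binding positions the columns of {G, K, T, S}
are boosted by `round(signal_strength)` (a nod to P-loop composition —
any fixed column subset would do); secondary-structure rows are Dirichlet
draws with coil favored inside binding runs. The coil bias is part of
the planted signal: at `signal_strength = 0` every track is independent
of the labels, so held-out skill on the null world is exactly spurious
skill. Homologs are simulated by point substitution at a given rate with
labels carried over — the premise template transfer relies on.

What the generator does **not** emulate: positional autocorrelation of
real profiles, database-dependent profile sharpness, compositional bias,
or inter-chain homology. A green signal-recovery test therefore
establishes that the pipeline's machinery can find a localized profile
signal under realistic imbalance — not that it reproduces benchmark
accuracy on real proteins, which requires external databases and tools.

## Numerical choices and edge cases

* MCC with a zero denominator factor is defined as 0, keeping
  comparisons total on degenerate predictions.
* ROC ties get half credit, so the trapezoidal AUC equals the normalized
  Mann–Whitney statistic; tests enforce agreement with a pair-counting
  oracle to 1e-12.
* Loss-side probabilities are clipped to [1e-7, 1−1e-7].
* The neural engine runs in float32; convolutions are computed as sums of
  kernel-offset matmuls (maps are ≤ 17×20, so this beats materializing
  im2col patches on CPU).
* Statistical acceptance bands on null-signal AUC apply to the AUC
  averaged over the stated seeds: a single held-out fold has ~10–50
  positive residues, where the null rank statistic has sd ≈ 0.05–0.09.
* Positions are 1-based in every file format and 0-based in memory.

## Known limitations

* No real-data benchmarking without external PSI-BLAST/PSIPRED runs; the
  optional subprocess wrappers are untested stubs by design.
* The numpy backend trains small networks in minutes, not the canonical
  widths in seconds; it is an instrument for correctness and desk-scale
  experiments, not production training.
* Template transfer treats all matched columns equally; no per-column
  conservation weighting.
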