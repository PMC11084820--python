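# Methods

## Problem and model

The package predicts the number of subunits (NS) of a homo-oligomeric
protein — how many identical chains form the functional complex — as a
10-class classification over NS ∈ {1, 2, 3, 4, 5, 6, 7, 8, 10, 12}
(9 and 11 are essentially absent from curated annotations). The input is
a single pooled protein-language-model embedding per sequence.

The classifier is

    H_gru       = f_gru(x)            x ∈ R^(1×1280)
    H_attention = f_attention(H_gru)  H_gru ∈ R^(1×H), H = 2 × gru_hidden
    Y           = f_fc(H_attention)   Y ∈ R^(n_classes), softmax

where f_gru is a bidirectional GRU, f_attention a multi-head self-attention
layer, and f_fc a fully connected softmax layer. The pooled vector enters
the GRU as a **single timestep** of width 1280: pooling happens before the
recurrence. With a single timestep the recurrence is degenerate — both
directions see the same input, the reset gate is inert (it multiplies
U·h₀ = 0) and attention softmaxes over one key — but the architecture is
reproduced faithfully in this form, because that is the architecture being
studied. The forward pass is written for a general timestep axis, so an
alternative mode that feeds the l × 1280 per-residue matrix to the GRU and
pools after attention is available through the same code path
(`forward(EmbeddingMatrix, model)`); it is not the default and not used in
training.

GRU convention: Cho-style update hₜ = (1 − zₜ)·hₜ₋₁ + zₜ·h̃ₜ with h₀ = 0.
Attention: queries/keys/values are square projections of the GRU output,
split into `attention_heads` heads (default 32; head key width
H/heads = 8), scaled dot-product softmax, concatenated and projected. No
residual connection or layer normalisation is added, since the model under
study has none.

## Training

Loss is the multi-class cross-entropy H(p, q) = −Σ p(x) log q(x) with the
predicted distribution clamped at 1e−12 to avoid log 0. The optimizer is
Adam — the learning rate (0.001) is fixed by the protocol; the optimizer
family is a design choice, exposed in config — with defaults: 200 epochs,
batch size 1024, dropout 0.5 (applied after the GRU output and after the
pooled attention output, inverted-dropout style), Glorot-uniform weight
initialisation, zero biases. All randomness (initialisation, shuffling,
dropout masks) derives from one seed, so training is bit-reproducible.
"128 hidden units" is read as per direction, giving a 256-wide
bidirectional output; this reading is configurable.

The whole network, including backpropagation through the bidirectional
recurrence and the attention softmax, is implemented in numpy. The
gradients are verified in the test suite against central finite
differences over every parameter on a 3-timestep batch (the key-projection
bias has an exactly-zero gradient — a constant shift of all keys leaves
each softmax row invariant — which the check accounts for).

Prediction is the argmax of Y mapped through the label map; the map is
kept in ascending NS order so argmax's first-index tie-breaking resolves
ties toward the smaller NS label.

## Curation rules

An entry is discarded if (in this order) it has no subunit description,
the description's evidence includes ECO:0000250 (inferred from sequence
similarity — tested on the subunit comment's evidence attributes only),
or the text contains "By similarity", "Probable" or "Potential". Each
discard carries exactly one reason, so the report obeys the conservation
law parsed = retained + Σ discards.

Labeling uses a two-tier rule table (shipped as YAML, substitutable):
compound "‹homo-n-mer› of" phrases are tested first in priority order and
decide the label immediately; otherwise exactly one distinct base keyword
(monomer, homodimer, …, homododecamer) must occur, else the entry is left
unlabeled. Matching is case-insensitive on whole words, tolerates a plural
"s", and folds hyphenated spellings ("homo-dodecamer"). Ambiguous
multi-keyword descriptions are excluded rather than resolved, trading
recall for label precision. Fragment entries are retained by default; a
`drop_fragments` switch (reason "fragment") is available. The streaming
parser bounds memory by clearing each processed `<entry>` element and is
checked field-for-field against an independent whole-document parse.

## Evaluation conventions

Metrics are one-vs-rest macro averages:

    mACC = (1/N) Σᵢ (TPᵢ + TNᵢ)/total        mPrecision = (1/N) Σᵢ TPᵢ/(TPᵢ + FPᵢ)
    mRecall = (1/N) Σᵢ TPᵢ/(TPᵢ + FNᵢ)       mF1 = 2·mP·mR/(mP + mR)

Zero-denominator per-class terms contribute 0 and **stay in the average**:
a rare class the model never gets right must drag the macro score down
rather than drop out. A side effect worth knowing: a class entirely absent
from a small test set also contributes 0, which lowers macro
precision/recall even under perfect prediction (visible in the examples);
stratified folds avoid it. Because the two mF1 conventions (harmonic
combination of the macro means vs. macro mean of per-class F1) disagree
whenever per-class precision/recall are imbalanced, both are computed; the
harmonic form is primary. A useful exact identity links mACC to plain
accuracy: mACC = 1 − 2(1 − accuracy)/N; it is tested in rational
arithmetic.

Cross-validation folds are random by default (stratified on request);
summary dispersion is the sample standard deviation (ddof = 1). The 8:2
split is a seeded permutation with sizes within one sample of the ratio.

## Pairwise identity

Needleman–Wunsch global alignment with BLOSUM62, gap open 10 / extend 0.5
(biopython's `PairwiseAligner`); identity = matches / alignment length,
gap columns included. These parameters are a documented choice exposed in
the API, not a canonical definition; the alternative shorter-sequence
denominator is not used. Same-EC pairs are enumerated and, beyond
`max_pairs`, subsampled with a seed. The aligner is validated against
exhaustive enumeration of all affine-gap global alignments on sequences of
length ≤ 6 — co-optimal alignments can differ in identity, so the check is
that the returned identity is attained by some optimal alignment.

## Synthetic data

The fixtures module generates (a) toy UniProt-dialect XML (subunit
comments, key-referenced ECO evidence, EC numbers, organisms, fragment
flags) that round-trips losslessly through the parser, and (b)
class-conditional embeddings: ten centers with standard-normal coordinates
(expected pairwise separation ≈ √(2·width)) and points drawn as
center + N(0, noise_sd²). Defaults — 20 points per class, width 64,
noise_sd 0.05 — put the noise two orders of magnitude below the
separation, so a nearest-centroid oracle classifies perfectly and any
failure of the trained network to do likewise indicates a defect in the
model code, not in the data. Synthetic sequences are uniform random
20-letter strings; their class is a stable hash of the sequence, and the
synthetic encoder adds the corresponding center to every residue vector,
so pooled embeddings inherit the cluster structure. The reduced width (64
rather than 1280) keeps the suite fast; the 1280-wide shape contract is
exercised once.

What these fixtures do **not** emulate: real embedding geometry (ESM2
clusters are neither Gaussian nor equally separated), class imbalance
(real NS data are dominated by monomers/homodimers with a handful of
heptamers), and any biological relationship between sequence and
stoichiometry. Passing parameter-recovery tests therefore demonstrates
that the training machinery optimises and generalises on separable data —
not that the model reaches any particular accuracy on real proteins.

## Problem sizes and numerical choices

The test suite and the acceptance script run at reduced scale: width-64
embeddings, 200 samples, 10-fold CV (≈ 10 s total for the training parts).
The published-table arithmetic checks use the printed per-fold values as
inputs; only the folds whose printed mF1 equals the harmonic combination
of the printed precision/recall at 3 d.p. (folds 1, 4, 6, 7, 8) are
asserted, since the remaining rows appear to mix mF1 conventions.
Degenerate inputs are rejected loudly: single-class training sets,
width mismatches, dropout outside [0, 1), duplicate rule priorities,
unknown labels. Non-finite training loss aborts with diagnostics.
Checkpoints are single-file npz archives (weights + config + label map +
schema version) and reload to bit-identical predictions.

## Known limitations

* The default keyword table is a reconstruction from the stated label set
  and the one documented worked example; the original appendix mapping may
  differ in edge cases. It is a config file precisely so users can swap
  in an exact table.
* The ESM2 encoder is an optional backend contract; without the external
  weights package the synthetic backend is the only encoder, and reported
  accuracies on synthetic data say nothing about real-protein accuracy.
* No class re-weighting or oversampling is applied, mirroring the
  protocol under study; heavily imbalanced real datasets will show the
  same rare-class failures it reports.
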