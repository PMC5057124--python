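# Methods

## The prediction task

A candidate A-to-I editing site is represented by a fixed-length RNA window
centered on the candidate adenosine: 51 nt by default, so the editable A
sits at 1-based position 26. Windows are classified as editing /
non-editing by an RBF-kernel SVM over a pseudo dinucleotide composition
(PseDNC) encoding. All public coordinates are 1-based and inclusive; DNA
input is accepted and converted T→U; ambiguity codes are rejected rather
than resolved, because the encoder's property lookup is undefined for them.
Input is assumed to be the sense/transcript strand.

## Encoding

For a window of length L, the encoder produces 16 + λ components: the 16
dinucleotide frequencies and λ tier correlation factors θ_j, the mean
structural dissimilarity Θ of all dinucleotide pairs j positions apart.
Θ(T, T′) is the mean squared difference of six dinucleotide step
parameters — Shift, Slide, Rise (translational, nm) and Tilt, Roll, Twist
(angular, degrees) — after each property column is z-scored over the 16
dinucleotides. The combined vector is normalized by Σf + wΣθ, so it is
non-negative and sums to one; w weighs the order-dependent pseudo
components against the composition block.

Parameters that matter:

- **w ∈ [0, 1]** (default 0.3): weight of the pseudo components. At w = 0
  the vector reduces to the plain dinucleotide composition.
- **λ ≥ 1** (default 4): number of correlation tiers; the feature dimension
  is 16 + λ. λ may not exceed L − 2, so every tier averages at least one
  pair. Large λ adds increasingly long-range (and noisier) terms.
- **counting_mode**: `overlapping` (default) counts all L−1 adjacent
  dinucleotides; `non_overlapping` counts the ⌊L/2⌋ disjoint pairs. The
  overlapping convention matches the dinucleotides the correlation factors
  themselves run over and is the convention of canonical PseDNC tooling;
  the non-overlapping reading is retained as an option because the verbal
  definition of the composition term admits it. Both are implemented and
  tested; the default is a documented choice, not a claim about intent.

Numerical choices: the z-score uses the population SD (divide by 16) —
the 16 dinucleotides are the entire population, and this matches reference
PseDNC implementations; a `ddof=1` switch exists for sensitivity analysis.
A constant property column is an error. All arithmetic is double
precision; the encoder is checked against an independent nested-loop
reference to 1e-12 per component, and vector normalization to 1e-9.

The built-in six-property table ships with the package; the printed source
values include one asymmetric pair (CC vs GG differ in Roll, 8.70 vs
12.10) which is preserved verbatim rather than symmetrized. User tables
are accepted as delimited text (header row of property names, one row per
dinucleotide, all 16 required).

## Classifier and training protocol

The SVM uses the RBF kernel through scikit-learn's libsvm-backed solver;
the package owns the protocol, not the QP optimizer. Features are not
rescaled before training — PseDNC components already live in [0, 1] and
sum to 1. No class weighting is applied (benchmark-shaped datasets are
nearly balanced, 125 vs 119). (C, γ) are chosen by exhaustive grid search
over the standard libsvm coarse grid (C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, steps of
2²) by stratified k-fold CV accuracy with a seeded fold assignment; ties
break toward smaller C, then smaller γ, making the search invariant to
grid ordering and duplication. The packaged default (C = 8, γ = 8) is the
grid-search optimum on the default synthetic benchmark; real datasets
should re-run `--grid`.

Trained models are serialized as a single versioned container that bundles
the SVM state, (C, γ), the encoding configuration and a fingerprint of the
property table; prediction refuses mismatched feature dimensions and warns
on a mismatched table fingerprint.

## Evaluation

Sn, Sp, Acc (percent, two decimals) and MCC (two decimals) are computed
from confusion counts pooled across CV folds — never from averaged
per-fold metrics, which are ill-defined for the jackknife where each fold
holds one sample. Jackknife (leave-one-out) is implemented as k-fold CV
with k = n and an identity fold assignment, so the equivalence of the two
protocols at k = n is exact by construction and asserted in tests. When a
class is absent, its rate is reported as NaN with a warning; MCC is 0 by
convention when any confusion marginal is zero. Hyperparameters are
selected once on the full training set and held fixed across jackknife
rounds; this mirrors the usual protocol (parameter optimization by 5-fold
CV preceding the jackknife) and carries a known optimistic bias, since the
held-out sample participated in hyperparameter selection.

The (w, λ) sweep evaluates k-fold accuracy over w ∈ [0, 1] step 0.1 and
λ ∈ [1, 10] step 1 (110 cells) by default; the reported optimum breaks
ties toward smaller λ, then smaller w (a package convention — a unique
peak needs no tie-break).

## Synthetic benchmark generator

The original benchmark windows are not retrievable, so the generator
emulates their *shape*: two classes of 51-nt windows with a central A,
defaulting to 125 positives and 119 negatives. Each window is drawn from a
first-order Markov chain over {A, C, G, U}; class-specific bias maps
multiply transition weights into favored dinucleotides (positives: CG/GC
×4; negatives: AU/UA ×4), and `separation` ∈ [0, 1] interpolates the
multipliers geometrically (m^separation), so separation 0 makes the
classes exchangeable uniform chains and separation 1 applies full
contrast. A first-order chain (rather than i.i.d. bases) is used precisely
because dinucleotide composition is what the encoder measures, making
signal-recovery tests meaningful. The central A is overwritten after
generation; the slight composition distortion this causes is accepted.

What the generator does **not** emulate: real ADAR neighbor preferences,
editing motifs, secondary-structure context, or the redundancy structure
of curated benchmarks. Passing recovery tests therefore demonstrates that
the pipeline can extract a dinucleotide-composition signal at benchmark
sample sizes — not that it attains any particular accuracy on real
editing data.

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline at the benchmark
shape (244 windows, 5-fold CV, 110-cell grid search, 244-round jackknife),
which completes in seconds; encoder cross-checks use 100 random windows of
lengths 10–80 and 1000 windows across 20 (w, λ) settings. Every stochastic
step (fold assignment, synthetic generation) is driven by an explicit
seed; the jackknife is seed-free. At zero separation the expected CV
accuracy is 50% with binomial SD ≈ 3.2 points at n = 244; checks allow a
±10-point (≈3 SD) band.

## Known limitations

- Trained on composition features only; no secondary structure, no
  conservation, no read-level evidence.
- The jackknife protocol's fixed hyperparameters are optimistically
  biased; per-round re-search is available (`--nested`-style usage via the
  library) but not the default.
- Windows shorter than λ + 2 cannot be encoded; no padding is applied at
  the library level.
- The species scope of any trained model is that of its training data;
  the package itself is organism-agnostic.
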