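# Methods

## Problem and model

`enacp` identifies anticancer peptides (ACPs): given a short amino-acid
sequence (typically 5–50 residues over the 20 natural letters), predict
whether it has selective anticancer activity. The classifier is a
two-stage stack:

1. **Encoder bank.** Each peptide is encoded 19 ways, drawn from four
   families — amino-acid composition (k-mer, distance-based residue
   pairs, distance pairs over a reduced alphabet), physicochemical
   autocorrelation (auto/cross/auto-cross covariance, physicochemical
   distance transformation), pseudo amino acid composition (parallel- and
   series-correlation PseAAC plus their General variants), and eight
   profile-based encoders over per-peptide PSSMs (Top-n-gram, DT,
   PDT-Profile, AC/CC/ACC over profile columns, PSSM-DT, PSSM-RT).
2. **Stage 1.** One gradient-boosted-tree classifier (LightGBM,
   library-default parameters) is trained per encoding; its
   positive-class probability becomes one coordinate of a k-dimensional
   meta-feature vector (k = 19, or 11 when profiles are unavailable).
3. **Stage 2.** An RBF-kernel SVM on the meta-features, with C and gamma
   chosen by exhaustive grid search (C ∈ 2^-5..2^15, gamma ∈ 2^-15..2^3,
   step 2^2) under internal stratified 5-fold accuracy. A peptide is
   called ACP when the stage-2 positive score reaches 0.5.

Profiles are optional inputs; the package never runs PSI-BLAST. Without
them the bank drops to the 11 sequence encoders with a logged warning.

## Encoder conventions

* Alphabet order is fixed: `ACDEFGHIKLMNPQRSTVWY`; words, residue pairs,
  and profile columns are always enumerated lexicographically in this
  order. Formulas are written 1-based (R1..RL); storage is 0-based.
* Every physicochemical index is standardized to zero mean and unit
  *population* spread (divide by 20) over the letters before use — the
  convention the PseAAC construction assumes — so scales of different
  magnitude contribute comparably. Auto/cross covariance additionally
  centers per sequence, which makes it invariant to constant shifts of
  the raw index.
* Defaults: k-mer k = 2; DR and Distance-Pair dmax = 3 (Distance-Pair
  over the bundled 14-cluster alphabet); autocorrelation and all profile
  encoders dmax = 2; Top-n-gram/DT n = 1; PseAAC λ = 4, w = 0.05 with the
  canonical hydrophobicity/hydrophilicity/side-chain-mass panel (the
  General variants use the full 8-index panel). These favor the short
  peptides of this problem: λ = 4 and dmax = 2 are the largest orders
  valid for every L ≥ 5 sequence. A sequence too short for an encoder's
  order raises with its id rather than silently lowering the order,
  which would desynchronize feature dimensions across a dataset.
* PSSM scores are mapped to a frequency profile by the bounded logistic
  transform f'(i,j) = 1/(1+2^(-score)) followed by row renormalization;
  explicit row-stochastic profiles are also accepted. The PSSM-RT
  ("relation transformation") family is only loosely specified in the
  literature; this package's explicit rule — binarize scores at a
  threshold (default 0) and count co-occurrences of above-threshold
  ordered residue pairs at each distance, normalized by L−d — is its
  documented stand-in and is exercised by the same reduction tests as
  the other profile encoders.

## Stage-1 scoring modes

The stacked construction trains stage 1 on the training split and scores
that same split to build stage-2 inputs (`in_sample`, the default).
Because boosted trees overfit their training rows, those meta-features
are nearly binary and optimistic; stage 2 still generalizes because test
rows are scored by the same fitted stage-1 models, but internal CV
accuracies reported during stage-2 grid search are inflated. The
`out_of_fold` mode instead scores each training row from an internal
stratified 5-fold model that never saw it (then refits on all rows for
deployment); it is the honest choice when the meta-features themselves
are analyzed. On the synthetic benchmark both modes reach similar
held-out performance.

## Stage-2 scores

The SVM's positive score is the logistic-squashed signed margin,
1/(1+exp(−decision_function)), not a Platt-calibrated probability:
Platt's internal calibration is unstable (and can even invert) on the
near-separable meta-features the in-sample mode produces, whereas the
squashed margin is monotone in the decision value, lies in [0, 1], and
places the 0.5 threshold exactly on the SVM's decision boundary, so
scores and hard calls can never disagree. Alternate second-layer
learners (AdaBoost, decision tree, logistic regression, naive Bayes,
random forest) are available for ablation and use their native
probabilities.

## Evaluation protocols

Sn, Sp, Acc, and MCC follow the standard confusion-matrix formulas; a
zero marginal reports MCC = 0 with an `mcc_undefined` flag. AUC uses the
Mann–Whitney rank identity with half-credit ties. Repeated stratified
k-fold cross-validation redraws folds each repeat from a derived seed,
pools confusion counts over folds within a repeat (micro aggregation —
stable at k = 5; macro averaging can be computed from the per-repeat
sets), computes AUC on the concatenated held-out scores, and reports
mean ± population sd per metric. The DeLong test estimates the
covariance of two paired empirical AUCs from midrank placement values
and refers the difference to a standard normal; a degenerate variance
(e.g. identical score vectors) is flagged and reported as p = 1.
Better/equal/worse "comparison triplets" across datasets count, per
ordered method pair, where the AUC difference is significant at the
given level.

## Synthetic benchmark

The generator emulates the *structure* of ACP benchmarks, not their
biology: two classes of peptides with lengths uniform on [5, 50],
negatives i.i.d. from a background distribution (uniform by default,
which makes null-calibration tests exact). The composition channel draws
positives from (1−δ)·background + δ·target with the target a point mass
on lysine, mimicking the polycationic enrichment that is the single most
characteristic compositional signal of natural ACPs. The target was
fixed by a design-time power analysis: enumerating the exact
Bayes-optimal AUC of the length mixture shows a diffuse six-residue
target caps at 0.92 and a two-residue target at 0.987, while the lysine
point mass reaches 0.994 — the level at which a well-fit pipeline can be
expected to hold ≥ 0.98 held-out AUC at δ = 0.3, the regime the
benchmark is meant to probe. An order channel plants a two-period
cationic/hydrophobic alternation in positives while negatives receive
the same letters shuffled (composition-matched); a profile channel makes
positive profiles sharper. Synthetic PSSMs draw each row from a
Dirichlet concentrated on the true residue and invert the
score→frequency transform so file round-trips are exact.

What passing these tests shows — and does not. The benchmark verifies
that the pipeline recovers a planted, purely compositional signal, stays
at chance under permuted labels, and is seed-deterministic and stable
under fold redraws. It does not establish performance on real ACP
collections, which differ in residue composition, length distribution,
homology structure, and the provenance of negatives.

## Problem sizes and numerical choices

The planted-signal benchmark runs at 200 positives / 200 negatives with
a fixed seed; a 200/200 draw carries sampling noise of roughly ±0.01 in
held-out AUC across generator seeds. The 30× repeated 5-fold stability
protocol runs at 100/100, a size chosen so the full protocol stays
desk-scale while leaving fold-redraw variance clearly measurable. The
DeLong calibration study uses 2,000 paired simulations at 100 per class.
Encoding is deterministic per peptide, so feature matrices are computed
once and reused across folds and repeats. All randomness (generator,
fold draws, learner seeds) derives from user-supplied integer seeds;
derived seeds stay below 2^31.

## Known limitations

* The published two-stage design leaves several details open (whether
  stage-1 outputs were probabilities or hard labels, in-sample or
  cross-validated; the exact encoder orders and index panels). This
  package fixes each choice explicitly, as documented above, and makes
  them configurable.
* Reduced alphabets and the physicochemical index panel are bundled
  defaults from the classical literature; swapping them changes
  Distance-Pair and autocorrelation features.
* MCC at extreme class imbalance, peptides shorter than 5 residues, and
  protein-scale profiles (L > 10^4) are outside the supported regime.
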