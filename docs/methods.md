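# Methods

## Problem and model

The package classifies DNA-binding proteins into single-stranded binders
(SSB, positive) and double-stranded binders (DSB, negative) from sequence
information. The model is a three-stage pipeline: (1) encode each protein as
a fixed 1510-column vector from seven feature blocks; (2) filter columns by
mutual-information relevance (mRMR); (3) fit a gradient-boosted tree
ensemble, assessed by stratified 10-fold cross-validation.

The classifier assumes nothing about the biology; all domain knowledge lives
in the encoders. Profile-derived blocks (PSSM, NetSurfP, DisEMBL) assume an
external predictor has produced a per-residue matrix for every protein —
these files are parsed, never generated, and a protein missing any enabled
input is excluded dataset-wide (a partially filled row is meaningless to a
tree ensemble), with the exclusion and its reason recorded in a manifest.

## Feature encoders

**Composition (OAAC).** 20 values in the fixed order `ACDEFGHIKLMNPQRSTVWY`.
The default is √(nᵢ/L) rather than nᵢ/L: the square root inflates small
frequencies, which behaves better for tree splits on sparse compositions;
plain frequencies remain available. Ambiguity codes B/Z/U are normalised to
X on ingest, and X positions are excluded from both the counts and L.

**Gapped dipeptides.** For gaps g ∈ {0, 1, 2} and every ordered pair (a, b),
p_ab[g] = D_ab[g]/(N−1), counting positions j with s_j = a and s_{j+g+1} = b.
The denominator is N−1 for *every* gap, although only N−1−g pairs exist at
gap g; the convention is kept deliberately, so the gap-g block sums to
(N−1−g)/(N−1), an invariant the tests assert. 400 × 3 = 1200 columns,
gap-major then first-residue-major order.

**Physicochemical profile.** A residue-to-scales table (28 properties by
default) unrolled along the sequence into a 28×L matrix. Scale 1 is the
Kyte–Doolittle hydropathy index; the remaining 27 are deterministic
*synthetic stand-in* scales (standardised per scale), because the exact
published selection of AAindex entries is not redistributed here. Any
AAindex subset can be supplied as a TSV; the pipeline only requires all 20
standard residues per scale. X imputes the per-scale table mean.

**Local structural entropy (LSE).** A 4-mer-to-value table turned into a 1×L
profile: each position receives the mean of the values of the 1–4 windows
covering it (window averaging is our documented choice; assigning values to
window starts is the plausible alternative, and the two differ only at the
three termini positions of each window run). The shipped table is a
synthetic stand-in — per-residue propensity sums over the 4-mer, enumerated
for all 160 000 4-mers — and is replaceable via TSV.

**ACC transform.** Lags run 1..LG with LG = 5 (lag 0 would duplicate the
variance); row means are taken over all L positions. AC contributes P·LG
values per profile, CC (off by default) P·(P−1)·LG more. AC-only with LG = 5
is the configuration that makes the seven blocks total 1510 columns
(20 + 1200 + 100 + 140 + 15 + 30 + 5). Proteins with L ≤ LG are rejected
with a named error rather than zero-padded: padding would fabricate
covariance mass. A single-property profile with CC requested degrades to
AC-only with a logged note.

## Feature selection

Continuous columns are discretised into three states at mean ± one
population σ, the convention of the classical mRMR implementation. The
boundaries are *inclusive*: a balanced two-valued column has its two values
exactly at mean ± σ, and strict inequalities would collapse it to one state
and destroy its information; σ = 0 maps to the single middle state. Mutual
information is the plug-in estimate in bits.

Ranking uses greedy forward selection under the difference (MID) criterion —
relevance minus mean redundancy with the selected set — with exact ties
resolved to the lower column index for reproducibility. The *final subset*,
however, is defined by relevance alone exceeding a threshold (default 0.005
bits), keeping original column order; the ranked list is a diagnostic. The
retained-column list is persisted as plain text and re-applied verbatim to
independent data — no selection ever happens on evaluation data.

## Classifier and evaluation

`sklearn.ensemble.GradientBoostingClassifier` with defaults of 200 trees,
learning rate 0.1, depth 3, full subsampling; the optional grid search scans
{100, 200, 500} × {0.05, 0.1} × depth {3, 5} by cross-validated AUC (ties:
accuracy, then grid order). These defaults are documented choices, not
reproductions of any published setting. All randomness — fold shuffling and
model fitting — derives from one recorded seed.

Headline metrics are computed on out-of-fold predictions *pooled* across the
stratified folds, which makes the confusion counts well-defined (they sum to
the sample count); per-fold reports are retained. SN, SP, F1, Accuracy and
MCC follow the standard confusion-matrix formulas with SSB positive; AUC is
the rank statistic (ties ½), hence invariant to monotone score transforms.
A metric whose denominator vanishes is reported as NaN, never silently 0.
The label threshold is 0.5 on the positive-class probability.

## Synthetic data

The generator emulates the statistical shape of the real inputs, not their
biology. Sequences are i.i.d. draws from class-specific residue
distributions: a designated subset (K, R, N, Q) gains `effect/2` total
probability mass in the positive class and loses the same in the negative
class. Defaults — 100+100 proteins of 50–150 residues, effect 0.3 — are the
study conditions used by the tests and the acceptance script.

Profiles are standard-normal P×L matrices with a planted offset of
±`profile_effect` on half the positions of designated rows, shifting the row
mean by ±`profile_effect`/2 per class. Because lagged covariances are
translation-invariant, a uniform mean shift would be invisible to the ACC
features; the offset therefore carries class-dependent *spatial structure* —
a contiguous segment in positives (which inflates small-lag autocovariance)
versus uniformly scattered positions in negatives (which does not). PSSM-
dialect profiles are integer-rounded so the ASCII round-trip is exact.

What passing these tests shows: the pipeline's mechanics — parsing,
encoding, covariance arithmetic, information-theoretic ranking, fold
hygiene, determinism — recover a known planted signal and stay at chance
under permuted labels. What it does not show: performance on real
evolutionary profiles, disorder predictions or curated strand-preference
datasets, whose feature dependence structure is far richer than independent
noise plus shifts.

## Numerical choices and degenerate inputs

- Covariances are computed from centred dot products in float64; agreement
  with direct summation is asserted to 1e−10 relative error.
- MI uses exact joint counts; no smoothing. Empty feature matrices, single
  class labels, constant columns, and thresholds above the maximum relevance
  are all defined behaviours (error, error, single-state, empty-with-warning
  respectively).
- Sequences shorter than an enabled extractor's minimum (4 for LSE,
  max gap + 2 for dipeptides, LG + 1 for ACC) are excluded with named
  reasons.
- Problem sizes throughout testing and the acceptance script (10–100
  proteins per class, ≤ 31-position oracle profiles, 10-fold CV on 200
  samples) were chosen so the planted effects are comfortably detectable at
  desk scale.

## Known limitations

- The shipped physicochemical and LSE tables are synthetic stand-ins;
  results on real data require supplying published tables.
- MI discretisation at mean ± σ is coarse for heavy-tailed features.
- The relevance threshold ignores redundancy among the retained columns; the
  mRMR ranking is provided but not used to cut the final subset.
- Grid search optimises AUC only; no nested cross-validation, so the CV
  estimate after grid search is mildly optimistic.
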