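# Methods

## Scope and model

The package operationalises a composite-biomarker workflow for two-group
compositional microbiome data: clean a taxon count table, learn a sparse
weighted signature with a Random Forest, collapse it into one signed score
per sample, and quantify discrimination with fixed-split statistics plus a
resampling battery.  Genus- and species-level tables are processed
independently end-to-end; the package never merges the two indices.

The score assumes only that the selected taxa's relative abundances carry
additive, monotone information about group membership.  It is not a
calibrated probability and no prevalence projection is attempted.

## Preprocessing

Filters operate on raw counts, in a fixed order, with total-sum scaling
last: (1) contaminant removal by case-insensitive name match against a
blacklist (default: *Propionibacterium acnes*, *Sphingomonas* sp. Oral
clone AV069, *Ralstonia* — taxa typically flagged by negative sequencing
controls); (2) low-count filter: a taxon is kept iff at least
⌈prevalence · n⌉ samples have ≥ `min_count` reads (defaults 20 reads, 10 %
— "at least 10 % of samples" is read as the smallest integer satisfying
the fraction); (3) low-spread filter: per-taxon interquartile range of
counts (linear-interpolation quantiles), removing taxa strictly below the
10th percentile of the IQR distribution, ties kept; a variance-based
statistic is available by flag.  Relative abundances are stored as
fractions in [0, 1]; percent formatting is display-only.  Scoring rejects
RA values above 1 rather than silently rescaling, because percent-scale
input is the most likely user error.

Two caveats are deliberate: the low-spread filter's cutoff is relative to
the current table, so it is *not* idempotent (re-application can remove
more taxa) — the absolute filters are; and rarefaction is intentionally
absent, preserving counts for low-abundance biomarker candidates.  Input
is plain TSV (counts, metadata, blacklist); BIOM containers are not read.

## Importance, selection, weighting

The forest (scikit-learn, `ntree=1500`, `mtry=⌊√p⌋`, single seed) is
trained on RA fractions.  Importance is the classic out-of-bag permutation
MDA computed per tree: for each tree, the drop in accuracy on its
out-of-bag samples when one feature column is permuted; the per-tree drops
are averaged and divided by their standard error across trees (population
SD / √ntree).  The scaled form is the default because the selection
threshold (MDA > 5, strict) is calibrated to it; the raw mean decrease is
reported alongside.  Out-of-bag bootstrap membership is reconstructed by
replaying scikit-learn's bootstrap draw; a test asserts bit-identical
agreement with the library's own OOB probability estimates.  An optional
stability check warns when the OOB error at ntree/2 differs from the full
forest by more than 0.02.

Selected MDAs are normalised per taxonomic level (weight = MDA / ΣMDA);
each taxon joins the case or control set by the larger group-mean RA.
Exact ties carry no directional signal: the taxon is dropped with a
warning and the remaining weights renormalised, keeping the signature's
sum-to-one invariant.  No class rebalancing is applied (the target cohorts
are near-balanced, 27 vs 24).

## Scoring

WCI = Σ case RA·w − Σ control RA·w.  Consequences used by the tests:
linearity (mean of scores = score of mean RA vector, to 1e-12), bounds
(−Σw_ctrl ≤ WCI ≤ Σw_case), and the exact ε·(w_case + w_ctrl) response to
transferring ε of mass between an assigned pair.  A signature taxon
missing from a scored table counts as RA 0 with a warning; `strict=True`
turns this into an error for schema-drift detection.

## Evaluation statistics

* Mann-Whitney: exact null when both groups ≤ 8 without ties, otherwise
  the tie-corrected normal approximation (SciPy).
* AUC: pair-counting form (wins + ½ ties)/(n₁n₂), identical to the
  trapezoidal ROC area and U/(n₁n₂); verified against brute-force pair
  enumeration and scikit-learn.
* AUC CI: DeLong placement-variance normal interval, clipped to [0, 1]
  (the CI method for proportions elsewhere is Wilson; no single published
  convention exists for the ROC CI, so the standard nonparametric choice
  was made).
* Youden cutoff: scanned over midpoints between consecutive sorted unique
  scores plus one candidate beyond each extreme (midpoints avoid the ≥/>
  asymmetry); ties in J break toward higher specificity by default, with a
  flag to prefer sensitivity.
* Sensitivity/specificity CIs: Wilson score intervals; the boundary cases
  k=0 and k=n are exactly 0 and 1.  The spreadsheet-style "Wilson/Brown"
  hybrid's edge-case modification is not implemented; near boundaries the
  last digits may differ from software using it.
* Age adjustment: maximum-likelihood logistic regression of group on
  (WCI, age) with Wald p-values (statsmodels); under perfect or
  quasi-separation the fit is flagged and refit with a small L2 ridge,
  reporting NaN p-values rather than misleading penalised Wald statistics.
* Per-taxon ROC: each signature taxon scored by its own RA, sign-flipped
  for control-assigned taxa so AUC > 0.5 always means "discriminates in
  the assigned direction".

## Cross-validation and permutation null

Repeated stratified k-fold CV (defaults k=5, 10 repetitions, seeded).  In
the default **fixed** mode the signature is frozen (matching a workflow
whose feature selection was performed once on the full data) and only the
Youden threshold is re-learned on each training fold; the repetition AUC
is computed on pooled out-of-fold scores and sensitivity/specificity from
pooled out-of-fold calls.  With a frozen signature the out-of-fold score
of a sample equals its full-data score — asserted exactly in the tests —
so fixed-mode AUC is constant across repetitions while the operating point
varies.  Fixed-mode CV is optimistically biased by construction; the
**nested** mode re-runs the entire discovery step inside every training
fold (with a leakage guard fingerprinting training indices) and should be
preferred when an honest generalisation estimate is needed.  Folds are
stratified because with ~25 samples per class unstratified folds risk
one-class test sets.  Confidence intervals over repetitions use the
t-distribution with repeats−1 degrees of freedom.

The permutation test shuffles labels (class sizes preserved), runs one
fixed-mode stratified 5-fold CV per shuffle, and reports the raw
proportion of null AUCs ≥ the observed mean CV AUC (a +1/(N+1) smoothed
variant is available).  Because fixed-mode pooled out-of-fold scores equal
full-data scores, each null draw reduces to the full-data AUC under the
permuted labels, which is what the implementation computes (the
equivalence is itself under test).  One CV per permutation (not 10
repeats) keeps the null exchangeable with the observed statistic at 10×
less cost.

## Synthetic cohorts

The generator draws, per sample, a composition from a Dirichlet with
concentration = (group mean composition) × θ, then counts from a
multinomial at a library size uniform in 20,000–100,000 reads (a typical
16S amplicon scale).  Group mean compositions come from the reference
signature table (the `table1` preset: 7 genus / 10 species taxa at their
published group-mean RAs, 27 case vs 24 control samples), with background
taxa sharing the residual mass through one fixed symmetric-Dirichlet
partition common to both groups — so background taxa are near-null,
differing only through the residual-mass ratio — and padding the table to
the reference dimensionality (33 genera / 85 species).  Published means of
0.00 % are floored at 10⁻⁵ before building concentrations (Dirichlet
parameters must be positive).  θ defaults to 200; recovery experiments use
θ = 1000 ("near-noiseless") so that planted effects are unambiguous.  A
`null` preset copies the control composition into both groups for
calibration checks, and `spike_contaminants` adds taxa at a fixed small RA
to exercise the blacklist stage.

What the generator does *not* emulate: real per-sample depth and
dispersion structure (no public per-sample depths to fit), taxon-taxon
correlations beyond compositional closure, batch effects, or taxonomy
mis-assignment.  Passing tests therefore demonstrate correctness of the
pipeline's logic and calibration of its statistics under a well-specified
compositional model — not clinical performance: at the default θ the
synthetic groups are far more separable (OOB error ≈ 0, AUC ≈ 1) than real
cohorts.

## Problem sizes and numerics

Test-suite experiments use 20-seed batches for recovery properties
(ntree = 500 forests on 51 × ~30 tables), 50 no-effect cohorts with
100-iteration permutation tests for null calibration, and
200-sample-per-group cohorts for law-of-large-numbers checks on the
generator.  JSON artifacts serialise floats rounded to 10 decimals so
identical configs produce byte-identical outputs.  All randomness flows
from explicit integer seeds (forest seed, generator seed, fold seeds
derived as seed + 7919·repetition, all reduced mod 2³¹).
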