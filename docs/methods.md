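# Methods

This note documents the statistical procedures implemented in `bariomics`,
the choices made where the design was genuinely open, and what the
synthetic cohort generator does and does not emulate.

## Normalization chain

The raw input is a samples × features table of nonnegative abundances
(relative frequencies or counts, used as given) with a Greengenes-style
lineage per feature. The chain is fixed in this order:

1. **Genus collapse.** All features sharing a lineage prefix at the chosen
   rank (default genus) are averaged — the arithmetic mean, not the sum, so
   a genus split into many sequence variants is not inflated. Features
   unassigned at the rank are grouped under their deepest assigned prefix.
2. **Contaminant filter.** Case-sensitive substring match of the full
   lineage against `{Thermi, S24-7, Chloroplast}` (configurable).
3. **Prevalence filter.** A taxon is kept iff it is strictly positive in at
   least 5 samples. Running this *after* collapsing matters: prevalence is
   a property of the genus, not of any one sequence variant, and the order
   is covered by a dedicated test.
4. **Log transform.** `v → log10(v + 0.1)`. The pseudocount 0.1 guards the
   zeros; it is applied to values as given (not rescaled to the input's
   units — callers feeding percentages vs fractions should be aware the
   effective compression differs).
5. **Whitening.** Per-feature z-score with the population SD (divisor *n*;
   pinned so tests are exact). Zero-variance features map to all-zero
   columns rather than erroring: a constant taxon carries no information
   and the decomposition simply ignores it. A second centering pass removes
   the cancellation error that `(v − μ)/σ` leaves when σ is many orders of
   magnitude below |μ|, keeping the stage invariant (|mean| < 1e-9) exact.

Per-feature (not per-sample) whitening is the default because it is the
conventional standardization before PCA — each taxon enters with unit
variance; the per-sample axis is available via `zscore_axis="sample"` for
users who want the alternative reading.

## Decomposition and screening

PCA is fitted once, by full SVD, on the z-scored table over **all**
samples — every obese time point together with the lean controls — giving
one score space in which all downstream analyses live. Downstream stages
select *rows* of the score matrix (e.g. only enrollment samples) rather
than refitting; this matches a single-projection workflow and is the
simplest defensible choice, at the cost of a mild optimism: the component
directions have seen the held-out subjects' samples (not their outcomes).
The data are explicitly re-centered at fit time, and projection of unseen
samples subtracts the *training* mean.

Eigenvector sign is arbitrary, so each loading column is oriented to make
its largest-magnitude entry positive; the decomposition is bit-reproducible.

The metadata screen computes Spearman ρ between every PC score and each of
BMI, age, gender (0/1), A1C, dropping missing values pairwise.
Benjamini–Hochberg correction is applied within each covariate across the
8 PCs (the family is "which PCs associate with this covariate"). A constant
or nearly absent covariate yields NaN statistics, not an error.

## Group classification

A linear SVM (hinge loss, L2 penalty, C = 1 by default) on the 8 PC scores
separates lean vs obese or presurgery {A, B} vs postsurgery {C, D, E}. Two
evaluation modes exist because they answer different questions:

* `stratified5` (default) pools decision values from held-out stratified
  folds — out-of-sample separability;
* `resubstitution` scores the training data — in-sample separability,
  cheap enough for large permutation ensembles and null calibrations.

The ROC is computed from the pooled decision values; the AUC equals the
Mann–Whitney U statistic normalized by n⁺n⁻, with ties counting one half
(verified against exhaustive pair counting). Significance comes from label
scrambling: the class multiset is preserved, the *entire* train+evaluate
path is re-run per scramble, and `p = (1 + #{AUC_perm ≥ AUC_obs})/(n_perm + 1)`
— the add-one rule keeps p off zero. Reported per-PC weights come from the
full-data fit.

## Outcome prediction

For each subject with an enrollment (A) sample and a follow-up BMI at the
chosen horizon (6, 12 or 18 months), the response is
`ΔBMI = BMI(follow-up) − BMI(A)` (negative = loss). The predictor matrix is
the subjects' A-point PC scores. The model is the LASSO, validated
leave-one-out so each subject is predicted by a model that never saw them.

* **Penalty.** Chosen per outer fold by an *inner* leave-one-out grid
  search (20 log-spaced values from the data-driven λ_max down 3 decades)
  with the one-standard-error rule: the largest penalty whose inner CV
  error is within one SE of the minimum. The 1-SE rule is used because the
  reported object is the fold-averaged coefficient vector, and minimum-CV
  penalties admit unstable, fold-specific noise coefficients. A fixed
  penalty can be passed for deterministic tests.
* **Support.** The fold-averaged coefficient of a variable is
  floating-point-nonzero as soon as one fold selects it, so `support` is
  operationalized the way stability selection (and a bar plot of averaged
  weights) reads it: a PC belongs to the support iff the LASSO kept it in a
  strict majority of the LOO fits. The raw averages are always reported.
* **Evaluation.** The binary target is "more than median loss": observed
  delta strictly below the median (ties go to the less-change class; the
  convention must be pinned and this is the conservative one). Because a
  *lower* predicted delta should rank such subjects first, the ROC score is
  the negated prediction. The permutation p scrambles the predicted values
  (the observed deltas and their median split stay fixed), add-one rule.
  One caveat: under a global null, out-of-fold LOO predictions are slightly
  *anticorrelated* with the held-out outcomes (each is built from the other
  subjects' responses), so this permutation test is conservative for
  LOO-derived predictions — it never inflates the type-I error.
  Spearman ρ between predicted and observed deltas is reported with its
  asymptotic p.
* **No leakage.** Removing or altering subject *i*'s outcome cannot change
  the prediction for *i* (its model never saw y_i); a dedicated test
  asserts this invariance, and the nested penalty search runs entirely
  inside the training fold.

The 12-month horizon is supported identically but deserves caution at
small n: intermediate horizons can sit in a low-signal regime.

## Interaction network

Within each subject, consecutive *sampled* time points (A<B<C<D<E; a
missed visit lengthens the step) define pairs (x(t), y(t) = x(t+1) − x(t))
on the log-transformed table, pooled across subjects and transitions. Lean
controls have one time point and contribute nothing by construction. For
each target taxon *i*, OLS with intercept regresses y_i on the levels of
*all* taxa at t — the self term included, since self-damping is a real and
expected effect. Two-sided t-tests per coefficient are Bonferroni-corrected
over all n² tests (the conservative denominator; n(n−1) without self
terms), and survivors at α = 0.05 become directed signed edges j → i.

Degenerate exact fits (noiseless simulated dynamics leave ~zero residuals,
making the t statistic 0/0) fall back to a numerical-zero threshold of
1e-10 on |β|. Identifiability requires more pairs than taxa — the error
message suggests collapsing to a coarser rank (default: class). The
published-style view restricts to the largest weakly connected component
of the significant-edge graph, ties broken toward the component containing
the lexicographically smallest taxon.

Phylum/class trend tracking collapses the log table at the coarse rank,
reports mean ± SD per time point, and flags monotone trends by Spearman of
sample values against the A–E time index (±1 at p < 0.05, 0 otherwise, NaN
with fewer than two sampled time points).

## Synthetic cohort generator

The generator provides ground truth for every recovery test. Per subject:
latent log10 abundance = taxon intercept + factor loadings · subject
factors (+ group shift for obese) + noise; abundances are exponentiated
and closed to relative frequencies per sample. Obese trajectories evolve
on the log scale as `x(t+1) − x(t) = B(x(t) − baseline) + drift + ε` with
a known sparse stable interaction matrix B (spectral radius of I + B ≤ 1;
the boundary case B = 0 — a random walk — is the legitimate
no-interaction null; random draws are rejection-sampled until stable,
deterministically per seed). Because the dynamics act on deviations from the
subject-invariant baseline, the constant term folds into the delta
regression's intercept and OLS sees B exactly. BMI at enrollment is drawn
around 43.3 (SD 6.8) for the obese and uniform 19–25 for the lean;
follow-up deltas are a linear function of two designated factors plus
noise at a signal-to-noise ratio of 2; attrition mirrors the emulated
design (sampling probabilities 1.0/0.88/0.35/0.33/0.14 for A–E).

Design choices made for identifiability, i.e. so that structure recovery
is mathematically possible and failures indict the estimator rather than
the simulation:

* **Disjoint factor blocks with balanced signs.** Each factor loads on its
  own block of taxa with equal-magnitude ± entries, signs greedily balanced
  against taxon abundance so the factor leaves the per-sample total (the
  closure denominator) untouched to first order. This keeps factor
  directions orthogonal to each other and to the compositional "size" axis.
* **Separated eigenvalues.** Block sizes (14, 8, 6, 4, 12) and scales are
  chosen so the component spectrum is ordered with clear gaps: group axis >
  factor 1 > factor 5 (the outcome-linked pair) > size axis > nuisance
  factors > noise bulk. Without the gaps, sample eigenvectors rotate freely
  within near-degenerate subspaces and no method could attribute outcome
  signal to individual components.
* **Dominant taxa carry no structure.** Factor blocks and the group-shift
  set avoid the six most abundant taxa, whose fluctuations drive the
  closure total.
* **Small amplitudes.** All per-taxon variation is kept below ~0.2 log10
  units so the `log10(freq + 0.1)` chain operates in its approximately
  linear regime; the whitening step restores scale, so only
  signal-to-noise ratios matter for the analysis.

What the generator does **not** emulate: sequencing counts and their
sampling noise, batch effects, diet composition, non-linear or saturating
dynamics, taxon birth/death, and real taxonomic correlation structure.
Passing recovery tests therefore demonstrates the estimators' correctness
under the assumed model, not performance on real sequencing data — the
published cohort's effect sizes and AUCs are not reproducible from
simulation and are out of scope here.

## Numerical conventions

* Population SD (divisor n) everywhere whitening is involved.
* Permutation p-values use the add-one rule; p ∈ [1/(n_perm+1), 1].
* All randomness flows through `numpy.random.default_rng` from explicit
  seeds; identical seeds give bit-identical outputs.
* Median-split ties go to the "less change" class.
* Duplicate enrollment samples for a subject are an error unless the
  caller opts into first-sample selection.
* The simulation sizes used by the test-suite and the acceptance script
  (e.g. 500 calibration replicates at 200 scrambles, 20 recovery seeds,
  10-taxon network simulations with 200 pairs) are the package's chosen
  desk-scale study conditions: large enough for the stated tolerance
  bands, small enough to run routinely.
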