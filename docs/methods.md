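# Methods

This note documents the models and numerical choices behind the package, what
the synthetic cohort does and does not emulate, and the decisions taken where
the design was genuinely open.

## Screen model and normalization

One patient sample occupies one 384-well plate: 64 drugs x 5 ascending
concentrations (320 treated wells), 32 DMSO control wells, 32 empty wells.
Viability of a well is its luminescence divided by the *median* of the 32
same-plate control RLUs, in percent. The median (midpoint of the two central
order statistics for even counts) makes the normalizer robust to a few
aberrant control wells; by construction the median of normalized controls is
exactly 100, and normalization is invariant to any rescaling of the plate's
luminescence. Values above 100% are retained — drug-induced viability
increases (e.g. paradoxical pathway activation by RAF inhibitors in
RAS-mutant cells) are a real signal — with clipping available as an option.
No edge-well filter or control trimming is applied by default; both would be
easy to add at the plate layer, but the plate design (breathable sealing
foil) is assumed to control evaporation.

Concentration index 1 is the lowest molar concentration; "the 2 lowest
concentrations" always means indices 1 and 2. If only one of the two lowest
is observed, the low-2 summary uses the available value rather than
propagating missingness — this maximizes sample retention and the case is
visible in the QC report. Replicate wells for the same (sample, drug,
concentration) are averaged at tensor assembly; the tested design has one
well per condition, the rule covers pilot layouts.

## Synthetic cohort: what is emulated

The generator produces the *statistical structure* the analysis stages
consume, not molecular-level data:

* **Composition.** 184 CLL + 62 other blood cancers + 3 healthy controls
  (249 screened samples). IGHV mutated with probability 98/172 ≈ 0.57.
* **Genetics.** Features are drawn by sequential logistic conditioning:
  TP53 | del17p13 (log-odds = log 29), del13q14 | trisomy 12 (log 0.2),
  pretreatment | TP53, IGHV (log 8, log 4). Intercepts are solved numerically
  (Brent) against the *realized* parent draws so marginal frequencies hit
  their targets exactly in expectation; infeasible OR/frequency combinations
  raise with the offending pair. Frequencies: trisomy 12 0.17 (the literature
  range is 15–20%), TP53 0.12, del17p13 0.10, del13q14 0.45, del11q22.3 0.15,
  plus rarer mutations at 2–5%.
* **Response groups.** Latent BTK/mTOR/MEK/weak labels with expected sizes
  50/26/23/85 of 184, assigned conditionally on IGHV so that the mTOR group
  is almost exclusively IGHV-mutated (target 22/23) and BTK/MEK lean
  unmutated.
* **Viability.** v(s,d,c) = 100 · (1 − e(d,c) · sens(s,d)) with per-drug kill
  fractions e nondecreasing in concentration (three regimes: targeted,
  cytotoxic, inert filler) and sens(s,d) = logistic(b₀(d) + β·x(s) + ε),
  ε ~ N(0, σ_bio = 0.3) on the logit (keeps sensitivities in (0,1) and gives
  right-skewed viability noise, as observed in such assays). The IGHV effect
  on ibrutinib is calibrated analytically so unmutated samples average 89.2%
  viability at the lowest concentration vs 99.5% in mutated samples — the one
  quantitative anchor available — and `beta_for_viability_delta` solves any
  other percent-point target the same way. TP53/del17p13 confer resistance to
  fludarabine, doxorubicin and nutlin-3; pretreated samples get an extra
  resistance effect on the fludarabine class so the blocked association test
  has a genuine confounder to remove; trisomy 12 sensitizes to PI3K/mTOR/MEK
  inhibition. Technical noise is multiplicative lognormal on RLU
  (σ_tech = 0.03, a typical plate-reader CV), applied either directly to the
  tensor or at plate rendering (RLU = L₀ · v/100 · lognormal), never both.
* **Outcomes.** Exponential hazards h₀·exp(η) with independent uniform
  administrative censoring; η_OS = 0.8·TP53 + 0.5·IGHV-U + 0.4·del17p13 +
  0.3·pretreated, η_TTT = 1.0·IGHV-U + 0.5·TP53 + 0.4·trisomy 12. The
  exponential baseline gives closed forms (median = ln 2 / h₀) for
  independent checks. TTT records are generated for 174 of 184 samples.
* **Omics.** Expression and methylation matrices are latent-factor models
  (leading factors tracking IGHV/trisomy 12 and the methylation programming
  cluster respectively) — just enough covariance structure for the lasso
  variance decomposition to find, not count- or beta-scale data.

What is *not* emulated: clonal heterogeneity and allele-frequency dose
effects, batch/edge spatial artifacts, inter-assay drift, non-exponential
hazards, informative censoring, and any molecular-level realism in the omics
blocks. Passing tests therefore demonstrate correctness of the statistical
machinery under its stated assumptions, not performance on real screens.

All randomness flows from one seed through spawned sub-streams; every planted
quantity is recorded in a `TruthTable` (per-sample groups, per-(drug,
covariate) viability deltas, per-sample Cox linear predictors, planted
decision thresholds).

## Numerical and statistical choices

* **Median polish**: rows swept first, convergence when the sum of absolute
  residuals drops by < 1% (relative), max 10 sweeps — the classical published
  defaults, all config-exposed. The per-sample aggregate is overall + row
  effect (the only orientation that yields one value per sample). The
  decomposition reconstructs every observed cell exactly and is linear under
  scaling.
* **t-test variant**: Student's pooled-variance t by default, Welch via
  `equal_var=False`. Measured under the generator's null, Welch's
  Satterthwaite approximation is several-fold anti-conservative at p < 10⁻³
  when a genotype group has only 3–10 carriers — precisely the tail an FDR
  scan reads — while the pooled statistic stays calibrated there. Group-vs-
  rest cosensitivity keeps Welch: its groups have ≥ 23 members, where Welch
  is safe and robust to unequal variances.
* **BH family**: one family across all drug x feature (or drug x
  concentration) tests per scan, not per drug.
* **Blocked tests**: two-factor linear model y ~ feature + block; effect and
  p from the feature coefficient. Genotypes are never imputed; features with
  > 20% missing annotations are tested on complete cases and flagged.
* **Fisher odds ratio**: conditional MLE (as in R's `fisher.test`), with the
  sample OR also emitted and an infinity sentinel for zero-cell tables.
* **Drug correlation**: pairwise-complete Pearson, cells with < 3 complete
  pairs missing, zero-variance drugs missing (not 0) with a warning;
  clustering on 1 − r with complete linkage (average/ward optional).
* **Embedding**: t-SNE as a pluggable standard component; per-column median
  imputation beforehand (neutral, deterministic); perplexity guard n ≥ 3·px.
* **Ternary statistic**: the degenerate denominator Σv = 300 maps to
  (1/3, 1/3, 1/3) so every sample stays plottable.
* **Decision-tree thresholds**: the exact published cutoffs are not in the
  main text of the literature this mirrors, so thresholds are mandatory
  config; `calibrate_thresholds` ships a sequential-quantile calibration that
  matches expected group sizes (50/26/23/85), and the generator exposes its
  planted boundaries. Classification uses the low-2 summary.
* **Lasso decomposition**: outer folds reshuffled each repetition (default
  100 x 10-fold; the acceptance suite uses 25 x 5-fold at n = 184 — CV
  estimates there are stable to ~0.02), λ by inner 5-fold CV with the
  minimum-error rule ('1se' optional), predictors standardized inside
  training folds only, out-of-fold R² floored at 0 for reporting (the
  quantity of interest is nonnegative explanatory power). Cross-validated
  rather than in-sample R² is reported — the honest generalization estimate,
  biased slightly low (≈ 0.03–0.05 at n = 184) relative to the population
  share.
* **Adaptive lasso**: stage-1 ridge (α by CV) rather than OLS for the
  weights — well-defined at p ≈ n with correlated features — γ = 1; stage-2 λ
  by the one-standard-error rule, because the profile exists to display a
  sparse biomarker signature (the min rule keeps ~1–2 noise features on null
  data; 1-SE keeps ≤ 1 in ≥ 90% of null fits). Coefficients are reported on
  the original feature scale.
* **Cox**: lifelines' partial-likelihood fit; ties handled by Efron's method
  (the lifelines implementation; with continuous times ties are almost surely
  absent, so the Breslow/Efron distinction is immaterial here). Drug
  covariates are pre-scaled so one regressor unit = 10 percent-viability
  points; age enters as linear years.
* **Maximally selected rank statistic**: candidates are observed values
  inside the 10–90% quantile window with ≥ 5 samples per side; the statistic
  is the standardized log-rank Z with hypergeometric variance and
  finite-population correction, vectorized over candidates; significance by a
  seeded permutation test (default 1000) that re-maximizes per permutation —
  exact at this scale, so no improved-Bonferroni approximation is
  implemented. The statistic at any fixed cutpoint squares to the ordinary
  log-rank chi-square.

## Degenerate inputs

Zero/negative control medians, unknown well coordinates, unmapped wells,
layout overflows, constant responses, constant covariates, all-censored
survival, infeasible OR targets and empty gene universes all raise with a
message naming the offender; missingness in viability data propagates as NaN
and never raises.

## Problem sizes in the test suite

Simulation-based checks use the study-shaped cohort (184 CLL, 63 drugs post
QC): 100 seeds for FDR/power calibration and tree recovery, 100 seeds for
adaptive-lasso support recovery, 200 simulations x 199 permutations for the
null calibration of the cutpoint test, n = 2000 for large-sample Cox checks,
and 12 noise draws x 5 repetitions for the planted variance-share check.
These sizes put Monte-Carlo error well inside each asserted tolerance.

## Known limitations

The generator's effect sizes beyond the ibrutinib/IGHV anchor are plausible
but invented, and are config — not asserted as external truth. The
classification tree is only as good as its thresholds; the shipped
calibration assumes the cohort mirrors the expected group mix. PAGE assumes
approximately independent gene statistics (its Z is anti-conservative under
strong inter-gene correlation). The permutation p of the cutpoint statistic
assumes exchangeability of the drug response against (time, event). Cox
standard errors assume proportional hazards, which the exponential generator
satisfies by construction but real cohorts need not.
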