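# Methods

This note records the models, numerical choices, and deliberate design
decisions behind `grm`, and what the synthetic-data experiments do and do
not demonstrate about real cohorts.

## Two-stage offset-corrected risk model

Demographic confounding is removed in stage 1: an unpenalized logistic
regression of dementia status on age, sex, and (where supplied)
ancestry-specific principal components, fit by Newton's method
(statsmodels) to a gradient norm below 1e-6. The fitted linear predictor
η₁ᵢ becomes the stage-2 *offset* — a term with coefficient fixed at 1 on
the logit scale. "Subtracting the demographic prediction" is not literally
computable for a binary outcome; offsetting in the linearized (link)
space is the standard GLM realization and is what stage 2 implements. A
direct consequence, used as a test invariant, is that a stage-2 model
whose genetic coefficients are all zero reproduces the stage-1
probabilities exactly.

Under (quasi-)perfect separation stage-1 coefficients diverge; they are
capped at |β| ≤ 15 with a warning so offsets stay bounded. Covariate
columns with zero variance are collinear with the intercept and receive
coefficient 0.

### Elastic-net stage 2

For the SNP-dosage predictor set, stage 2 minimizes

    -(1/n) ℓ(β₀, β) + λ [α‖β‖₁ + (1-α)/2 ‖β‖₂²]

with the offset unpenalized and the intercept unpenalized. The solver is
glmnet-style: IRLS outer loops around cyclic coordinate descent on the
weighted least-squares subproblem, warm-started along a decreasing
λ path of `n_lambda` log-spaced values from λ_max (the smallest λ with all
coefficients zero, computed from the score at the intercept+offset-only
fit; for α below 0.001 the α in that formula is floored at 0.001) down to
λ_max·10⁻³. Features are standardized internally (penalty applied on the
standardized scale, as glmnet does) and coefficients returned on the
original scale; all-constant columns are dropped with a warning. The
compiled kernel (numba) converges each CD sweep to 1e-7 coefficient
change. Correctness anchors: at λ→0 the fit matches the statsmodels GLM
maximum-likelihood solution with offset to ~1e-9; at large λ all genetic
coefficients are zero and predictions equal stage 1; at fixed (α, λ) on
pre-standardized features the solution matches
`GLM.fit_regularized(method="elastic_net")` to ~1e-9.

### Cross-validation design

Hyperparameters are chosen by stratified k-fold (default 5) CV deviance
over an α grid (default 0.1…1.0 in steps of 0.1) × the λ path, ties going
to the larger λ then larger α. The reported model is refit on all samples
at that choice. Pooled hold-out predictions — the basis of every
performance number — come from per-fold refits in which (α, λ) are
re-chosen by *inner* CV on the training folds only; hold-out samples never
inform selection. Fold assignment is stratified by case status and
deterministic under the seed. One source of optimism remains by design:
stage 1 is fit once on the full analytical sample (as the workflow defines
the offset per cohort), which inflates null AUROC by roughly +0.01 at
n = 5000 with two covariates; the calibration test therefore checks that
the across-seed interval covers 0.5 rather than the mean equalling 0.5.

### Bootstrap stability selection and importance

Each of `n_boot` iterations resamples subjects with replacement (a
single-class resample is redrawn and logged), refits stage 1 and an
elastic-net stage 2 (λ re-chosen by CV within the resample, α frozen;
reusing both is available), and records the nonzero-coefficient SNP set.
SNPs selected in ≥95% of iterations are retained. Variable importance —
whose definition the source workflow leaves open — is |β_j|·sd(x_j)
normalized to sum to 1 over the nonzero set; this is invariant to feature
rescaling. The report renormalizes mean importances over the retained set
(so retained importances sum to 1) and gives 2.5/97.5 percentile intervals
of the per-iteration importances (zeros included when unselected).

### Frozen-weight transfer

Validation on a second cohort refits stage 1 on the new cohort's
demographics (demographic effects are always estimated in-cohort) and
applies the trained genetic coefficients unchanged on top of the new
offsets.

## SNP prioritization

Risk loci are built by greedy LD clumping: the unassigned variant with the
smallest p-value below 5e-8 (ties: smaller position, then id) becomes an
index SNP and captures every unassigned same-chromosome variant with
r² ≥ 0.2 against it, with r² computed as the squared Pearson correlation of
dosages on a caller-supplied reference panel; iteration continues until no
sub-threshold variant remains, then loci whose spans lie within a 250 kb
merge window (a common locus-definition default, exposed as a parameter
and skippable) are merged. Per locus, the p-significant lead is the
minimum-p member and the CADD lead the maximum-CADD member (ties: smaller
p, then position). A 0.1 r² cutoff, used as a sensitivity analysis,
produces coarser loci in which every 0.2-locus nests; the test suite
asserts this empirically. Effect alleles are harmonized to the panel's
alternate allele with β sign flips; strand-ambiguous variants are assumed
removed by upstream QC, and panels without allele metadata (bare-rsID
dosage TSVs) pass betas through unchanged.

## Genetic features

PRSs are plain weighted dosage sums standardized to mean 0 / sd 1 of the
score distribution in an external reference panel (emulating a reference
population), with missing dosages imputed to twice the allele frequency of
the scored matrix. The APOE-ε4 count derives the diplotype from the
unphased rs429358/rs7412 genotype pair by the standard lookup; the
rs429358-het/rs7412-het pair is resolved to ε2/ε4 (ε1 haplotypes are
vanishingly rare) and flagged ambiguous.

## EHR phenotyping

Filters run in a fixed order, and the first failure is the recorded
exclusion reason: complete demographics → ≥2 encounters after age 55 →
age at last encounter < 90 (censoring) → case iff a dementia-coded
encounter exists with first occurrence strictly after 55 → otherwise
control iff no dementia/exclusion code ever, last visit at ≥70, span ≥5
years, and ≥1 encounter/year on average. Span is the years between first
and last encounter (fractional days); a single-encounter patient has span
0 and rate equal to the count. Dementia and exclusion ICD-10 code sets are
configuration; the shipped defaults cover the five major dementia code
families (G30, F03, F02, F01, G31.83) and a small dementia-adjacent
exclusion list, and real studies should supply their own curated lists.

## Evaluation

AUROC uses the Mann–Whitney formulation (ties ½); AUPRC the step-wise
non-interpolated estimator (average precision). The operating point
maximizes |MCC| over midpoints of adjacent distinct scores (ties: lower
threshold; a negative-MCC optimum is flagged as an orientation warning),
and F1/accuracy/precision/recall/specificity are reported there. The
DeLong test uses placement-value structural components with midrank tie
handling; it matches R's `pROC::roc.test` on shared instances and is
calibrated (type-I error and p-uniformity) in the acceptance suite. The
Wilcoxon signed-rank test drops zero differences, uses the exact null for
≤25 distinct nonzero differences and the tie/continuity-corrected normal
approximation otherwise. Relative model improvements are reported as
(b−a)/a in percent. Paired bootstrap AUPRC vectors share resample indices
across models so the Wilcoxon pairing is valid; the acceptance script
performs this bootstrap at the evaluation level (resampling pooled
hold-out predictions) rather than refitting models per iteration, a
runtime compromise that preserves the pairing.

## Gene mapping and enrichment

Mapping is positional only: containment in a gene interval wins, otherwise
the nearest gene within 10 kb of an interval edge (all ties reported);
eQTL and chromatin-interaction tiers require external resources and are
out of scope. Enrichment is the upper-tail hypergeometric probability with
Benjamini–Hochberg correction across all tested sets; the background
defaults to all annotated genes.

## Synthetic cohorts: what they emulate, and what they do not

Genotypes: two haplotypes per individual from a latent equicorrelated
Gaussian per LD block, thresholded at the allele frequency. Thresholding
attenuates correlation, so the latent correlation is solved numerically
(bivariate-normal orthant probability, bisection to 1e-6) to make the
realized dosage r² match the configured `block_r2`; variants within a
block share a base allele frequency (±0.02 jitter) because large frequency
mismatches cap the attainable correlation. Ancestry groups perturb block
frequencies by a Balding–Nichols Beta draw (default Fst 0.05). The
reference panel is an independent draw from the same block model. Two
designated variants play rs429358/rs7412, drawn from ε2/ε3/ε4 haplotype
frequencies (default 0.08/0.78/0.14, European-like).

Summary statistics: the expected effect at each variant is the *marginal*
(LD-convolved) effect Σ_c r_jc β_c, as single-SNP GWAS regressions
estimate, with sampling noise se = 1/√(2p(1−p)·n·φ(1−φ)) (φ = GWAS case
fraction, default 0.5) and two-sided normal p-values; Z = β/se reproduces
p to 1e-10 relative error, and variants uncorrelated with any causal SNP
are exact nulls.

Phenotype: Bernoulli draws from a logistic model on age (N(75, 7²),
clipped to [56, 89.5]), sex, and causal dosages, with the intercept
root-found so expected prevalence matches the configuration (default 0.20,
matching the motivating cohorts' case fractions). Encounters: a
homogeneous Poisson process over a Gamma-distributed observation window
(case spans shorter than control spans by default, ~6 vs ~9.5 years, with
~14 encounters/year — the pattern the eligibility filters induce); cases
carry one dementia-coded encounter strictly after the onset floor, and a
configurable fraction of controls (default 0.25) receives histories that
fail one eligibility filter.

The multi-disease study (`grm.pipeline.multi_disease_study`) plants twelve
5-SNP blocks plus the APOE pair; AD/PD/PSP "GWASs" are significant at
designated block leads, but the cohort's dementia liability misaligns with
the GWAS weights in the two ways that motivate in-cohort reweighting: one
GWAS-significant SNP per disease is dementia-null, and each shared SNP's
GWAS weight is the cohort effect scaled by a log-uniform (0.4, 2.5)
transferability factor. The default study size is 2000 samples — large
enough that AUPRC sampling noise does not swamp the true margins between
models; the acceptance experiments use 50 such studies.

What passing tests do **not** show: the generator has no recombination
maps, admixture tracts, imputation error, genotyping batch effects,
missing-not-at-random EHR observation, diagnostic miscoding, or
competing-risk mortality. Results on these cohorts demonstrate the
correctness and internal consistency of the pipeline and the qualitative
mechanism behind the model ordering — not clinical performance on any real
population.

## Known limitations

- The elastic-net λ path bottom (λ_max·10⁻³) can leave weak effects
  unselected on very small cohorts; extend `n_lambda`/`lambda_min_ratio`
  if needed.
- `bootstrap_stability` refits λ per iteration by default; at 1000
  iterations on large cohorts this is the dominant cost.
- VCF dosages round-trip through a single-precision DS FORMAT field
  (~1e-7 relative loss); the dosage TSV round-trip is bit-exact.
- The DeLong variance estimate degenerates (p = 1, flagged) when both
  score vectors induce identical placements.
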