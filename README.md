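# grm — genetic risk modeling of dementia from EHR-linked genotypes

`grm` is a tested re-implementation of an ancestry-stratified workflow for
modeling all-cause dementia risk from real-world data: GWAS summary
statistics are clumped into genomic risk loci against a reference LD panel,
two prioritized SNP sets are extracted per locus (the most significant SNP
and the highest-CADD SNP), polygenic risk scores (PRSs) and APOE-ε4 counts
are built as genetic predictors, eligible cases and controls are phenotyped
from ICD-10 encounter tables, and dementia status is predicted with
two-stage offset-corrected models compared under imbalanced-classification
metrics. Because the motivating cohorts (biobank-linked EHR data) are
access-restricted, the package ships a synthetic-cohort generator with
known ground truth that exercises every stage end to end.

It is written for statistical geneticists and clinical-informatics
researchers who want a transparent, reproducible version of this modeling
workflow, or a harness for methods experiments on it.

## The model

Stage 1 removes demographics: an unpenalized logistic regression of case
status on age, sex, and ancestry-specific principal components. Its fitted
linear predictor enters stage 2 as a GLM **offset** (coefficient fixed at
1), so stage 2 measures genetic signal net of demographics and population
structure:

    ŷ_i = g⁻¹(β₀ + Σ_j β_j x_ij + offset_i),     g = logit.

Stage-2 predictor sets: (1) APOE-ε4 allele count from the rs429358/rs7412
diplotype; (2) a single standardized PRS, `PRS_i = Σ_j β̂_j · dosage_ij`
with GWAS weights; (3) multiple disease PRSs; (4) raw prioritized SNP
dosages under elastic-net regularization, with (α, λ) chosen by
cross-validated deviance over a grid (inner CV confined to training folds)
and performance reported on pooled hold-out predictions. Bootstrap
stability selection (resampling subjects, refitting both stages) retains
SNPs selected in ≥95% of iterations. Models are compared by AUPRC and
AUROC, with DeLong tests on paired AUROCs and Wilcoxon signed-rank tests
on paired bootstrap AUPRCs; thresholded metrics use the |MCC|-optimal
operating point.

## Worked example

```python
from grm.pipeline import multi_disease_study, run_model_comparison

study = multi_disease_study(seed=1)          # 2000 samples, 62 variants
comp = run_model_comparison(study, seed=1, alpha_grid=(0.5, 1.0),
                            n_lambda=25)
for name in ("apoe", "multi_prs", "elasticnet_snps"):
    r = comp.reports[name]
    print(f"{name:16s} AUPRC {r.auprc:.3f}  AUROC {r.auroc:.3f}")
```

prints

```
apoe             AUPRC 0.369  AUROC 0.671
multi_prs        AUPRC 0.377  AUROC 0.680
elasticnet_snps  AUPRC 0.405  AUROC 0.698
```

The cohort has a case fraction of 0.195, so an uninformative score would
sit near AUPRC 0.195 and AUROC 0.5; all three genetic models add signal on
top of the demographic offset, and the elastic-net SNP model — which can
reweight SNPs in-cohort instead of trusting external GWAS weights — ranks
best on both metrics, a ~10% relative AUPRC improvement over the APOE-only
model (DeLong p ≈ 0.002 for the AUROC difference on these data).

A CLI covers the file-based steps (`grm simulate`, `grm qc`,
`grm prioritize`, `grm prs`, `grm select-cohort`, `grm fit`,
`grm evaluate`, `grm enrich`); run `grm --help` for details.

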