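"""End-to-end workflow: multi-disease synthetic study and model comparison.

Bundles the steps a full analysis runs in order: simulate a cohort whose
dementia liability draws on risk SNPs from several neurodegenerative
"diseases" (each with its own GWAS summary statistics, only partially
aligned with the dementia phenotype), clump each GWAS into risk loci
against an independent reference panel, build the three classes of genetic
predictors (APOE-e4 count, standardized per-disease PRSs, and raw lead-SNP
dosages), and fit the two-stage offset-corrected models for comparison.

The deliberate misalignment between GWAS effects and dementia effects —
some genome-wide-significant SNPs carry no dementia risk — is what gives
per-SNP reweighting (the elastic net) an edge over fixed-weight PRSs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluate import EvalReport, evaluate
from .features import apoe_e4_count, compute_prs, standardize_prs
from .genotypes import GenotypeMatrix
from .models import FittedRiskModel, OffsetVector, apply_model, fit_stage1, \
    fit_stage2
from .prioritize import SummaryStats, build_risk_loci, independent_psig_snps
from .synthetic import GroundTruth, SimulationConfig, simulate_genotypes, \
    simulate_phenotype, simulate_reference_panel, simulate_summary_stats


@dataclass
class MultiDiseaseStudy:
    """One synthetic discovery study with per-disease GWAS inputs."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    truth: GroundTruth
    gwas: dict                      # phenotype tag -> SummaryStats
    reference: GenotypeMatrix
    disease_effects: dict           # phenotype tag -> {variant id: beta}


def multi_disease_study(seed: int, n_samples: int = 2000,
                        gwas_n: int = 300_000, n_ref: int = 400,
                        block_r2: float = 0.6) -> MultiDiseaseStudy:
    """Simulate a dementia cohort with AD / PD / PSP GWAS architectures.

    Twelve 5-SNP LD blocks plus the two APOE-region variants. Each disease
    GWAS has genome-wide-significant effects on designated block leads, but
    the cohort's dementia liability misaligns with the GWAS weights in two
    ways that mirror applying external (largely European-ancestry, other-
    phenotype) GWAS weights to a diverse dementia cohort: (i) some
    GWAS-significant SNPs carry no dementia risk at all (one per disease),
    and (ii) for shared risk SNPs the GWAS effect is the cohort's dementia
    effect scaled by a per-SNP factor drawn log-uniformly from (0.4, 2.5)
    — the SNP is detectable in the external GWAS but its relative weight is
    wrong in this cohort. Fixed-GWAS-weight PRSs therefore misweight
    features that the elastic net can reweight in-cohort.
    """
    apoe_eff = 0.9
    rng = np.random.default_rng(seed + 40_000)
    # cohort dementia architecture: variant index -> log-odds per allele
    dementia_arch = {0: 0.50, 5: 0.45, 15: 0.45, 25: 0.40}
    # disease GWAS candidates: shared risk SNPs plus one GWAS-only (null
    # for dementia) SNP per disease
    gwas_members = {"AD": [0, 5, 10], "PD": [15, 20], "PSP": [25, 30]}

    def transfer(j):
        true_eff = dementia_arch.get(j, 0.0)
        if true_eff == 0.0:
            return float(rng.uniform(0.40, 0.55))   # GWAS-only signal
        return true_eff * float(np.exp(rng.uniform(np.log(0.4), np.log(2.5))))

    gwas_arch = {tag: {j: transfer(j) for j in members}
                 for tag, members in gwas_members.items()}
    config = SimulationConfig(
        n_samples=n_samples, n_blocks=12, snps_per_block=5,
        block_r2=block_r2, maf_range=(0.10, 0.50), prevalence=0.20,
        seed=seed, include_apoe=True, apoe_effect=apoe_eff,
        causal_snps=sorted(dementia_arch.items()))
    geno = simulate_genotypes(config)
    truth = simulate_phenotype(geno, config, config.seed + 11)
    ids = geno.variant_ids
    disease_effects = {
        tag: {ids[j]: e for j, e in arch.items()}
        for tag, arch in gwas_arch.items()
    }
    # the AD GWAS sees the APOE signal attenuated like other shared SNPs
    disease_effects["AD"]["rs429358"] = apoe_eff * \
        float(np.exp(rng.uniform(np.log(0.4), np.log(1.2))))
    gwas = {}
    for k, (tag, effects) in enumerate(disease_effects.items()):
        t = GroundTruth(set(effects), dict(effects),
                        np.zeros(geno.n_samples, dtype=int),
                        ["NA"] * geno.n_samples,
                        truth.age, truth.sex)
        gwas[tag] = simulate_summary_stats(geno, t, gwas_n,
                                           config.seed + 101 + k,
                                           phenotype_tag=tag)
    reference = simulate_reference_panel(config, n_ref=n_ref)
    return MultiDiseaseStudy(config, geno, truth, gwas, reference,
                             disease_effects)


@dataclass
class ModelComparison:
    """Fitted models, pooled hold-out predictions, and per-model reports."""

    models: dict                    # name -> FittedRiskModel
    stage1: OffsetVector
    features: dict                  # name -> pd.DataFrame used by that model
    predictions: dict               # name -> pooled hold-out yhat
    reports: dict                   # name -> EvalReport
    labels: np.ndarray
    lead_snps: dict = field(default_factory=dict)   # tag -> psig leads


def build_genetic_features(study: MultiDiseaseStudy,
                           p_threshold: float = 5e-8,
                           r2_threshold: float = 0.2):
    """Clump each GWAS and construct the three predictor families.

    Returns (feature frames by model name, lead SNPs by GWAS tag).
    """
    geno, ref = study.genotypes, study.reference
    leads, prs_cols = {}, {}
    for tag, stats in study.gwas.items():
        loci = build_risk_loci(stats, ref, p_threshold=p_threshold,
                               r2_threshold=r2_threshold)
        if len(loci) == 0:
            continue
        snp_ids = independent_psig_snps(loci)
        leads[tag] = snp_ids
        raw = compute_prs(geno, stats, snp_ids, snp_set_tag="psig")
        prs_cols[f"PRS_{tag}"] = standardize_prs(raw, ref, stats,
                                                 snp_ids).scores
    apoe = apoe_e4_count(geno)
    pooled = sorted({s for ids in leads.values() for s in ids})
    feats = {
        "apoe": pd.DataFrame({"apoe_e4": apoe.counts.astype(float)}),
        "ad_prs": pd.DataFrame({"PRS_AD": prs_cols["PRS_AD"]})
        if "PRS_AD" in prs_cols else None,
        "multi_prs": pd.DataFrame(prs_cols),
        "elasticnet_snps": pd.DataFrame(
            {s: study.genotypes.column(s) for s in pooled}),
    }
    return {k: v for k, v in feats.items() if v is not None}, leads


def run_model_comparison(study: MultiDiseaseStudy, seed: int = 0,
                         alpha_grid=(0.1, 0.5, 1.0), n_lambda: int = 30,
                         n_folds: int = 5) -> ModelComparison:
    """Fit APOE-count, multi-PRS, and elastic-net SNP models on one study.

    All models share the stage-1 demographic offset and fold assignment;
    reports are computed on pooled hold-out predictions.
    """
    y = study.truth.true_case_labels
    cov = pd.DataFrame({"age": study.truth.age, "sex": study.truth.sex})
    stage1 = fit_stage1(y, cov)
    features, leads = build_genetic_features(study)
    models, preds, reports = {}, {}, {}
    for name, X in features.items():
        models[name] = fit_stage2(
            y, X, stage1, predictor_set=name,
            alpha_grid=alpha_grid, n_folds=n_folds, n_lambda=n_lambda,
            seed=seed)
        preds[name] = models[name].cv_predictions
        reports[name] = evaluate(preds[name], y)
    return ModelComparison(models, stage1, features, preds, reports, y, leads)


def transfer_to_cohort(comparison: ModelComparison, study: MultiDiseaseStudy,
                       new_seed: int) -> dict:
    """Frozen-weight transfer of every fitted model to a fresh cohort drawn
    from the same generative process (a validation-cohort analogue).

    Returns per-model EvalReports on the new cohort.
    """
    cfg = study.config
    new_geno = simulate_genotypes(cfg, seed=new_seed)
    new_truth = simulate_phenotype(new_geno, cfg, new_seed + 11)
    y = new_truth.true_case_labels
    cov = pd.DataFrame({"age": new_truth.age, "sex": new_truth.sex})
    new_study = MultiDiseaseStudy(cfg, new_geno, new_truth, study.gwas,
                                  study.reference, study.disease_effects)
    features, _ = build_genetic_features(new_study)
    out = {}
    for name, model in comparison.models.items():
        probs, _ = apply_model(model, y, cov, features[name])
        out[name] = evaluate(probs, y)
    return out
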