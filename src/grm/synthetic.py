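"""Synthetic cohort generation with known ground truth.

Every downstream stage of the pipeline — QC, clumping, PRS construction,
EHR phenotyping, and offset-corrected risk modeling — is exercised on data
from this module, which plants a known causal architecture so that recovery
can be asserted.

The genotype model draws two haplotypes per individual from a latent
equicorrelated Gaussian per LD block, thresholded at the allele frequency.
Thresholding attenuates correlation, so the latent correlation is solved
numerically (via the bivariate-normal orthant probability) to hit the
configured dosage r2. Between blocks, variants are independent. Ancestry
groups share ancestral allele frequencies perturbed by a Balding-Nichols
Beta draw governed by an Fst parameter.

Phenotypes follow a logistic model on age, sex, and planted causal dosages,
with the intercept calibrated by root-finding so the expected prevalence
matches the configuration. Encounter histories are homogeneous Poisson
processes over a sampled observation window; cases receive a dementia
ICD-10 code at an onset age above the configured floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotypes import GenotypeMatrix, VariantRecord


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


# Default ICD-10 codes: dementia codes weighted toward the most prevalent
# diagnoses (Alzheimer's G30, unspecified dementia F03), plus common
# non-dementia codes used for filler encounters.
DEMENTIA_CODES = ("G30.9", "F03.90", "F02.80", "F01.50", "G31.83")
DEMENTIA_CODE_WEIGHTS = (0.40, 0.30, 0.12, 0.12, 0.06)
FILLER_CODES = ("I10", "E11.9", "M54.5", "J06.9", "Z00.00", "E78.5")

#: Default APOE haplotype frequencies (epsilon2/3/4), European-like.
APOE_HAP_FREQS = {"e2": 0.08, "e3": 0.78, "e4": 0.14}

AS_OF_DATE = pd.Timestamp("2024-01-01")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic study.

    ``n_samples`` is the count per ancestry group; ``causal_snps`` is a list
    of ``(variant_index, log_odds_effect)`` pairs addressing columns of the
    simulated genotype matrix; ``demographic_effects`` is
    ``(log-odds per year of age, log-odds for female sex)``.
    """

    n_samples: int = 1000
    n_blocks: int = 10
    snps_per_block: int = 5
    block_r2: float = 0.5
    causal_snps: Sequence[tuple[int, float]] = ()
    demographic_effects: tuple[float, float] = (0.10, -0.20)
    prevalence: float = 0.20
    maf_range: tuple[float, float] = (0.05, 0.50)
    seed: int = 0
    ancestries: tuple[str, ...] = ("HLA",)
    fst: float = 0.05
    dosage_noise_sd: float = 0.0
    # encounter-history parameters (years / per-year)
    case_mean_span: float = 6.0
    control_mean_span: float = 9.5
    mean_encounter_rate: float = 14.0
    control_fail_fraction: float = 0.25
    case_onset_age_min: float = 55.0
    include_apoe: bool = False
    apoe_hap_freqs: dict = field(default_factory=lambda: dict(APOE_HAP_FREQS))
    #: log-odds per copy of the rs429358 alternate (C) allele, the epsilon4
    #: tag; applies only when include_apoe is set.
    apoe_effect: float = 0.0

    def __post_init__(self):
        if not 0 <= self.prevalence <= 1:
            raise ConfigurationError("prevalence must lie in [0, 1]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for name in ("n_samples", "n_blocks", "snps_per_block"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 <= self.block_r2 <= 1:
            raise ConfigurationError("block_r2 must lie in [0, 1]")
        m = self.n_variants
        for idx, _ in self.causal_snps:
            if not 0 <= idx < m:
                raise ConfigurationError(
                    f"causal variant index {idx} outside [0, {m})")

    @property
    def n_variants(self) -> int:
        return self.n_blocks * self.snps_per_block

    @property
    def n_total_samples(self) -> int:
        return self.n_samples * len(self.ancestries)


@dataclass
class GroundTruth:
    """Planted truth exposed for downstream assertions."""

    causal_variant_ids: set
    true_effects: dict                 # variant id -> log-odds
    true_case_labels: np.ndarray       # 0/1 per sample
    ancestry_label: list
    age: np.ndarray                    # years at study end
    sex: np.ndarray                    # 1 = female
    intercept: float = 0.0

    def __post_init__(self):
        if self.causal_variant_ids != set(self.true_effects):
            raise ConfigurationError(
                "causal_variant_ids must equal keys of true_effects")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _bvn_p11(t: float, rho: float) -> float:
    """P(Z1 < t, Z2 < t) for standard bivariate normal with correlation rho."""
    if rho >= 1.0:
        return stats.norm.cdf(t)
    return float(stats.multivariate_normal(
        mean=[0, 0], cov=[[1, rho], [rho, 1]], allow_singular=True
    ).cdf([t, t]))


def _solve_latent_rho(target_r: float, maf: float) -> float:
    """Latent Gaussian correlation yielding Pearson correlation ``target_r``
    between alleles thresholded at frequency ``maf``."""
    if target_r <= 0:
        return 0.0
    t = stats.norm.ppf(maf)

    def bern_corr(rho: float) -> float:
        p11 = _bvn_p11(t, rho)
        return (p11 - maf * maf) / (maf * (1 - maf))

    if bern_corr(0.9999) <= target_r:
        return 0.9999
    return float(optimize.brentq(lambda r: bern_corr(r) - target_r,
                                 0.0, 0.9999, xtol=1e-6))


def _variant_records(config: SimulationConfig, mafs: np.ndarray) -> list[VariantRecord]:
    """One chromosome per block, 10 kb spacing within blocks."""
    recs = []
    j = 0
    for b in range(config.n_blocks):
        for s in range(config.snps_per_block):
            recs.append(VariantRecord(
                id=f"rs{100000 + j}", chrom=str(b + 1), pos=1_000_000 + s * 10_000,
                ref_allele="A", alt_allele="G",
                info={"af": float(mafs[j])}))
            j += 1
    return recs


def _ancestral_mafs(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Block base frequencies plus small per-variant jitter.

    Variants sharing an LD block get near-identical frequencies (as variants
    on a shared haplotype background do); large frequency mismatches would
    cap the attainable dosage correlation below the block_r2 target.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.maf_range
    base = rng.uniform(lo, hi, size=config.n_blocks)
    jitter = rng.uniform(-0.02, 0.02, size=config.n_variants)
    return base, jitter


def _ancestry_mafs(config: SimulationConfig, base: np.ndarray,
                   jitter: np.ndarray, rng) -> np.ndarray:
    """Balding-Nichols drift applied at the block level (drift acts on the
    shared haplotype background), preserving within-block similarity."""
    fst = config.fst
    if fst > 0:
        a = base * (1 - fst) / fst
        b = (1 - base) * (1 - fst) / fst
        base = rng.beta(a, b)
    per_variant = np.repeat(base, config.snps_per_block) + jitter
    return np.clip(per_variant, 0.005, 0.995)


def _draw_dosages(config: SimulationConfig, mafs_by_anc: list[np.ndarray],
                  n_per_anc: int, rng) -> np.ndarray:
    """Draw hard-call dosages for all ancestry groups (stacked rows)."""
    m = config.n_variants
    blocks = [np.arange(b * config.snps_per_block, (b + 1) * config.snps_per_block)
              for b in range(config.n_blocks)]
    target_r = np.sqrt(config.block_r2)
    out = []
    for mafs in mafs_by_anc:
        dos = np.empty((n_per_anc, m))
        for cols in blocks:
            p = mafs[cols]
            rho = _solve_latent_rho(target_r, float(np.mean(p))) \
                if len(cols) > 1 else 0.0
            nh = 2 * n_per_anc
            if rho > 0:
                f = rng.standard_normal((nh, 1))
                e = rng.standard_normal((nh, len(cols)))
                z = np.sqrt(rho) * f + np.sqrt(1 - rho) * e
            else:
                z = rng.standard_normal((nh, len(cols)))
            alleles = (z < stats.norm.ppf(p)[None, :]).astype(float)
            dos[:, cols] = alleles[0::2] + alleles[1::2]
        out.append(dos)
    dosages = np.vstack(out)
    if config.dosage_noise_sd > 0:
        dosages = np.clip(
            dosages + rng.normal(0, config.dosage_noise_sd, dosages.shape),
            0.0, 2.0)
    return dosages


def simulate_genotypes(config: SimulationConfig,
                       n_samples: int | None = None,
                       seed: int | None = None) -> GenotypeMatrix:
    """Simulate block-LD genotypes for every ancestry group in ``config``.

    Allele frequencies are derived deterministically from ``config.seed`` so
    that independent draws (study sample, reference panel) share them;
    ``seed`` overrides the seed of the genotype draw only. ``n_samples``
    overrides the per-ancestry count (used for reference panels).
    """
    n = n_samples if n_samples is not None else config.n_samples
    draw_seed = config.seed if seed is None else seed
    base, jitter = _ancestral_mafs(config)
    frq_rng = np.random.default_rng(config.seed + 1)
    mafs_by_anc = [_ancestry_mafs(config, base, jitter, frq_rng)
                   for _ in config.ancestries]
    rng = np.random.default_rng(draw_seed + 2)
    dosages = _draw_dosages(config, mafs_by_anc, n, rng)
    pooled = np.mean(mafs_by_anc, axis=0)
    variants = _variant_records(config, pooled)
    sample_ids = [f"{anc}_{i:05d}" for anc in config.ancestries for i in range(n)]
    ancestry = [anc for anc in config.ancestries for _ in range(n)]
    geno = GenotypeMatrix(dosages, variants, sample_ids, ancestry)
    if config.include_apoe:
        geno = append_apoe_variants(geno, config.apoe_hap_freqs, draw_seed + 3)
    return geno


def simulate_reference_panel(config: SimulationConfig, n_ref: int = 500,
                             seed: int | None = None) -> GenotypeMatrix:
    """Independent draw from the same block model, standing in for an
    external reference population (LD and PRS standardization)."""
    return simulate_genotypes(config, n_samples=n_ref,
                              seed=(config.seed + 7919) if seed is None else seed)


# ---------------------------------------------------------------------------
# APOE-region emulation
# ---------------------------------------------------------------------------

def append_apoe_variants(geno: GenotypeMatrix, hap_freqs: dict,
                         seed: int) -> GenotypeMatrix:
    """Append two variants playing the roles of rs429358 and rs7412.

    Haplotypes are drawn from the epsilon2/3/4 frequencies: epsilon2 carries
    rs429358-T / rs7412-T, epsilon3 T/C, epsilon4 C/C. Dosages count the
    alternate allele (C at rs429358, T at rs7412).
    """
    rng = np.random.default_rng(seed)
    probs = np.array([hap_freqs["e2"], hap_freqs["e3"], hap_freqs["e4"]])
    probs = probs / probs.sum()
    haps = rng.choice(3, size=(geno.n_samples, 2), p=probs)  # 0=e2,1=e3,2=e4
    dos_429358 = np.sum(haps == 2, axis=1).astype(float)     # C allele count
    dos_7412 = np.sum(haps == 0, axis=1).astype(float)       # T allele count
    v1 = VariantRecord("rs429358", "19", 44_908_684, "T", "C")
    v2 = VariantRecord("rs7412", "19", 44_908_822, "C", "T")
    dosages = np.column_stack([geno.dosages, dos_429358, dos_7412])
    return GenotypeMatrix(dosages, geno.variants + [v1, v2],
                          geno.sample_ids, geno.ancestry)


# ---------------------------------------------------------------------------
# Phenotype
# ---------------------------------------------------------------------------

def simulate_phenotype(geno: GenotypeMatrix, config: SimulationConfig,
                       seed: int) -> GroundTruth:
    """Draw case labels from a logistic model on age, sex, and causal dosages.

    The intercept is calibrated by root-finding so that the expected
    prevalence equals ``config.prevalence``; prevalence 0 or 1 short-circuits
    to all-controls / all-cases.
    """
    rng = np.random.default_rng(seed)
    n = geno.n_samples
    age = np.clip(rng.normal(75.0, 7.0, n), 56.0, 89.5)
    sex = rng.integers(0, 2, n).astype(float)
    b_age, b_sex = config.demographic_effects
    eta = b_age * (age - age.mean()) + b_sex * sex
    ids = geno.variant_ids
    true_effects = {}
    for idx, eff in config.causal_snps:
        vid = ids[idx]
        true_effects[vid] = float(eff)
        col = geno.column(vid)
        eta = eta + eff * np.where(np.isnan(col), 2 * geno.allele_freq(vid), col)
    if config.apoe_effect != 0.0 and "rs429358" in geno:
        true_effects["rs429358"] = float(config.apoe_effect)
        eta = eta + config.apoe_effect * geno.column("rs429358")

    if config.prevalence <= 0.0:
        labels = np.zeros(n, dtype=int)
        b0 = -np.inf
    elif config.prevalence >= 1.0:
        labels = np.ones(n, dtype=int)
        b0 = np.inf
    else:
        def mean_prob(b0):
            return np.mean(1.0 / (1.0 + np.exp(-(b0 + eta)))) - config.prevalence
        b0 = float(optimize.brentq(mean_prob, -50, 50))
        labels = (rng.random(n) < 1.0 / (1.0 + np.exp(-(b0 + eta)))).astype(int)

    anc = geno.ancestry if geno.ancestry is not None else ["NA"] * n
    return GroundTruth(set(true_effects), true_effects, labels, list(anc),
                       age, sex, b0)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_summary_stats(geno: GenotypeMatrix, truth: GroundTruth,
                           gwas_n: int, seed: int,
                           phenotype_tag: str = "AD-EUR",
                           gwas_case_fraction: float = 0.5):
    """Per-variant effect estimates with sampling noise appropriate to a
    case-control GWAS of ``gwas_n`` subjects.

    The expected effect at each variant is the *marginal* (LD-convolved)
    effect, sum_c r_jc * beta_c over causal variants c, as a single-SNP GWAS
    regression would estimate — so LD partners of causal SNPs show
    attenuated signals while variants uncorrelated with any causal SNP are
    true nulls with uniform p-values. Sampling noise has
    se_j = 1 / sqrt(2 p_j (1-p_j) * n * phi (1-phi)) with phi the GWAS case
    fraction; p-values are two-sided normal on beta_hat / se.
    """
    from .prioritize import SummaryStats

    if gwas_n <= 0:
        raise ConfigurationError("gwas_n must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    phi = gwas_case_fraction
    causal_cols = {vid: geno.column(vid) for vid in truth.true_effects
                   if vid in geno}
    for v in geno.variants:
        p = geno.allele_freq(v.id)
        p = min(max(p, 1e-4), 1 - 1e-4)
        se = 1.0 / np.sqrt(2 * p * (1 - p) * gwas_n * phi * (1 - phi))
        marginal = 0.0
        x = geno.column(v.id)
        for cid, col in causal_cols.items():
            if cid == v.id:
                marginal += truth.true_effects[cid]
            elif geno.variant(cid).chrom == v.chrom:
                ok = ~np.isnan(x) & ~np.isnan(col)
                if ok.sum() > 2 and np.ptp(x[ok]) > 0 and np.ptp(col[ok]) > 0:
                    r = np.corrcoef(x[ok], col[ok])[0, 1]
                    marginal += r * truth.true_effects[cid]
        beta = marginal + rng.normal(0, se)
        z = beta / se
        pval = min(2 * stats.norm.sf(abs(z)), 1.0)
        pval = max(pval, np.nextafter(0, 1))
        rows.append((v.id, v.chrom, v.pos, v.alt_allele, v.ref_allele,
                     beta, se, pval))
    table = pd.DataFrame(rows, columns=["id", "chrom", "pos", "effect_allele",
                                        "other_allele", "beta", "se", "p"])
    return SummaryStats(table, phenotype_tag)


# ---------------------------------------------------------------------------
# Encounters
# ---------------------------------------------------------------------------

def simulate_encounters(config: SimulationConfig, truth: GroundTruth,
                        seed: int,
                        sample_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Longitudinal encounter histories as a homogeneous Poisson process.

    Cases carry one dementia-coded encounter at an onset age strictly above
    ``config.case_onset_age_min``; all other encounters carry filler codes.
    A ``control_fail_fraction`` of controls is given histories that fail an
    eligibility filter (short span, low rate, or last visit before 70).
    Patients with zero encounters are absent from the output.
    """
    rng = np.random.default_rng(seed)
    n = len(truth.true_case_labels)
    if sample_ids is None:
        sample_ids = [f"{truth.ancestry_label[i]}_{i % n:05d}" for i in range(n)]
    rows = []
    for i in range(n):
        is_case = truth.true_case_labels[i] == 1
        age = float(truth.age[i])
        sex = "F" if truth.sex[i] == 1 else "M"
        mean_span = config.case_mean_span if is_case else config.control_mean_span
        last_age = age
        if is_case:
            # cases must be codeable strictly after the onset floor
            last_age = max(last_age, config.case_onset_age_min + 0.2)
        span = float(np.clip(rng.gamma(4.0, mean_span / 4.0), 0.5,
                             max(0.5, last_age - 1.0)))
        rate = max(rng.gamma(2.0, config.mean_encounter_rate / 2.0), 0.5)
        if not is_case and rng.random() < config.control_fail_fraction:
            mode = rng.integers(0, 3)
            if mode == 0:
                span = float(rng.uniform(0.5, 4.0))          # short span
            elif mode == 1:
                rate = float(rng.uniform(0.1, 0.8))          # low rate
            else:
                last_age = float(rng.uniform(58.0, 69.0))    # last visit < 70
        first_age = max(last_age - span, 1.0)
        n_enc = rng.poisson(rate * (last_age - first_age))
        enc_ages = np.sort(rng.uniform(first_age, last_age, n_enc))
        codes = list(rng.choice(FILLER_CODES, size=n_enc))
        if is_case:
            onset_lo = max(config.case_onset_age_min + 0.1, first_age)
            onset_age = float(rng.uniform(onset_lo, last_age)) \
                if last_age > onset_lo else last_age
            dem_code = str(rng.choice(DEMENTIA_CODES, p=DEMENTIA_CODE_WEIGHTS))
            enc_ages = np.append(enc_ages, onset_age)
            codes.append(dem_code)
        if len(enc_ages) == 0:
            continue
        birth = AS_OF_DATE - pd.to_timedelta(age * 365.25, unit="D")
        for a, code in zip(enc_ages, codes):
            rows.append((sample_ids[i], birth.normalize(), sex,
                         (birth + pd.to_timedelta(a * 365.25, unit="D")).normalize(),
                         code))
    return pd.DataFrame(rows, columns=["patient_id", "birth_date", "sex",
                                       "encounter_date", "icd10_code"])


# ---------------------------------------------------------------------------
# Bundled cohort
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A self-consistent study: genotypes, truth, summary stats, encounters,
    and an independent reference panel."""

    config: SimulationConfig
    genotypes: GenotypeMatrix
    truth: GroundTruth
    summary_stats: object
    encounters: pd.DataFrame
    reference: GenotypeMatrix


def simulate_cohort(config: SimulationConfig, gwas_n: int = 500_000,
                    n_ref: int = 500) -> SyntheticCohort:
    """Generate every input of the pipeline from one configuration."""
    geno = simulate_genotypes(config)
    truth = simulate_phenotype(geno, config, config.seed + 11)
    stats_ = simulate_summary_stats(geno, truth, gwas_n, config.seed + 13)
    enc = simulate_encounters(config, truth, config.seed + 17,
                              sample_ids=geno.sample_ids)
    ref = simulate_reference_panel(config, n_ref=n_ref)
    return SyntheticCohort(config, geno, truth, stats_, enc, ref)
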