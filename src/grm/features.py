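"""Per-individual genetic predictors: polygenic risk scores and APOE-e4 count.

A PRS is the plain weighted sum of risk-allele dosages,
``PRS_i = sum_j beta_j * dosage_ij``, standardized against an external
reference panel so scores are comparable across GWAS sources. The APOE-e4
count derives the epsilon diplotype from the unphased rs429358/rs7412
genotype pair by the standard lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .prioritize import HarmonizationError, SummaryStats


class FeatureError(ValueError):
    pass


@dataclass
class PRSVector:
    scores: np.ndarray
    sample_ids: list
    snp_set_tag: str = ""              # "psig" or "map"
    phenotype_tag: str = ""
    standardization: dict | None = None  # {"ref_mean": m, "ref_sd": s}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "score": self.scores,
                             "snp_set": self.snp_set_tag,
                             "phenotype": self.phenotype_tag})


def _weights(stats: SummaryStats, snp_ids: list[str]) -> np.ndarray:
    table = stats.table.set_index("id")
    missing = [s for s in snp_ids if s not in table.index]
    if missing:
        raise FeatureError(f"SNPs absent from summary stats: {missing[:10]}")
    return table.loc[snp_ids, "beta"].to_numpy(dtype=float)


def compute_prs(geno: GenotypeMatrix, stats: SummaryStats,
                snp_ids: list[str], snp_set_tag: str = "") -> PRSVector:
    """Raw PRS over ``snp_ids``; betas must already be harmonized to the
    genotype alt-allele coding (see :func:`grm.prioritize.harmonize_to_panel`).

    Missing dosages are imputed to twice the allele frequency of the matrix
    before summation.
    """
    missing_g = [s for s in snp_ids if s not in geno]
    if missing_g:
        raise FeatureError(f"SNPs absent from genotypes: {missing_g[:10]}")
    betas = _weights(stats, snp_ids)
    X = np.column_stack([geno.column(s) for s in snp_ids]) \
        if snp_ids else np.zeros((geno.n_samples, 0))
    if X.size:
        af = np.array([geno.allele_freq(s) for s in snp_ids])
        idx = np.where(np.isnan(X))
        X[idx] = 2.0 * np.take(af, idx[1])
    scores = X @ betas if snp_ids else np.zeros(geno.n_samples)
    return PRSVector(scores, list(geno.sample_ids), snp_set_tag,
                     stats.phenotype_tag)


def standardize_prs(raw: PRSVector, reference: GenotypeMatrix,
                    stats: SummaryStats, snp_ids: list[str]) -> PRSVector:
    """Standardize scores to mean 0 / sd 1 of the reference-panel PRS.

    The reference mean and sd are computed by scoring the reference panel
    with the same weights and SNP set, and are recorded on the result.
    """
    if reference.n_samples == 0:
        raise FeatureError("reference panel is empty")
    ref = compute_prs(reference, stats, snp_ids)
    mu = float(np.mean(ref.scores))
    sd = float(np.std(ref.scores, ddof=0))
    if sd == 0:
        raise FeatureError("reference PRS has zero variance")
    return PRSVector((raw.scores - mu) / sd, raw.sample_ids, raw.snp_set_tag,
                     raw.phenotype_tag, {"ref_mean": mu, "ref_sd": sd})


# ---------------------------------------------------------------------------
# APOE
# ---------------------------------------------------------------------------

@dataclass
class ApoeCount:
    counts: np.ndarray                 # e4 alleles per sample, in {0,1,2}
    ambiguous: np.ndarray              # True where e2/e4 vs e1/e3 ambiguity
    sample_ids: list = field(default_factory=list)


# (rs429358 C count, rs7412 T count) -> (e4 count, ambiguous). The double
# heterozygote is resolved to e2/e4 (e1 is vanishingly rare) and flagged.
_APOE_TABLE = {
    (0, 0): (0, False),  # e3/e3
    (0, 1): (0, False),  # e2/e3
    (0, 2): (0, False),  # e2/e2
    (1, 0): (1, False),  # e3/e4
    (1, 1): (1, True),   # e2/e4 (or e1/e3)
    (1, 2): (0, False),  # e1/e2
    (2, 0): (2, False),  # e4/e4
    (2, 1): (1, False),  # e1/e4
    (2, 2): (0, False),  # e1/e1
}


def apoe_e4_count(geno: GenotypeMatrix, rs429358_id: str = "rs429358",
                  rs7412_id: str = "rs7412") -> ApoeCount:
    """Count epsilon4 alleles from the unphased rs429358/rs7412 genotypes.

    Dosages must be hard calls in {0, 1, 2} counting the alternate allele
    (C at rs429358, T at rs7412). Each genotype pair maps to exactly one
    diplotype (two epsilon alleles); the rs429358-het / rs7412-het pair is
    assigned e2/e4 (count 1) with the ambiguity flagged.
    """
    c = geno.column(rs429358_id)
    t = geno.column(rs7412_id)
    both = np.column_stack([c, t])
    if np.isnan(both).any() or not np.all(both == np.round(both)):
        raise FeatureError("APOE counting requires hard-call dosages in {0,1,2}")
    counts = np.empty(len(c), dtype=int)
    amb = np.empty(len(c), dtype=bool)
    for i, (ci, ti) in enumerate(zip(c.astype(int), t.astype(int))):
        counts[i], amb[i] = _APOE_TABLE[(ci, ti)]
    return ApoeCount(counts, amb, list(geno.sample_ids))
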