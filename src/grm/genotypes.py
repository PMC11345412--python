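"""Genotype containers, standard-format I/O, and quality control.

Dosage genotypes (expected alternate-allele counts in [0, 2], possibly
fractional after imputation) are held in a samples x variants matrix with
variant and sample metadata. The QC filters mirror common biobank practice:
sample missingness, variant missingness, monomorphic and strand-ambiguous
variant removal, an imputation-quality cut, and a minor-allele-frequency cut.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class GenotypeError(ValueError):
    """Malformed genotype input or an operation on incompatible variants."""


class UndefinedLDError(GenotypeError):
    """LD requested between variants without dosage variance."""


@dataclass
class VariantRecord:
    """One variant: identifier, position, and allele coding.

    ``id`` is an rsID or a ``chr:pos:ref:alt`` string; ``pos`` is 1-based.
    ``info`` may carry per-variant annotations such as imputation r2
    (key ``"imputation_r2"``).
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.pos < 1:
            raise GenotypeError(f"variant {self.id}: pos must be >= 1")
        if not self.ref_allele or not self.alt_allele:
            raise GenotypeError(f"variant {self.id}: alleles must be nonempty")

    @property
    def key(self) -> str:
        """Canonical chr:pos:ref:alt matching key."""
        return f"{self.chrom}:{self.pos}:{self.ref_allele}:{self.alt_allele}"

    def is_strand_ambiguous(self) -> bool:
        return {self.ref_allele, self.alt_allele} in ({"A", "T"}, {"C", "G"})


def _parse_variant_id(vid: str) -> VariantRecord:
    """Build a VariantRecord from an identifier, decoding chr:pos:ref:alt
    ids; other ids get placeholder coordinates."""
    parts = vid.split(":")
    if len(parts) == 4 and parts[1].isdigit():
        return VariantRecord(vid, parts[0], int(parts[1]), parts[2], parts[3])
    return VariantRecord(vid, "0", 1, "N", "N")


class GenotypeMatrix:
    """Samples x variants dosage matrix with metadata.

    Missing dosages are NaN. Construction validates shape agreement,
    dosage range, and variant-ID uniqueness.
    """

    def __init__(self, dosages: np.ndarray, variants: Sequence[VariantRecord],
                 sample_ids: Sequence[str], ancestry: Sequence[str] | None = None):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise GenotypeError("dosages must be 2-dimensional")
        if dosages.shape[1] != len(variants):
            raise GenotypeError("variant list length must equal column count")
        if dosages.shape[0] != len(sample_ids):
            raise GenotypeError("sample list length must equal row count")
        with np.errstate(invalid="ignore"):
            if np.any((dosages < 0) | (dosages > 2)):
                raise GenotypeError("dosages must lie in [0, 2] or be missing")
        ids = [v.id for v in variants]
        if len(set(ids)) != len(ids):
            raise GenotypeError("variant IDs must be unique")
        self.dosages = dosages
        self.variants = list(variants)
        self.sample_ids = list(sample_ids)
        self.ancestry = list(ancestry) if ancestry is not None else None
        self._index = {vid: j for j, vid in enumerate(ids)}

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._index[variant_id]]
        except KeyError:
            raise GenotypeError(f"variant {variant_id!r} not present") from None

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def variant(self, variant_id: str) -> VariantRecord:
        return self.variants[self._index[variant_id]]

    def allele_freq(self, variant_id: str) -> float:
        """Alternate-allele frequency from non-missing dosages."""
        col = self.column(variant_id)
        return float(np.nanmean(col) / 2.0)

    def subset(self, sample_mask: np.ndarray | None = None,
               variant_mask: np.ndarray | None = None) -> "GenotypeMatrix":
        d = self.dosages
        sids = np.asarray(self.sample_ids, dtype=object)
        anc = np.asarray(self.ancestry, dtype=object) if self.ancestry else None
        variants = self.variants
        if sample_mask is not None:
            d = d[sample_mask, :]
            sids = sids[sample_mask]
            if anc is not None:
                anc = anc[sample_mask]
        if variant_mask is not None:
            d = d[:, variant_mask]
            variants = [v for v, keep in zip(self.variants, variant_mask) if keep]
        return GenotypeMatrix(d, variants, list(sids),
                              list(anc) if anc is not None else None)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_genotypes(geno: GenotypeMatrix, path: str, format: str = "dosage_tsv") -> None:
    """Write to dosage TSV (rows = samples, header = variant IDs) or to VCF
    with the dosage in a DS FORMAT field."""
    if format == "dosage_tsv":
        df = pd.DataFrame(geno.dosages, index=geno.sample_ids,
                          columns=geno.variant_ids)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")
    elif format == "vcf":
        _write_vcf(geno, path)
    else:
        raise GenotypeError(f"unknown genotype format {format!r}")


def read_genotypes(path: str, format: str = "dosage_tsv") -> GenotypeMatrix:
    """Read a dosage TSV or a VCF carrying dosages in the DS FORMAT field.

    Round-trips bit-exactly with :func:`write_genotypes` for dosage TSV.
    Missing genotypes are preserved as NaN.
    """
    if format == "dosage_tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
        except Exception as exc:  # pandas names the offending line
            raise GenotypeError(f"malformed dosage TSV {path}: {exc}") from exc
        variants = [_parse_variant_id(str(c)) for c in df.columns]
        return GenotypeMatrix(df.to_numpy(dtype=float), variants,
                              [str(s) for s in df.index])
    elif format == "vcf":
        return _read_vcf(path)
    raise GenotypeError(f"unknown genotype format {format!r}")


def _write_vcf(geno: GenotypeMatrix, path: str) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">')
    chroms = []
    for v in geno.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    for c in chroms:
        header.contigs.add(c)
    for s in geno.sample_ids:
        header.add_sample(s)
    order = sorted(range(geno.n_variants),
                   key=lambda j: (chroms.index(geno.variants[j].chrom),
                                  geno.variants[j].pos))
    with pysam.VariantFile(path, "w", header=header) as out:
        for j in order:
            v = geno.variants[j]
            rec = out.new_record(contig=v.chrom, start=v.pos - 1,
                                 stop=v.pos - 1 + len(v.ref_allele),
                                 alleles=(v.ref_allele, v.alt_allele), id=v.id)
            for i, s in enumerate(geno.sample_ids):
                d = geno.dosages[i, j]
                rec.samples[s]["DS"] = None if np.isnan(d) else float(d)
            out.write(rec)


def _read_vcf(path: str) -> GenotypeMatrix:
    import pysam

    try:
        vf = pysam.VariantFile(path)
    except Exception as exc:
        raise GenotypeError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    with vf:
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                raise GenotypeError(
                    f"VCF record at {rec.chrom}:{rec.pos} is not biallelic")
            info = {}
            if "R2" in rec.info:
                info["imputation_r2"] = float(rec.info["R2"])
            vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
            variants.append(VariantRecord(vid, rec.chrom, rec.pos, rec.ref,
                                          rec.alts[0], info))
            col = np.full(len(samples), np.nan)
            for i, s in enumerate(samples):
                ds = rec.samples[s].get("DS")
                if ds is not None:
                    col[i] = float(ds)
            cols.append(col)
    if not cols:
        return GenotypeMatrix(np.empty((len(samples), 0)), [], samples)
    return GenotypeMatrix(np.column_stack(cols), variants, samples)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Audit trail of a QC pass: every removed sample/variant appears exactly
    once with its first failing (primary) reason."""

    samples_removed: list[tuple[str, str]] = field(default_factory=list)
    variants_removed: list[tuple[str, str]] = field(default_factory=list)
    thresholds_used: dict = field(default_factory=dict)
    empty_result: bool = False

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump({"samples_removed": self.samples_removed,
                       "variants_removed": self.variants_removed,
                       "thresholds_used": self.thresholds_used,
                       "empty_result": self.empty_result}, fh, indent=2)


def qc_filter(geno: GenotypeMatrix, sample_miss_max: float = 0.05,
              variant_miss_max: float = 0.05, maf_min: float = 0.01,
              drop_monomorphic: bool = True, drop_strand_ambiguous: bool = True,
              imput_r2_min: float = 0.90) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample- and variant-level QC in a fixed order.

    Order: sample missingness -> variant missingness -> monomorphic ->
    strand-ambiguous -> imputation r2 -> MAF. Allele frequencies are computed
    from non-missing dosages after sample removal. The imputation-r2 filter
    applies only to variants whose ``info`` carries an ``imputation_r2`` key.
    An empty post-filter matrix is reported via ``report.empty_result``, not
    an exception.
    """
    for name, thr in [("sample_miss_max", sample_miss_max),
                      ("variant_miss_max", variant_miss_max),
                      ("maf_min", maf_min), ("imput_r2_min", imput_r2_min)]:
        if not 0 <= thr <= 1:
            raise GenotypeError(f"{name} must lie in [0, 1]")
    report = QCReport(thresholds_used={
        "sample_miss_max": sample_miss_max, "variant_miss_max": variant_miss_max,
        "maf_min": maf_min, "drop_monomorphic": drop_monomorphic,
        "drop_strand_ambiguous": drop_strand_ambiguous,
        "imput_r2_min": imput_r2_min})

    d = geno.dosages
    # samples first (PLINK convention)
    if d.shape[1] > 0:
        smiss = np.isnan(d).mean(axis=1)
    else:
        smiss = np.zeros(d.shape[0])
    keep_s = smiss <= sample_miss_max
    for sid, m in zip(geno.sample_ids, smiss):
        if m > sample_miss_max:
            report.samples_removed.append((sid, "sample_missingness"))
    geno = geno.subset(sample_mask=keep_s)
    d = geno.dosages

    n = d.shape[0]
    keep_v = np.ones(geno.n_variants, dtype=bool)

    def drop(j: int, reason: str) -> None:
        keep_v[j] = False
        report.variants_removed.append((geno.variants[j].id, reason))

    for j, v in enumerate(geno.variants):
        col = d[:, j]
        obs = col[~np.isnan(col)]
        miss = 1.0 - len(obs) / n if n else 1.0
        if miss > variant_miss_max:
            drop(j, "variant_missingness")
            continue
        if drop_monomorphic and (len(obs) == 0 or np.all(obs == obs[0])):
            drop(j, "monomorphic")
            continue
        if drop_strand_ambiguous and v.is_strand_ambiguous():
            drop(j, "strand_ambiguous")
            continue
        r2 = v.info.get("imputation_r2")
        if r2 is not None and r2 < imput_r2_min:
            drop(j, "imputation_r2")
            continue
        af = np.mean(obs) / 2.0
        if min(af, 1 - af) < maf_min:
            drop(j, "maf")

    out = geno.subset(variant_mask=keep_v)
    report.empty_result = out.n_samples == 0 or out.n_variants == 0
    return out, report


def ld_r2(geno: GenotypeMatrix, a: str, b: str) -> float:
    """Squared Pearson correlation of two dosage columns over samples
    non-missing at both variants."""
    x, y = geno.column(a), geno.column(b)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedLDError(
            f"LD undefined between {a} and {b}: zero dosage variance")
    r = np.corrcoef(x, y)[0, 1]
    return float(min(r * r, 1.0))


def intersect_variants(a: Iterable[VariantRecord],
                       b: Iterable[VariantRecord]) -> list[str]:
    """IDs of variants (from ``a``) shared between two variant lists, matched
    on the chr:pos:ref:alt key."""
    bkeys = {v.key for v in b}
    return [v.id for v in a if v.key in bkeys]


# ---------------------------------------------------------------------------
# Ancestry PCs
# ---------------------------------------------------------------------------

@dataclass
class PCMatrix:
    """Principal-component scores with explained-variance shares."""

    scores: np.ndarray            # samples x k
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray          # variants x k
    truncated: bool = False       # fewer components than requested

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def ancestry_pcs(geno: GenotypeMatrix, k: int) -> PCMatrix:
    """Top-k PC scores of the column-standardized dosage matrix.

    Missing dosages are mean-imputed per variant; zero-variance columns
    contribute nothing. Components are ordered by decreasing explained
    variance with the sign fixed so the largest-magnitude loading of each
    component is positive. If ``k`` exceeds the matrix rank the available
    components are returned with a warning.
    """
    if k > min(geno.n_samples, geno.n_variants):
        raise GenotypeError("k must not exceed min(n_samples, n_variants)")
    X = geno.dosages.copy()
    mu = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = np.take(mu, idx[1])
    sd = X.std(axis=0, ddof=0)
    X = X - X.mean(axis=0)
    nz = sd > 0
    X[:, nz] /= sd[nz]
    X[:, ~nz] = 0.0

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(S > tol))
    kk = min(k, rank)
    truncated = kk < k
    if truncated:
        warnings.warn(f"requested {k} components but rank is {rank}; "
                      f"returning {kk}", stacklevel=2)
    U, S, Vt = U[:, :kk], S[:kk], Vt[:kk, :]
    # sign convention: largest-|loading| entry positive
    for c in range(kk):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U * S
    total = np.sum(X.var(axis=0, ddof=0)) * X.shape[0]
    evr = (S ** 2) / total if total > 0 else np.zeros(kk)
    return PCMatrix(scores, evr, Vt.T, truncated)
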