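"""Genomic risk loci from GWAS summary statistics and prioritized SNP sets.

Significant variants are clumped greedily into LD-defined risk loci against
a reference dosage panel: the most significant unassigned variant below the
p-value threshold becomes an index SNP and captures every unassigned
same-chromosome variant in LD with it (r2 at or above the threshold),
iterating until no sub-threshold variant remains. Loci whose genomic
intervals fall within a merge window are merged, mirroring common
FUMA-style locus definition. Two SNPs are then prioritized per locus: the
minimum-p lead and the maximum-CADD lead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix


class PrioritizationError(ValueError):
    pass


class MissingLDError(PrioritizationError):
    """Candidate variants absent from the LD reference panel."""


class HarmonizationError(PrioritizationError):
    """Effect/other alleles irreconcilable with the panel coding."""


@dataclass
class SummaryStats:
    """Per-variant GWAS results for one phenotype/ancestry.

    ``table`` columns: id, chrom, pos, effect_allele, other_allele, beta, p
    (optionally se). ``beta`` is the log-odds effect of the effect allele.
    """

    table: pd.DataFrame
    phenotype_tag: str = ""

    def __post_init__(self):
        t = self.table
        required = {"id", "chrom", "pos", "effect_allele", "other_allele",
                    "beta", "p"}
        missing = required - set(t.columns)
        if missing:
            raise PrioritizationError(f"summary stats missing columns {missing}")
        if t["id"].duplicated().any():
            dups = t.loc[t["id"].duplicated(), "id"].tolist()
            raise PrioritizationError(f"duplicate variant ids {dups[:5]}")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise PrioritizationError("p-values must lie in (0, 1]")
        if (t["effect_allele"] == t["other_allele"]).any():
            raise PrioritizationError("effect allele must differ from other allele")
        self.table = t.reset_index(drop=True)

    def beta_of(self, vid: str) -> float:
        row = self.table.loc[self.table["id"] == vid]
        if row.empty:
            raise PrioritizationError(f"variant {vid!r} not in summary stats")
        return float(row["beta"].iloc[0])

    def subset(self, ids) -> "SummaryStats":
        keep = self.table["id"].isin(set(ids))
        return SummaryStats(self.table.loc[keep].copy(), self.phenotype_tag)


def read_summary_stats(path: str, phenotype_tag: str = "",
                       column_map: dict | None = None) -> SummaryStats:
    """Read a tab-separated summary-statistics file.

    ``column_map`` maps file column names to the canonical names
    (id, chrom, pos, effect_allele, other_allele, beta, p).
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    return SummaryStats(df, phenotype_tag)


def write_summary_stats(stats: SummaryStats, path: str) -> None:
    stats.table.to_csv(path, sep="\t", index=False)


@dataclass
class VariantAnnotation:
    """Per-variant CADD deleteriousness scores (and optional nearest gene)."""

    cadd: dict                              # id -> score >= 0
    nearest_gene: dict = field(default_factory=dict)

    def __post_init__(self):
        bad = [k for k, v in self.cadd.items() if v < 0]
        if bad:
            raise PrioritizationError(f"negative CADD scores for {bad[:5]}")


def read_cadd_scores(path: str) -> VariantAnnotation:
    """TSV with columns ``id`` and ``cadd`` (optional ``nearest_gene``)."""
    df = pd.read_csv(path, sep="\t")
    genes = (dict(zip(df["id"], df["nearest_gene"]))
             if "nearest_gene" in df.columns else {})
    return VariantAnnotation(dict(zip(df["id"], df["cadd"].astype(float))), genes)


@dataclass
class Locus:
    """One genomic risk locus: LD-assigned members around index SNP(s)."""

    members: list                   # variant ids
    lead_psig: str                  # minimum-p member
    chrom: str
    start: int
    end: int
    lead_cadd: str | None = None    # filled by independent_cadd_snps


@dataclass
class RiskLocusSet:
    loci: list
    params: dict

    def __len__(self):
        return len(self.loci)

    def member_ids(self) -> set:
        return {m for loc in self.loci for m in loc.members}


def harmonize_to_panel(stats: SummaryStats, panel: GenotypeMatrix,
                       permissive: bool = False) -> SummaryStats:
    """Align effect alleles to the panel's alternate allele, flipping beta.

    Variants whose allele pair does not match the panel's (in either
    orientation) raise a harmonization error; strand-ambiguous variants are
    expected to have been removed upstream. With ``permissive``, variants
    absent from the panel are dropped with a warning instead of erroring.
    """
    t = stats.table.copy()
    keep, betas, eff, oth = [], [], [], []
    dropped = []
    for _, row in t.iterrows():
        vid = row["id"]
        if vid not in panel:
            if permissive:
                dropped.append(vid)
                keep.append(False)
                betas.append(row["beta"])
                eff.append(row["effect_allele"])
                oth.append(row["other_allele"])
                continue
            raise MissingLDError(f"variant {vid!r} absent from panel")
        v = panel.variant(vid)
        if v.ref_allele == "N" or v.alt_allele == "N":
            # panel format carried no allele metadata (e.g. dosage TSV with
            # bare rsIDs): pass through unchanged
            betas.append(row["beta"])
            eff.append(row["effect_allele"])
            oth.append(row["other_allele"])
        elif (row["effect_allele"], row["other_allele"]) == (v.alt_allele, v.ref_allele):
            betas.append(row["beta"])
            eff.append(v.alt_allele)
            oth.append(v.ref_allele)
        elif (row["effect_allele"], row["other_allele"]) == (v.ref_allele, v.alt_allele):
            betas.append(-row["beta"])
            eff.append(v.alt_allele)
            oth.append(v.ref_allele)
        else:
            raise HarmonizationError(
                f"variant {vid!r}: alleles {row['effect_allele']}/"
                f"{row['other_allele']} do not match panel "
                f"{v.alt_allele}/{v.ref_allele}")
        keep.append(True)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} variants absent from panel: "
                      f"{dropped[:5]}...", stacklevel=2)
    t["beta"], t["effect_allele"], t["other_allele"] = betas, eff, oth
    return SummaryStats(t.loc[keep].reset_index(drop=True), stats.phenotype_tag)


def _pairwise_r2(panel: GenotypeMatrix, idx_col: np.ndarray,
                 others: np.ndarray) -> np.ndarray:
    """r2 of one dosage column against many, pairwise-complete."""
    out = np.zeros(others.shape[1])
    x = idx_col
    for j in range(others.shape[1]):
        y = others[:, j]
        ok = ~np.isnan(x) & ~np.isnan(y)
        xs, ys = x[ok], y[ok]
        if len(xs) < 2 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
            out[j] = 0.0
            continue
        r = np.corrcoef(xs, ys)[0, 1]
        out[j] = min(r * r, 1.0)
    return out


def build_risk_loci(stats: SummaryStats, panel: GenotypeMatrix,
                    p_threshold: float = 5e-8, r2_threshold: float = 0.2,
                    merge_window_bp: int | None = 250_000,
                    permissive: bool = False) -> RiskLocusSet:
    """Greedy LD clumping of GWAS-significant variants into risk loci.

    Repeatedly takes the unassigned variant with the smallest p below
    ``p_threshold`` (ties: smaller position, then lexicographic id) as an
    index SNP and assigns every unassigned same-chromosome variant with
    r2 >= ``r2_threshold`` (computed on the reference panel) to its locus.
    Loci whose spans lie within ``merge_window_bp`` on the same chromosome
    are merged afterwards (``None`` skips merging entirely).
    """
    if not (0 < p_threshold <= 1) or not (0 <= r2_threshold <= 1):
        raise PrioritizationError("invalid thresholds")
    t = stats.table
    missing = [vid for vid in t["id"] if vid not in panel]
    if missing:
        if not permissive:
            raise MissingLDError(f"variants absent from panel: {missing[:10]}")
        warnings.warn(f"dropping {len(missing)} variants absent from panel",
                      stacklevel=2)
        t = t.loc[~t["id"].isin(set(missing))].reset_index(drop=True)

    ids = t["id"].to_numpy()
    ps = t["p"].to_numpy(dtype=float)
    pos = t["pos"].to_numpy(dtype=int)
    chrom = t["chrom"].astype(str).to_numpy()
    unassigned = np.ones(len(t), dtype=bool)
    loci: list[Locus] = []

    while True:
        cand = np.where(unassigned & (ps < p_threshold))[0]
        if len(cand) == 0:
            break
        # min p, ties -> smaller pos, then id
        order = sorted(cand, key=lambda i: (ps[i], pos[i], ids[i]))
        i0 = order[0]
        same_chr = np.where(unassigned & (chrom == chrom[i0]))[0]
        idx_col = panel.column(ids[i0])
        others = np.column_stack([panel.column(ids[j]) for j in same_chr])
        r2 = _pairwise_r2(panel, idx_col, others)
        members = [int(j) for j, r in zip(same_chr, r2)
                   if r >= r2_threshold or j == i0]
        unassigned[members] = False
        member_ids = [ids[j] for j in members]
        loci.append(Locus(member_ids, ids[i0], chrom[i0],
                          int(min(pos[j] for j in members)),
                          int(max(pos[j] for j in members))))

    if merge_window_bp is not None and loci:
        loci = _merge_loci(loci, ps, ids, pos, merge_window_bp)
    else:
        loci.sort(key=lambda l: (_chrom_key(l.chrom), l.start))
    return RiskLocusSet(loci, {"p_threshold": p_threshold,
                               "r2_threshold": r2_threshold,
                               "merge_window_bp": merge_window_bp})


def _merge_loci(loci: list[Locus], ps: np.ndarray, ids: np.ndarray,
                pos: np.ndarray, merge_window_bp: int) -> list[Locus]:
    pmap = {vid: (float(p), int(x)) for vid, p, x in zip(ids, ps, pos)}
    by_chr: dict[str, list[Locus]] = {}
    for loc in loci:
        by_chr.setdefault(loc.chrom, []).append(loc)
    merged: list[Locus] = []
    for chrom, group in by_chr.items():
        group.sort(key=lambda l: l.start)
        cur = group[0]
        for nxt in group[1:]:
            if nxt.start - cur.end <= merge_window_bp:
                members = cur.members + nxt.members
                lead = min(members,
                           key=lambda v: (pmap[v][0], pmap[v][1], v))
                cur = Locus(members, lead, chrom, cur.start,
                            max(cur.end, nxt.end))
            else:
                merged.append(cur)
                cur = nxt
        merged.append(cur)
    merged.sort(key=lambda l: (_chrom_key(l.chrom), l.start))
    return merged


def _chrom_key(c: str):
    return (0, int(c)) if str(c).isdigit() else (1, str(c))


def independent_psig_snps(loci: RiskLocusSet) -> list[str]:
    """The minimum-p lead of each locus, sorted by chromosome and position.

    Requires a nonempty locus set.
    """
    if len(loci) == 0:
        raise PrioritizationError("empty locus set")
    leads = [(loc.chrom, loc.start, loc.lead_psig) for loc in loci.loci]
    leads.sort(key=lambda t: (_chrom_key(t[0]), t[1]))
    return [l[2] for l in leads]


def independent_cadd_snps(loci: RiskLocusSet, annot: VariantAnnotation,
                          stats: SummaryStats | None = None) -> list[str]:
    """The maximum-CADD member of each locus (ties: smaller p, then position).

    Every member must be annotated; the chosen lead is recorded on each
    locus as ``lead_cadd``. ``stats`` supplies p-values for tie-breaking; if
    omitted, ties break on position then id.
    """
    if len(loci) == 0:
        raise PrioritizationError("empty locus set")
    unannot = sorted(loci.member_ids() - set(annot.cadd))
    if unannot:
        raise PrioritizationError(f"unannotated locus members: {unannot[:10]}")
    pmap, posmap = {}, {}
    if stats is not None:
        pmap = dict(zip(stats.table["id"], stats.table["p"]))
        posmap = dict(zip(stats.table["id"], stats.table["pos"]))
    out = []
    for loc in sorted(loci.loci, key=lambda l: (_chrom_key(l.chrom), l.start)):
        lead = min(loc.members,
                   key=lambda v: (-annot.cadd[v], pmap.get(v, 1.0),
                                  posmap.get(v, 0), v))
        loc.lead_cadd = lead
        out.append(lead)
    return out


def pool_multi_gwas(snp_lists: list[tuple[str, list[str]]]) -> list[tuple[str, set]]:
    """Union of prioritized SNP lists with per-GWAS provenance tags.

    Duplicates are collapsed; all source tags are retained. Order follows
    first appearance.
    """
    seen: dict[str, set] = {}
    order: list[str] = []
    for tag, ids in snp_lists:
        for vid in ids:
            if vid not in seen:
                seen[vid] = set()
                order.append(vid)
            seen[vid].add(tag)
    return [(vid, seen[vid]) for vid in order]
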