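"""Positional SNP-to-gene mapping and hypergeometric gene-set enrichment.

Retained risk SNPs are assigned to genes positionally: a SNP inside a gene
interval maps to that gene; otherwise to the nearest gene within a distance
cutoff (all tied genes reported). Mapped genes are tested against GMT gene
sets with the upper-tail hypergeometric test and Benjamini-Hochberg
correction. eQTL and chromatin-interaction mapping tiers are deliberately
absent: they require external resources, so the mapping corresponds to a
"nearest gene" column only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .genotypes import VariantRecord


class AnnotationError(ValueError):
    pass


@dataclass
class GeneAnnotation:
    """Gene intervals, 1-based inclusive, symbols unique per chromosome."""

    table: pd.DataFrame       # gene, chrom, start, end, strand

    def __post_init__(self):
        t = self.table
        need = {"gene", "chrom", "start", "end"}
        if need - set(t.columns):
            raise AnnotationError(f"annotation missing columns {need - set(t.columns)}")
        if (t["start"] > t["end"]).any():
            raise AnnotationError("gene intervals must have start <= end")
        if t.duplicated(["chrom", "gene"]).any():
            raise AnnotationError("gene symbols must be unique per chromosome")
        if "strand" not in t.columns:
            t = t.assign(strand="+")
        self.table = t.reset_index(drop=True)

    @property
    def genes(self) -> set:
        return set(self.table["gene"])


def read_gene_annotation(path: str, format: str = "bed") -> GeneAnnotation:
    """Read gene intervals from BED (0-based half-open, converted to 1-based
    inclusive) or TSV with columns gene/chrom/start/end[/strand]."""
    if format == "bed":
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df = df.iloc[:, :6]
        df.columns = ["chrom", "start", "end", "gene", "score", "strand"][:df.shape[1]]
        df["start"] = df["start"].astype(int) + 1       # BED -> 1-based
        df["end"] = df["end"].astype(int)
        if "strand" not in df.columns:
            df["strand"] = "+"
        return GeneAnnotation(df[["gene", "chrom", "start", "end", "strand"]])
    if format == "tsv":
        return GeneAnnotation(pd.read_csv(path, sep="\t"))
    raise AnnotationError(f"unknown annotation format {format!r}")


def read_gmt(path: str) -> dict:
    """GMT gene sets: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def map_snps_to_genes(snps: list[VariantRecord], annot: GeneAnnotation,
                      max_distance: int = 10_000) -> dict:
    """Positional SNP-to-gene map.

    A SNP inside a gene interval maps to that gene (all containing genes);
    otherwise to the nearest gene(s) within ``max_distance`` bp of an
    interval edge, reporting all ties. SNPs beyond the cutoff, or on
    chromosomes absent from the annotation, map to an empty list (the
    latter with a warning). Invariant to gene record order.
    """
    if annot.table.empty:
        raise AnnotationError("gene annotation is empty")
    by_chr = {c: g for c, g in annot.table.groupby("chrom")}
    out = {}
    for snp in snps:
        genes = by_chr.get(str(snp.chrom))
        if genes is None:
            warnings.warn(f"chromosome {snp.chrom!r} absent from annotation "
                          f"({snp.id} unmapped)", stacklevel=2)
            out[snp.id] = []
            continue
        start = genes["start"].to_numpy()
        end = genes["end"].to_numpy()
        names = genes["gene"].to_numpy()
        inside = (start <= snp.pos) & (snp.pos <= end)
        if inside.any():
            out[snp.id] = sorted(names[inside])
            continue
        dist = np.maximum(start - snp.pos, snp.pos - end)
        dmin = dist.min()
        if dmin <= max_distance:
            out[snp.id] = sorted(names[dist == dmin])
        else:
            out[snp.id] = []
    return out


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    results: pd.DataFrame   # set_name, k, K, n, N, p, p_adj


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise AnnotationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(mapped_genes: set, gene_sets: dict,
                     background: set) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of mapped genes in each set.

    With N background genes, K of them in the set, and n mapped genes of
    which k fall in the set, p = P(X >= k) for X hypergeometric(N, K, n).
    BH correction is applied across all tested sets.
    """
    if not background:
        raise AnnotationError("background gene set is empty")
    if not mapped_genes <= background:
        raise AnnotationError("mapped genes must be a subset of the background")
    N = len(background)
    n = len(mapped_genes)
    rows = []
    for name, members in gene_sets.items():
        inset = members & background
        K = len(inset)
        k = len(mapped_genes & inset)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((name, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    df["p_adj"] = bh_adjust(df["p"]) if len(df) else []
    return EnrichmentResult(df)
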