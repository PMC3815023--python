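"""Divergently paired gene (DPG) detection from gene coordinates.

A DPG pair is two adjacent genes on opposite strands whose transcription
start sites (TSSs) lie within 1 kb of each other, the head-to-head
arrangement in which both genes typically share a bidirectional promoter.

Coordinates are 0-based, half-open (BED convention).  The TSS of a
plus-strand gene is its ``start``; the TSS of a minus-strand gene is
``end - 1`` (the last base of the half-open interval).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneModel",
    "DpgPair",
    "gene_table",
    "tss_distance",
    "find_dpgs",
    "count_distance_classes",
    "chromosome_enrichment",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene: id, chromosome, strand, and 0-based half-open coordinates."""

    gene_id: str
    chromosome: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end ({self.start} >= {self.end})")

    @property
    def tss(self) -> int:
        """Transcription start site: start on '+', end-1 on '-'."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class DpgPair:
    """An ordered head-to-head pair: minus-strand gene, plus-strand gene.

    ``tss_distance`` is ``tss(plus) - tss(minus)``: positive when the two
    TSSs diverge without overlap, negative when the 5' regions overlap.
    """

    minus_gene: str
    plus_gene: str
    chromosome: str
    tss_distance: int

    @property
    def distance_class(self) -> str:
        return "positive" if self.tss_distance > 0 else "negative"

    @property
    def genes(self) -> tuple[str, str]:
        return (self.minus_gene, self.plus_gene)


def gene_table(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Tabulate genes as a DataFrame (gene_id, chromosome, strand, start, end, tss)."""
    rows = [
        (g.gene_id, g.chromosome, g.strand, g.start, g.end, g.tss)
        for g in genes
    ]
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "strand", "start", "end", "tss"])


def tss_distance(minus_gene: GeneModel, plus_gene: GeneModel) -> int:
    """Signed TSS distance of a head-to-head candidate pair.

    Returns ``tss(plus) - tss(minus)``.  Raises if the genes are on
    different chromosomes or the strands are not (-, +) in that order.
    """
    if minus_gene.chromosome != plus_gene.chromosome:
        raise ValueError("genes on different chromosomes have no TSS distance")
    if minus_gene.strand != "-" or plus_gene.strand != "+":
        raise ValueError("tss_distance expects (minus-strand gene, plus-strand gene)")
    return plus_gene.tss - minus_gene.tss


def find_dpgs(
    genes: Iterable[GeneModel],
    window: int = 1000,
    require_adjacent: bool = True,
) -> list[DpgPair]:
    """Call divergently paired genes from a gene table.

    A candidate pair is an opposite-strand gene pair on one chromosome with
    signed TSS distance strictly inside ``(-window, 0) or (0, window)``
    (distance 0 is excluded).  With ``require_adjacent`` (default) the two
    TSSs must also be adjacent in TSS order: no third gene's TSS strictly
    between them.

    Each gene joins at most one pair.  When a gene has several candidate
    partners, the partner with the smallest ``|tss_distance|`` wins; ties
    break by lexicographic gene id.  Candidates are committed greedily in
    that global order, so the output is independent of input row order.
    """
    genes = list(genes)
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate gene ids: {dupes}")

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)

    candidates: list[tuple[int, str, str, GeneModel, GeneModel]] = []
    for chrom, chrom_genes in by_chrom.items():
        order = sorted(chrom_genes, key=lambda g: (g.tss, g.gene_id))
        tss_sorted = [g.tss for g in order]
        for i, a in enumerate(order):
            for j in range(i + 1, len(order)):
                b = order[j]
                if b.tss - a.tss >= window:
                    break
                if a.strand == b.strand:
                    continue
                minus, plus = (a, b) if a.strand == "-" else (b, a)
                d = plus.tss - minus.tss
                if d == 0 or abs(d) >= window:
                    continue
                if require_adjacent:
                    lo, hi = min(a.tss, b.tss), max(a.tss, b.tss)
                    k = bisect.bisect_right(tss_sorted, lo)
                    # any gene with TSS strictly inside (lo, hi)?
                    if k < len(tss_sorted) and tss_sorted[k] < hi:
                        continue
                key = tuple(sorted((minus.gene_id, plus.gene_id)))
                candidates.append((abs(d), key[0], key[1], minus, plus))

    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used: set[str] = set()
    pairs: list[DpgPair] = []
    for _, _, _, minus, plus in candidates:
        if minus.gene_id in used or plus.gene_id in used:
            continue
        used.add(minus.gene_id)
        used.add(plus.gene_id)
        pairs.append(
            DpgPair(minus.gene_id, plus.gene_id, minus.chromosome, plus.tss - minus.tss)
        )
    pairs.sort(key=lambda p: (p.chromosome, p.minus_gene, p.plus_gene))
    return pairs


def count_distance_classes(pairs: Iterable[DpgPair]) -> dict[str, int]:
    """Count pairs with positive vs negative signed TSS distance."""
    out = {"positive": 0, "negative": 0}
    for p in pairs:
        out[p.distance_class] += 1
    return out


def chromosome_enrichment(
    genes: Iterable[GeneModel],
    dpg_genes: Iterable[str],
    chromosomes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-chromosome hypergeometric enrichment of DPG genes.

    For each chromosome the null draws ``n_genes(chrom)`` genes from the
    genome-wide pool and asks how surprising the observed DPG-gene count
    is.  The smaller of the two tails (over- vs under-representation) is
    reported with its direction, plus Benjamini-Hochberg adjusted values.
    Chromosome gene counts are the density normalizer; chromosome length
    is not modeled.
    """
    genes = list(genes)
    dpg_set = set(dpg_genes)
    known = {g.gene_id for g in genes}
    missing = dpg_set - known
    if missing:
        raise ValueError(f"dpg genes absent from the gene table: {sorted(missing)[:5]}")

    total = len(genes)
    total_dpg = len(dpg_set)
    rows = []
    chroms = sorted({g.chromosome for g in genes} | set(chromosomes or ()))
    for chrom in chroms:
        on_chrom = [g for g in genes if g.chromosome == chrom]
        n = len(on_chrom)
        k = sum(1 for g in on_chrom if g.gene_id in dpg_set)
        if n == 0:
            rows.append((chrom, 0, 0, 1.0, "none"))
            continue
        rv = hypergeom(total, total_dpg, n)
        p_over = float(rv.sf(k - 1))
        p_under = float(rv.cdf(k))
        if p_over < p_under:
            p, direction = p_over, "over"
        elif p_under < p_over:
            p, direction = p_under, "under"
        else:
            p, direction = p_over, "none"
        rows.append((chrom, n, k, min(p, 1.0), direction))

    df = pd.DataFrame(
        rows, columns=["chromosome", "n_genes", "n_dpg_genes", "p_value", "enrichment_direction"]
    )
    df["p_adjusted"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    return df
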