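"""Classify SVs against gene models and compute genome-fraction statistics.

Each SV receives exactly one primary category with precedence
CDS > intron > upstream > downstream > intergenic:

* ``CDS_full``    — the SV span contains the entire CDS extent of >=1 gene
* ``CDS_partial`` — the SV overlaps >=1 CDS base but no full CDS extent
* ``intron``      — overlaps an intron but no CDS
* ``upstream``    — within ``window`` bp 5' of a TSS (strand-aware)
* ``downstream``  — within ``window`` bp 3' of a TES (strand-aware)
* ``intergenic``  — none of the above

An insertion is treated as a 1-bp point at its insertion site.  An SV touching
features of several genes takes the highest-precedence feature overall but
lists every touched gene, so SV counts and gene counts are tallied separately
(genes may recur across categories; SVs may not).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gffutils
import pandas as pd

from .sv_io import SVRecord

CATEGORIES = ["CDS_full", "CDS_partial", "intron", "upstream", "downstream", "intergenic"]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: strand, transcription boundaries and CDS/intron
    structure.  All intervals are 0-based half-open and sorted."""

    gene_id: str
    chrom: str
    strand: str
    start0: int
    end0: int
    cds_intervals: tuple[tuple[int, int], ...]
    intron_intervals: tuple[tuple[int, int], ...]

    @property
    def tss0(self) -> int:
        """Transcription start site (0-based position of the first base)."""
        return self.start0 if self.strand == "+" else self.end0 - 1

    @property
    def tes0(self) -> int:
        """Transcription end site."""
        return self.end0 - 1 if self.strand == "+" else self.start0

    @property
    def cds_extent(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]


def introns_from_cds(cds: Sequence[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Gaps between consecutive CDS intervals."""
    cds = sorted(cds)
    return tuple(
        (cds[i][1], cds[i + 1][0]) for i in range(len(cds) - 1) if cds[i + 1][0] > cds[i][1]
    )


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 (gene rows with CDS children)."""
    genes: dict[str, dict] = {}
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype == "gene":
            gid = feat.attributes["ID"][0]
            genes[gid] = {
                "chrom": feat.seqid, "strand": feat.strand,
                "start0": feat.start - 1, "end0": feat.end, "cds": [],
            }
        elif feat.featuretype == "CDS":
            parent = feat.attributes["Parent"][0]
            genes[parent]["cds"].append((feat.start - 1, feat.end))
    models = []
    for gid, g in genes.items():
        cds = tuple(sorted(g["cds"]))
        models.append(
            GeneModel(
                gene_id=gid, chrom=g["chrom"], strand=g["strand"],
                start0=g["start0"], end0=g["end0"],
                cds_intervals=cds, intron_intervals=introns_from_cds(cds),
            )
        )
    models.sort(key=lambda m: (m.chrom, m.start0))
    return models


def write_gff3(path: str | Path, genes: Sequence[GeneModel]) -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda m: (m.chrom, m.start0)):
            fh.write(
                f"{g.chrom}\tpeachsv\tgene\t{g.start0 + 1}\t{g.end0}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
            for s, e in g.cds_intervals:
                fh.write(
                    f"{g.chrom}\tpeachsv\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                    f"Parent={g.gene_id}\n"
                )


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return a0 < b1 and b0 < a1


def classify_sv(
    sv: SVRecord, genes: Sequence[GeneModel], window: int = 1000
) -> tuple[str, list[str]]:
    """Assign the primary category and the list of genes whose
    assigned-category feature the SV touches."""
    s, e = sv.start0, sv.end0
    hits: dict[str, list[str]] = {c: [] for c in CATEGORIES}
    for g in genes:
        if g.chrom != sv.chrom:
            continue
        if g.cds_intervals:
            ce0, ce1 = g.cds_extent
            if s <= ce0 and e >= ce1:
                hits["CDS_full"].append(g.gene_id)
                continue
            if any(_overlaps(s, e, c0, c1) for c0, c1 in g.cds_intervals):
                hits["CDS_partial"].append(g.gene_id)
                continue
        if any(_overlaps(s, e, i0, i1) for i0, i1 in g.intron_intervals):
            hits["intron"].append(g.gene_id)
            continue
        if g.strand == "+":
            up = (g.start0 - window, g.start0)
            down = (g.end0, g.end0 + window)
        else:
            up = (g.end0, g.end0 + window)
            down = (g.start0 - window, g.start0)
        if _overlaps(s, e, *up):
            hits["upstream"].append(g.gene_id)
            continue
        if _overlaps(s, e, *down):
            hits["downstream"].append(g.gene_id)
    for cat in CATEGORIES[:-1]:
        if hits[cat]:
            return cat, sorted(hits[cat])
    return "intergenic", []


@dataclass
class AnnotationResult:
    """Per-SV primary categories, touched genes, and the category count table
    (SV counts and distinct-gene counts per svtype)."""

    categories: pd.Series        # index: sv id -> category
    genes_hit: dict[str, list[str]]
    table: pd.DataFrame          # rows: category, cols: svtype + Total, sv counts
    gene_table: pd.DataFrame     # same layout, distinct gene counts


def annotation_table(
    svs: Sequence[SVRecord], genes: Sequence[GeneModel], window: int = 1000
) -> AnnotationResult:
    svtypes = ["DEL", "INS", "DUP", "INV"]
    counts = pd.DataFrame(0, index=CATEGORIES, columns=svtypes + ["Total"])
    gene_sets: dict[str, dict[str, set]] = {
        c: {t: set() for t in svtypes + ["Total"]} for c in CATEGORIES
    }
    cats, gene_hits = {}, {}
    for sv in svs:
        cat, glist = classify_sv(sv, genes, window=window)
        cats[sv.id] = cat
        gene_hits[sv.id] = glist
        counts.loc[cat, sv.svtype] += 1
        counts.loc[cat, "Total"] += 1
        gene_sets[cat][sv.svtype].update(glist)
        gene_sets[cat]["Total"].update(glist)
    gene_counts = pd.DataFrame(
        {t: [len(gene_sets[c][t]) for c in CATEGORIES] for t in svtypes + ["Total"]},
        index=CATEGORIES,
    )
    return AnnotationResult(
        categories=pd.Series(cats, dtype=object),
        genes_hit=gene_hits,
        table=counts,
        gene_table=gene_counts,
    )


def merge_intervals(intervals: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 0-based half-open intervals."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def genome_fraction(
    svs: Sequence[SVRecord], genome_size: int, mode: str = "sum"
) -> float:
    """Percentage of the genome occupied by SVs.

    ``sum`` adds svlen over records (insertions contribute their inserted
    length); ``union`` measures the merged reference span (insertions
    contribute zero span).
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    if mode == "sum":
        total = sum(sv.svlen for sv in svs)
    elif mode == "union":
        total = 0
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for sv in svs:
            if sv.svtype != "INS":
                by_chrom.setdefault(sv.chrom, []).append((sv.start0, sv.end0))
        for ivs in by_chrom.values():
            total += sum(e - s for s, e in merge_intervals(ivs))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return 100.0 * total / genome_size


def gene_overlap_fraction(
    svs: Sequence[SVRecord], genes: Sequence[GeneModel], n_genes_total: int
) -> float:
    """Percentage of annotated genes touched by >=1 bp of any SV (any genic
    feature, introns included; gene body = transcription span)."""
    if n_genes_total <= 0:
        raise ValueError("n_genes_total must be positive")
    touched: set[str] = set()
    by_chrom: dict[str, list[SVRecord]] = {}
    for sv in svs:
        by_chrom.setdefault(sv.chrom, []).append(sv)
    for g in genes:
        for sv in by_chrom.get(g.chrom, []):
            if _overlaps(sv.start0, sv.end0, g.start0, g.end0):
                touched.add(g.gene_id)
                break
    return 100.0 * len(touched) / n_genes_total
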