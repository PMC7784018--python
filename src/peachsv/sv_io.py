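"""Reading, writing, normalising and merging SV call sets and genotype matrices.

Coordinate conventions
----------------------
Externally, VCF and GFF3 are 1-based inclusive and BED is 0-based half-open.
:class:`SVRecord` stores the VCF convention (``start`` = first affected base,
1-based; ``end`` inclusive; insertions have ``end == start``), and exposes
``start0``/``end0`` properties giving the 0-based half-open interval used by
every internal overlap computation.  All conversions happen at the format
boundary and nowhere else.

Genotypes are stored as alt-allele dosages in ``{0, 1, 2}`` with ``-1`` for a
missing call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

SV_TYPES = ("DEL", "INS", "DUP", "INV")

MISSING = -1


class SVFormatError(ValueError):
    """A malformed SV record (missing SVTYPE/END, inconsistent coordinates)."""


@dataclass(frozen=True)
class SVRecord:
    """One structural variant.

    ``svlen`` is the absolute event length: span length for DEL/DUP/INV and
    inserted-sequence length for INS.
    """

    id: str
    chrom: str
    start: int  # 1-based first affected base
    end: int    # 1-based inclusive; == start for INS
    svtype: str
    svlen: int

    def __post_init__(self) -> None:
        if self.svtype not in SV_TYPES:
            raise SVFormatError(f"{self.id}: unknown SVTYPE {self.svtype!r}")
        if self.end < self.start:
            raise SVFormatError(f"{self.id}: end {self.end} < start {self.start}")
        if self.svlen <= 0:
            raise SVFormatError(f"{self.id}: non-positive SVLEN {self.svlen}")
        if self.svtype != "INS" and self.svlen != self.end - self.start + 1:
            raise SVFormatError(
                f"{self.id}: SVLEN {self.svlen} != span {self.end - self.start + 1}"
            )

    @property
    def start0(self) -> int:
        """0-based half-open interval start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open interval end (insertion point + 1 for INS)."""
        return self.end if self.svtype != "INS" else self.start

    @property
    def span(self) -> int:
        """Reference bases occupied (0 reference span is impossible here; an
        insertion occupies its 1-bp anchor point)."""
        return self.end0 - self.start0

    @property
    def midpoint0(self) -> int:
        """0-based midpoint, the anchor used for hotspot counting and
        Manhattan positions."""
        return (self.start0 + self.end0) // 2


@dataclass
class GenotypeMatrix:
    """Markers x samples alt-allele dosage matrix with sample metadata."""

    markers: list[str]
    samples: list[str]
    dosage: np.ndarray  # int8, markers x samples, -1 missing
    population: np.ndarray = field(default=None)  # type: ignore[assignment]
    phenotype: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.markers), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.markers)}, {len(self.samples)})"
            )
        if self.population is None:
            self.population = np.array(["NA"] * len(self.samples), dtype=object)
        else:
            self.population = np.asarray(self.population, dtype=object)
        if self.phenotype is None:
            self.phenotype = np.array(["NA"] * len(self.samples), dtype=object)
        else:
            self.phenotype = np.asarray(self.phenotype, dtype=object)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, names: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[n] for n in names], dtype=int)

    def marker_index(self, names: Iterable[str]) -> np.ndarray:
        pos = {m: i for i, m in enumerate(self.markers)}
        return np.array([pos[n] for n in names], dtype=int)

    def subset_samples(self, names: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_index(names)
        return GenotypeMatrix(
            markers=list(self.markers),
            samples=list(names),
            dosage=self.dosage[:, idx].copy(),
            population=self.population[idx].copy(),
            phenotype=self.phenotype[idx].copy(),
        )

    def attach_metadata(self, sheet: pd.DataFrame) -> None:
        """Attach population/phenotype labels from a sample sheet
        (columns: sample, population, phenotype)."""
        meta = sheet.set_index("sample")
        self.population = np.array(
            [meta.loc[s, "population"] for s in self.samples], dtype=object
        )
        self.phenotype = np.array(
            [meta.loc[s, "phenotype"] for s in self.samples], dtype=object
        )


def _gt_to_dosage(gt_type: int) -> int:
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    return {0: 0, 1: 1, 3: 2, 2: MISSING}[gt_type]


def read_sv_vcf(path: str | Path, min_size: int = 30) -> tuple[list[SVRecord], GenotypeMatrix]:
    """Read an SV VCF into records and a dosage matrix.

    Records with ``svlen <= min_size`` are dropped (the >30 bp map rule);
    BND records are rejected; records of unknown type are logged and skipped.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    records: list[SVRecord] = []
    rows: list[np.ndarray] = []
    for i, v in enumerate(vcf):
        svtype = v.INFO.get("SVTYPE")
        if svtype is None:
            raise SVFormatError(f"{path}: record {i + 1} ({v.CHROM}:{v.POS}) lacks SVTYPE")
        if svtype == "BND":
            raise SVFormatError(
                f"{path}: record {i + 1} ({v.CHROM}:{v.POS}) is a breakend (BND); "
                "breakend records are not supported"
            )
        if svtype not in SV_TYPES:
            log.warning("%s: record %d has unknown SVTYPE %r; skipped", path, i + 1, svtype)
            continue
        end = v.INFO.get("END")
        if end is None and svtype != "INS":
            raise SVFormatError(f"{path}: record {i + 1} ({v.CHROM}:{v.POS}) lacks END")
        svlen = v.INFO.get("SVLEN")
        if svlen is None:
            if svtype == "INS":
                raise SVFormatError(f"{path}: INS record {i + 1} lacks SVLEN")
            svlen = int(end) - v.POS + 1
        svlen = abs(int(svlen))
        if svlen <= min_size:
            continue
        rec = SVRecord(
            id=v.ID or f"sv{i + 1}",
            chrom=v.CHROM,
            start=v.POS,
            end=int(end) if svtype != "INS" else v.POS,
            svtype=svtype,
            svlen=svlen,
        )
        records.append(rec)
        rows.append(np.array([_gt_to_dosage(t) for t in v.gt_types], dtype=np.int8))
    dosage = (
        np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    )
    matrix = GenotypeMatrix(
        markers=[r.id for r in records], samples=samples, dosage=dosage
    )
    return records, matrix


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Absolute SV length">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _dosage_to_gt(d: int) -> str:
    return {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}[int(d)]


def write_sv_vcf(
    path: str | Path,
    records: Sequence[SVRecord],
    matrix: GenotypeMatrix | None = None,
    contigs: Sequence[tuple[str, int]] | None = None,
) -> None:
    """Write SV records (optionally with genotypes) as VCF 4.2 text."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in contigs or []:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        samples = matrix.samples if matrix is not None else []
        if samples:
            cols += ["FORMAT"] + list(samples)
        fh.write("\t".join(cols) + "\n")
        for i, r in enumerate(records):
            info = f"SVTYPE={r.svtype};END={r.end};SVLEN={r.svlen}"
            row = [r.chrom, str(r.start), r.id, "N", f"<{r.svtype}>", ".", "PASS", info]
            if samples:
                row.append("GT")
                row += [_dosage_to_gt(d) for d in matrix.dosage[i]]
            fh.write("\t".join(row) + "\n")


def write_snp_vcf(
    path: str | Path,
    chroms: Sequence[str],
    positions: Sequence[int],
    ids: Sequence[str],
    ref: Sequence[str],
    alt: Sequence[str],
    matrix: GenotypeMatrix,
    contigs: Sequence[tuple[str, int]] | None = None,
) -> None:
    """Write biallelic SNPs with genotypes as VCF 4.2 text."""
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in contigs or []:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "\t".join(
                ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
                + list(matrix.samples)
            )
            + "\n"
        )
        for i in range(len(ids)):
            row = [
                chroms[i], str(positions[i]), ids[i], ref[i], alt[i], ".", "PASS", ".", "GT",
            ] + [_dosage_to_gt(d) for d in matrix.dosage[i]]
            fh.write("\t".join(row) + "\n")


def read_snp_vcf(path: str | Path) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Read a biallelic SNP VCF into a site table and dosage matrix."""
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    sites, rows = [], []
    for v in vcf:
        sites.append((v.CHROM, v.POS, v.ID, v.REF, v.ALT[0]))
        rows.append(np.array([_gt_to_dosage(t) for t in v.gt_types], dtype=np.int8))
    table = pd.DataFrame(sites, columns=["chrom", "pos", "id", "ref", "alt"])
    dosage = np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    return table, GenotypeMatrix(markers=list(table["id"]), samples=samples, dosage=dosage)


# --- BED / sample-sheet helpers ------------------------------------------------

def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED track (0-based half-open) into a DataFrame."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_bed(path: str | Path, intervals: Iterable[tuple], extra: bool = True) -> None:
    """Write (chrom, start, end[, ...]) tuples as BED (0-based half-open)."""
    with Path(path).open("w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    # "NA" is a meaningful phenotype level (outgroup), not a missing value
    return pd.read_csv(path, sep="\t", dtype={"sample": str}, keep_default_na=False)


# --- merging -------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_callsets(
    callsets: Sequence[Sequence[SVRecord]],
    max_dist: int = 1000,
    require_same_type: bool = True,
) -> list[tuple[SVRecord, int]]:
    """Single-linkage merge of SV call sets.

    Two records link when their starts and ends are each within ``max_dist``
    (and, by default, when they share svtype).  One representative per cluster:
    lowest start, ties broken by longest svlen.  Returns (representative,
    support) pairs where support is the number of distinct contributing call
    sets, sorted by position.
    """
    flat: list[SVRecord] = []
    origin: list[int] = []
    for k, cs in enumerate(callsets):
        for r in cs:
            flat.append(r)
            origin.append(k)
    if not flat:
        return []
    order = sorted(range(len(flat)), key=lambda i: (flat[i].chrom, flat[i].start))
    uf = _UnionFind(len(flat))
    for a_pos, i in enumerate(order):
        ri = flat[i]
        for j in order[a_pos + 1:]:
            rj = flat[j]
            if rj.chrom != ri.chrom or rj.start - ri.start > max_dist:
                break
            if require_same_type and ri.svtype != rj.svtype:
                continue
            if abs(ri.end - rj.end) <= max_dist:
                uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(flat)):
        clusters.setdefault(uf.find(i), []).append(i)
    merged = []
    for members in clusters.values():
        rep = min(members, key=lambda i: (flat[i].start, -flat[i].svlen))
        support = len({origin[i] for i in members})
        merged.append((flat[rep], support))
    merged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].id))
    return merged


def genotype_presence(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker carrier counts (dosage >= 1) vs non-carriers vs missing,
    overall and per population label."""
    if matrix.n_markers == 0:
        raise ValueError("empty genotype matrix")
    d = matrix.dosage
    pops = sorted(set(matrix.population))
    out: dict[str, np.ndarray] = {
        "carriers": (d >= 1).sum(axis=1),
        "non_carriers": (d == 0).sum(axis=1),
        "missing": (d == MISSING).sum(axis=1),
    }
    for p in pops:
        mask = matrix.population == p
        out[f"carriers_{p}"] = (d[:, mask] >= 1).sum(axis=1)
        out[f"non_carriers_{p}"] = (d[:, mask] == 0).sum(axis=1)
        out[f"missing_{p}"] = (d[:, mask] == MISSING).sum(axis=1)
    return pd.DataFrame(out, index=matrix.markers)
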