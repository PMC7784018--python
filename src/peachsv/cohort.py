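"""Synthetic study generator.

Builds a complete toy cohort — genome, gene models, repeat tracks, SNP and SV
genotypes, fruit-shape phenotype and an expression phenotype — with the
statistical structure the downstream stages assume:

* SV positions follow a two-rate mixture over 30-kb tiles (a background rate
  and an elevated rate inside planted hotspot tiles);
* SV derived-allele frequencies are stochastically smaller than synonymous
  SNP frequencies, the left-shifted spectrum expected under purifying
  selection against SVs;
* a designated subset of deletions carries identical homology blocks across
  both breakpoint flanks (the NAHR signature), another subset sits inside
  planted VNTR tandem arrays, and everything else has i.i.d. random flanks;
* one large inversion is heterozygous in every flat-fruit sample and absent
  from every round-fruit sample, mirroring the dominant-heterozygous flat
  locus, and expression rises additively with inversion dosage;
* outgroup samples are fixed for the ancestral allele at every polarizable
  site (a configurable fraction of sites has the derived allele as REF so
  polarity flipping is exercised).

Population sizes default to the study panel: 41 landraces, 108 modern
cultivars, 37 outgroup accessions, 37 flat among the 149 ingroup samples.
Random streams are partitioned per component so adding a component never
perturbs the others, and identical seeds give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import sv_io
from .annotate import GeneModel, introns_from_cds, write_gff3
from .hotspots import tile_genome
from .sv_io import MISSING, GenotypeMatrix, SVRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort."""

    seed: int = 0
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("Chr1", 3_000_000),
        ("Chr2", 990_000),
    )
    n_landrace: int = 41
    n_cultivar: int = 108
    n_outgroup: int = 37
    n_flat: int = 37
    n_snp: int = 3000
    n_sv: int = 1000
    n_genes: int = 60
    hotspot_fraction: float = 0.05
    hotspot_fold: float = 10.0
    interval_size: int = 30_000
    sfs_shift: float = 1.0
    inversion_span: tuple[str, int, int] = ("Chr1", 1_000_000, 2_674_221)
    expression_effect: float = 2.0
    noise_sd: float = 0.5
    n_nahr: int = 40
    n_vntr_sv: int = 15
    n_divergent: int = 60
    cultivar_het_boost: float = 0.25
    missing_rate: float = 0.02
    flip_fraction: float = 0.1
    fst: float = 0.05
    synonymous_fraction: float = 0.4

    def __post_init__(self) -> None:
        for name in ("n_landrace", "n_cultivar", "n_outgroup", "n_snp", "n_sv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.hotspot_fraction <= 1:
            raise ValueError("hotspot_fraction must be in [0, 1]")
        chrom, s, e = self.inversion_span
        lengths = dict(self.chrom_lengths)
        if chrom not in lengths:
            raise ValueError(f"inversion chromosome {chrom!r} not in genome")
        if s < 2000 or e > lengths[chrom] - 2000 or e <= s:
            raise ValueError(
                "inversion_span must lie inside its chromosome with >= 2 kb "
                "clearance at each end (breakpoint flanks must be extractable)"
            )


@dataclass
class StudyTruth:
    """Planted ground truth for detector recovery tests."""

    hotspot_intervals: list[tuple[str, int, int]]
    nahr_sv_ids: list[str]
    vntr_sv_ids: list[str]
    inversion_id: str
    divergent_ids: dict[str, str]  # sv id -> favorable/unfavorable


@dataclass
class SyntheticStudy:
    spec: CohortSpec
    genome: dict[str, str]
    genes: list[GeneModel]
    vntr_track: pd.DataFrame
    segdup_track: pd.DataFrame
    svs: list[SVRecord]
    sv_genotypes: GenotypeMatrix
    snp_table: pd.DataFrame        # chrom,pos,id,ref,alt,snp_class
    snp_genotypes: GenotypeMatrix
    samples: pd.DataFrame          # sample, population, phenotype, expression
    truth: StudyTruth = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def ingroup(self) -> list[str]:
        m = self.samples["population"] != "outgroup"
        return list(self.samples.loc[m, "sample"])

    @property
    def outgroup(self) -> list[str]:
        m = self.samples["population"] == "outgroup"
        return list(self.samples.loc[m, "sample"])

    @property
    def landraces(self) -> list[str]:
        m = self.samples["population"] == "landrace"
        return list(self.samples.loc[m, "sample"])

    @property
    def cultivars(self) -> list[str]:
        m = self.samples["population"] == "cultivar"
        return list(self.samples.loc[m, "sample"])


# --- reusable samplers (also exercised directly by calibration tests) ---------

def sample_sv_positions(
    rng: np.random.Generator,
    chrom_lengths: tuple[tuple[str, int], ...],
    n_sv: int,
    hotspot_intervals: set[tuple[str, int, int]] | list,
    fold: float,
    interval_size: int = 30_000,
) -> list[tuple[str, int]]:
    """Anchor positions from the two-rate tile mixture: each SV picks a tile
    with probability proportional to 1 (background) or ``fold`` (hotspot),
    then a uniform position within the tile."""
    tiles = tile_genome(chrom_lengths, interval_size)
    hot = set(map(tuple, hotspot_intervals))
    weights = np.array([fold if t in hot else 1.0 for t in tiles])
    weights = weights * np.array([e - s for _, s, e in tiles])  # length-weighted
    weights /= weights.sum()
    picks = rng.choice(len(tiles), size=n_sv, p=weights)
    out = []
    for t in picks:
        chrom, s, e = tiles[t]
        out.append((chrom, int(rng.integers(s, e))))
    return out


def sample_allele_frequencies(
    rng: np.random.Generator, n: int, sfs_shift: float = 0.0,
    a: float = 0.4, b: float = 0.8,
) -> np.ndarray:
    """Derived-allele frequencies from Beta(a, b * (1 + sfs_shift)); the
    shift parameter pushes mass toward rare alleles, leaving SNPs
    (sfs_shift = 0) stochastically larger than SVs (sfs_shift > 0)."""
    f = rng.beta(a, b * (1.0 + sfs_shift), size=n)
    return np.clip(f, 0.01, 0.95)


def _hw_dosages(rng: np.random.Generator, p: float, n: int) -> np.ndarray:
    return rng.binomial(2, p, size=n).astype(np.int8)


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=n)]


def generate_study(spec: CohortSpec) -> SyntheticStudy:
    """Deterministically build the full synthetic study from ``spec.seed``."""
    streams = np.random.SeedSequence(spec.seed).spawn(8)
    rng_genome, rng_pos, rng_freq, rng_geno, rng_noise, rng_genes, rng_tracks, rng_assign = (
        np.random.default_rng(s) for s in streams
    )
    lengths = dict(spec.chrom_lengths)

    # -- genome: i.i.d. uniform bases, later overwritten by planted features
    genome_arr = {c: _random_seq(rng_genome, n) for c, n in spec.chrom_lengths}

    # -- samples
    names = (
        [f"L{i + 1:03d}" for i in range(spec.n_landrace)]
        + [f"C{i + 1:03d}" for i in range(spec.n_cultivar)]
        + [f"O{i + 1:03d}" for i in range(spec.n_outgroup)]
    )
    population = (
        ["landrace"] * spec.n_landrace
        + ["cultivar"] * spec.n_cultivar
        + ["outgroup"] * spec.n_outgroup
    )
    n_ingroup = spec.n_landrace + spec.n_cultivar
    flat_idx = rng_assign.choice(n_ingroup, size=spec.n_flat, replace=False)
    phenotype = np.array(
        ["round"] * n_ingroup + ["NA"] * spec.n_outgroup, dtype=object
    )
    phenotype[flat_idx] = "flat"

    # -- gene models on a jittered grid so genes never collide
    genes: list[GeneModel] = []
    gid = 0
    for chrom, length in spec.chrom_lengths:
        n_here = max(1, round(spec.n_genes * length / sum(lengths.values())))
        slot = length // (n_here + 1)
        for k in range(n_here):
            start = (k + 1) * slot + int(rng_genes.integers(0, max(1, slot // 4)))
            exon, intron = 300, 200
            cds = tuple(
                (start + j * (exon + intron), start + j * (exon + intron) + exon)
                for j in range(3)
            )
            if cds[-1][1] >= length:
                continue
            strand = "+" if rng_genes.random() < 0.5 else "-"
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:04d}", chrom=chrom, strand=strand,
                    start0=start, end0=cds[-1][1],
                    cds_intervals=cds, intron_intervals=introns_from_cds(cds),
                )
            )
            gid += 1

    # -- VNTR + segdup tracks (VNTR arrays are really written into the genome)
    vntr_rows, segdup_rows = [], []
    for chrom, length in spec.chrom_lengths:
        n_vntr = max(4, length // 150_000)
        for _ in range(n_vntr):
            unit = _random_seq(rng_tracks, int(rng_tracks.integers(8, 15)))
            copies = int(rng_tracks.integers(25, 45))
            arr = np.tile(unit, copies)
            start = int(rng_tracks.integers(5_000, length - len(arr) - 5_000))
            genome_arr[chrom][start:start + len(arr)] = arr
            vntr_rows.append((chrom, start, start + len(arr)))
        for _ in range(max(2, length // 400_000)):
            s = int(rng_tracks.integers(0, length - 6_000))
            segdup_rows.append((chrom, s, s + int(rng_tracks.integers(2_000, 6_000))))
    vntr_track = (
        pd.DataFrame(vntr_rows, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"]).reset_index(drop=True)
    )
    segdup_track = (
        pd.DataFrame(segdup_rows, columns=["chrom", "start", "end"])
        .sort_values(["chrom", "start"]).reset_index(drop=True)
    )

    # -- hotspot truth and SV positions
    tiles = tile_genome(spec.chrom_lengths, spec.interval_size)
    n_hot = round(spec.hotspot_fraction * len(tiles))
    hot_pick = rng_pos.choice(len(tiles), size=n_hot, replace=False) if n_hot else []
    hotspot_intervals = [tiles[i] for i in sorted(hot_pick)]
    anchors = sample_sv_positions(
        rng_pos, spec.chrom_lengths, spec.n_sv - 1, hotspot_intervals,
        spec.hotspot_fold, spec.interval_size,
    )

    # -- SV records
    svs: list[SVRecord] = []
    type_probs = {"DEL": 0.55, "INS": 0.39, "DUP": 0.055, "INV": 0.005}
    types = rng_pos.choice(
        list(type_probs), size=len(anchors), p=list(type_probs.values())
    )
    for i, ((chrom, pos), svtype) in enumerate(zip(anchors, types)):
        svlen = int(np.clip(np.exp(rng_pos.normal(5.5, 1.2)), 31, 20_000))
        pos = int(np.clip(pos, 300, lengths[chrom] - svlen - 300))
        start = pos + 1  # 1-based
        end = start if svtype == "INS" else start + svlen - 1
        svs.append(SVRecord(f"sv{i:04d}", chrom, start, end, str(svtype), svlen))
    inv_chrom, inv_s, inv_e = spec.inversion_span
    inversion = SVRecord(
        "sv_inversion", inv_chrom, inv_s + 1, inv_e, "INV", inv_e - inv_s
    )
    svs.append(inversion)
    svs.sort(key=lambda r: (r.chrom, r.start, r.id))

    # -- plant NAHR homology blocks (30 bp identical across both flanks) into
    #    well-separated deletions away from VNTRs
    def vntr_overlap(r: SVRecord) -> bool:
        sub = vntr_track[vntr_track["chrom"] == r.chrom]
        return any(
            min(r.end0, te) - max(r.start0, ts) > 0
            for ts, te in zip(sub["start"], sub["end"])
        )

    candidates = [
        r for r in svs
        if r.svtype == "DEL" and r.svlen > 200 and not vntr_overlap(r)
        and r.start0 > 200 and r.end0 < lengths[r.chrom] - 200
    ]
    nahr_ids: list[str] = []
    used: list[tuple[str, int, int]] = []
    for r in candidates:
        if len(nahr_ids) >= spec.n_nahr:
            break
        if any(
            c == r.chrom and (abs(bp - s) < 500 or abs(bp - e) < 500)
            for c, s, e in used
            for bp in (r.start0, r.end0)
        ):
            continue
        block = _random_seq(rng_tracks, 30)
        for bp in (r.start0, r.end0):
            genome_arr[r.chrom][bp - 15: bp + 15] = block
        nahr_ids.append(r.id)
        used.append((r.chrom, r.start0, r.end0))

    # -- move a designated subset of SVs inside VNTR arrays (full coverage)
    vntr_sv_ids: list[str] = []
    replaceable = [i for i, r in enumerate(svs)
                   if r.svtype == "DEL" and r.id not in nahr_ids]
    vi = 0
    for _, row in vntr_track.iterrows():
        if vi >= min(spec.n_vntr_sv, len(replaceable)):
            break
        ts, te = int(row["start"]), int(row["end"])
        if te - ts < 60:
            continue
        idx = replaceable[vi]
        old = svs[idx]
        start0 = ts + 5
        end0 = min(te - 5, start0 + max(40, (te - ts) // 2))
        svs[idx] = SVRecord(old.id, row["chrom"], start0 + 1, end0, "DEL", end0 - start0)
        vntr_sv_ids.append(old.id)
        vi += 1
    svs.sort(key=lambda r: (r.chrom, r.start, r.id))

    # -- allele frequencies and genotypes
    sv_ids = [r.id for r in svs]
    inv_row = sv_ids.index("sv_inversion")
    f_sv = sample_allele_frequencies(rng_freq, len(svs), spec.sfs_shift)
    f_snp = sample_allele_frequencies(rng_freq, spec.n_snp, 0.0)

    def drift(f: np.ndarray) -> np.ndarray:
        """Mild population differentiation around the shared frequency."""
        if spec.fst <= 0:
            return f.copy()
        noise = rng_freq.normal(0.0, np.sqrt(spec.fst * f * (1 - f)))
        return np.clip(f + noise, 0.01, 0.99)

    # shared structure in both marker sets (SNP and SV PCA must concord),
    # plus a strongly divergent planted subset of SVs
    f_sv_l, f_sv_c = drift(f_sv), drift(f_sv)
    f_snp_l, f_snp_c = drift(f_snp), drift(f_snp)
    div_pick = rng_freq.choice(
        [i for i in range(len(svs)) if i != inv_row],
        size=min(spec.n_divergent, len(svs) - 1), replace=False,
    )
    divergent_ids: dict[str, str] = {}
    for j, i in enumerate(div_pick):
        if j % 2 == 0:
            f_sv_l[i], f_sv_c[i] = 0.05, 0.60   # cultivar-enriched: favorable
            divergent_ids[sv_ids[i]] = "favorable"
        else:
            f_sv_l[i], f_sv_c[i] = 0.60, 0.05   # landrace-enriched: unfavorable
            divergent_ids[sv_ids[i]] = "unfavorable"

    flipped_sv = rng_freq.random(len(svs)) < spec.flip_fraction
    flipped_snp = rng_freq.random(spec.n_snp) < spec.flip_fraction
    # keep the planted divergent SVs in ancestral-REF coding so the planted
    # carrier-frequency direction is the observable one
    flipped_sv[div_pick] = False

    def genotype_block(f_l, f_c, flipped, n_markers):
        d = np.empty((n_markers, len(names)), dtype=np.int8)
        for i in range(n_markers):
            gl = _hw_dosages(rng_geno, f_l[i], spec.n_landrace)
            gc = _hw_dosages(rng_geno, f_c[i], spec.n_cultivar)
            if spec.cultivar_het_boost > 0:
                # het excess from crossbreeding + clonal propagation: derived
                # homozygotes resolve to heterozygotes, preserving carrier status
                boost = rng_geno.random(spec.n_cultivar) < spec.cultivar_het_boost
                gc = np.where(boost & (gc == 2), 1, gc).astype(np.int8)
            go = np.zeros(spec.n_outgroup, dtype=np.int8)  # fixed ancestral
            row = np.concatenate([gl, gc, go])
            if flipped[i]:  # REF is the derived allele at this site
                row = (2 - row).astype(np.int8)
            miss = rng_geno.random(len(row)) < spec.missing_rate
            row[miss] = MISSING
            d[i] = row
        return d

    sv_dosage = genotype_block(f_sv_l, f_sv_c, flipped_sv, len(svs))
    snp_dosage = genotype_block(f_snp_l, f_snp_c, flipped_snp, spec.n_snp)

    # the planted inversion: heterozygous in every flat, absent in every round,
    # ancestral (absent) in the outgroup; no missing calls
    inv_dosage = np.zeros(len(names), dtype=np.int8)
    inv_dosage[flat_idx] = 1
    sv_dosage[inv_row] = inv_dosage
    flipped_sv[inv_row] = False

    sv_genotypes = GenotypeMatrix(
        markers=sv_ids, samples=names, dosage=sv_dosage,
        population=np.array(population, dtype=object), phenotype=phenotype,
    )

    # -- SNP site table
    snp_pos, snp_chrom = [], []
    remaining = spec.n_snp
    for ci, (chrom, length) in enumerate(spec.chrom_lengths):
        if ci == len(spec.chrom_lengths) - 1:
            k = remaining
        else:
            k = round(spec.n_snp * length / sum(lengths.values()))
            k = min(k, remaining)
        remaining -= k
        snp_chrom += [chrom] * k
        snp_pos += sorted(rng_freq.choice(length - 2, size=k, replace=False) + 1)
    snp_class = np.where(
        rng_freq.random(spec.n_snp) < spec.synonymous_fraction, "synonymous", "other"
    )
    ref_alt = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    ra = [ref_alt[i] for i in rng_freq.integers(0, 4, size=spec.n_snp)]
    snp_table = pd.DataFrame(
        {"chrom": snp_chrom, "pos": snp_pos,
         "id": [f"snp{i:05d}" for i in range(spec.n_snp)],
         "ref": [x[0] for x in ra], "alt": [x[1] for x in ra],
         "snp_class": snp_class}
    )
    snp_genotypes = GenotypeMatrix(
        markers=list(snp_table["id"]), samples=names, dosage=snp_dosage,
        population=np.array(population, dtype=object), phenotype=phenotype,
    )

    # -- expression phenotype: additive in inversion dosage, on ingroup scale
    expression = (
        spec.expression_effect * inv_dosage.astype(float)
        + rng_noise.normal(0.0, spec.noise_sd, size=len(names))
    )
    samples = pd.DataFrame(
        {"sample": names, "population": population, "phenotype": phenotype,
         "expression": np.round(expression, 6)}
    )

    genome = {c: arr.tobytes().decode("ascii") for c, arr in genome_arr.items()}
    truth = StudyTruth(
        hotspot_intervals=hotspot_intervals,
        nahr_sv_ids=nahr_ids,
        vntr_sv_ids=vntr_sv_ids,
        inversion_id="sv_inversion",
        divergent_ids=divergent_ids,
    )
    return SyntheticStudy(
        spec=spec, genome=genome, genes=genes, vntr_track=vntr_track,
        segdup_track=segdup_track, svs=svs, sv_genotypes=sv_genotypes,
        snp_table=snp_table, snp_genotypes=snp_genotypes, samples=samples,
        truth=truth,
    )


def write_fasta(path: Path, genome: dict[str, str], width: int = 80) -> None:
    with path.open("w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_study(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Write the study in standard formats; returns the file manifest.
    Round-trips losslessly through the sv_io readers."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}
    contigs = list(study.spec.chrom_lengths)

    manifest["genome"] = d / "genome.fa"
    write_fasta(manifest["genome"], study.genome)
    manifest["genes"] = d / "genes.gff3"
    write_gff3(manifest["genes"], study.genes)
    manifest["sv_vcf"] = d / "svs.vcf"
    sv_io.write_sv_vcf(manifest["sv_vcf"], study.svs, study.sv_genotypes, contigs)
    manifest["snp_vcf"] = d / "snps.vcf"
    sv_io.write_snp_vcf(
        manifest["snp_vcf"], list(study.snp_table["chrom"]),
        list(study.snp_table["pos"]), list(study.snp_table["id"]),
        list(study.snp_table["ref"]), list(study.snp_table["alt"]),
        study.snp_genotypes, contigs,
    )
    manifest["vntr_bed"] = d / "vntr.bed"
    sv_io.write_bed(manifest["vntr_bed"], study.vntr_track.itertuples(index=False))
    manifest["segdup_bed"] = d / "segdup.bed"
    sv_io.write_bed(manifest["segdup_bed"], study.segdup_track.itertuples(index=False))
    manifest["truth_hotspots_bed"] = d / "truth_hotspots.bed"
    sv_io.write_bed(manifest["truth_hotspots_bed"], study.truth.hotspot_intervals)
    manifest["samples"] = d / "samples.tsv"
    study.samples.to_csv(manifest["samples"], sep="\t", index=False)
    manifest["snp_classes"] = d / "snp_classes.tsv"
    study.snp_table[["id", "snp_class"]].to_csv(
        manifest["snp_classes"], sep="\t", index=False
    )
    return manifest
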