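"""SV formation-mechanism classification.

An SV is first screened against a VNTR track: when more than 80% of its span
is tandem repeat the call is ``excluded_vntr`` and no homology search runs.
Otherwise the +/-100 bp flanks of its two breakpoint junctions are aligned
against each other and the SV is called ``NAHR`` when a homology block exists
with identity >= 85%, an exact-match run >= 20 bp, an offset between the two
flank positions <= 20 bp, and coverage of the breakpoint in both flanks;
otherwise ``other``.

Block discovery uses banded ungapped alignment: an offset budget of +/-20 bp
is exactly a diagonal band, and every published threshold (identity, exact
run, offset, breakpoint coverage) is expressible on ungapped diagonals, which
keeps the search exhaustively enumerable and therefore exactly testable
against a brute-force oracle.  Identity is matches / aligned columns.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sv_io import SVRecord

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HomologyBlock:
    """A qualifying ungapped homology block between the two breakpoint flanks.

    ``offset`` is the block's start position in flank_b minus its start
    position in flank_a (both flanks centred on their breakpoint, so offset 0
    means the block sits identically relative to each junction).
    """

    offset: int
    a_start: int
    length: int
    identity: float
    covers_breakpoint: bool

    @property
    def b_start(self) -> int:
        return self.a_start + self.offset


@dataclass
class MechanismCall:
    sv_id: str
    vntr_fraction: float
    mech_class: str  # NAHR | other | excluded_vntr
    best_block: HomologyBlock | None = None
    flank_truncated: bool = False


def vntr_fraction(sv: SVRecord, vntr_track: pd.DataFrame) -> float:
    """Fraction of the SV reference span covered by the (merged, sorted) VNTR
    track.  Insertions are 1-bp points: fraction is 0 or 1."""
    s, e = sv.start0, sv.end0
    span = e - s
    covered = 0
    sub = vntr_track[vntr_track["chrom"] == sv.chrom]
    for ts, te in zip(sub["start"], sub["end"]):
        covered += max(0, min(e, te) - max(s, ts))
    return covered / span


def find_homology_blocks(
    flank_a: str,
    flank_b: str,
    breakpoint_a: int | None = None,
    breakpoint_b: int | None = None,
    min_identity: float = 0.85,
    min_identical_run: int = 20,
    max_offset: int = 20,
) -> list[HomologyBlock]:
    """Best qualifying homology block per diagonal offset.

    Breakpoints default to the flank centres (the +/-100 bp windows place the
    junction mid-flank).  For each offset in [-max_offset, max_offset] the
    maximal-length window is reported that (i) covers the breakpoint in both
    flanks, (ii) has identity >= min_identity, and (iii) contains an exact
    match run >= min_identical_run; ties prefer the leftmost window.
    """
    na, nb = len(flank_a), len(flank_b)
    if min(na, nb) < 2 * min_identical_run:
        log.warning("flank shorter than 2x min_identical_run; no blocks searched")
        return []
    bp_a = na // 2 if breakpoint_a is None else breakpoint_a
    bp_b = nb // 2 if breakpoint_b is None else breakpoint_b
    a = np.frombuffer(flank_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(flank_b.upper().encode(), dtype=np.uint8)
    kernel = np.ones(min_identical_run, dtype=int)
    blocks: list[HomologyBlock] = []
    for d in range(-max_offset, max_offset + 1):
        lo = max(0, -d)
        hi = min(na, nb - d)
        if hi - lo < min_identical_run:
            continue
        m = a[lo:hi] == b[lo + d: hi + d]
        run_start = np.convolve(m.astype(int), kernel, "valid") == min_identical_run
        if not run_start.any():
            continue
        # windows [s, e) in flank_a coordinates that cover both breakpoints
        s_max = min(bp_a, bp_b - d)
        e_min = max(bp_a, bp_b - d) + 1
        if s_max < lo or e_min > hi:
            continue
        starts = np.arange(lo, s_max + 1)
        ends = np.arange(e_min, hi + 1)
        cum = np.concatenate([[0], np.cumsum(m)])        # index by pos - lo
        runs = np.concatenate([[0], np.cumsum(run_start)])  # run starting at pos - lo
        matches = cum[ends[None, :] - lo] - cum[starts[:, None] - lo]
        lengths = ends[None, :] - starts[:, None]
        ident = matches / lengths
        # exact run fully inside the window: a run start in [s, e - min_run]
        r_hi = np.clip(ends[None, :] - min_identical_run + 1 - lo, 0, len(runs) - 1)
        r_lo = np.clip(starts[:, None] - lo, 0, len(runs) - 1)
        has_run = (runs[r_hi] - runs[r_lo]) > 0
        ok = (ident >= min_identity) & has_run
        if not ok.any():
            continue
        # maximal length, tie -> leftmost start
        cand_len = np.where(ok, lengths, -1)
        best_flat = None
        best = (-1, na + 1)  # (length, start)
        si, ei = np.nonzero(ok)
        for i, j in zip(si, ei):
            key = (int(cand_len[i, j]), int(starts[i]))
            if key[0] > best[0] or (key[0] == best[0] and key[1] < best[1]):
                best = key
                best_flat = (i, j)
        i, j = best_flat
        s, e = int(starts[i]), int(ends[j])
        blocks.append(
            HomologyBlock(
                offset=d,
                a_start=s,
                length=e - s,
                identity=float(ident[i, j]),
                covers_breakpoint=True,
            )
        )
    return blocks


def extract_flanks(
    genome: Mapping[str, str], sv: SVRecord, flank: int = 100
) -> tuple[str, str, int, int, bool]:
    """The +/-``flank`` bp windows around the two breakpoint junctions,
    truncated (and flagged) at chromosome ends.  Returns
    (flank_a, flank_b, breakpoint_a, breakpoint_b, truncated)."""
    seq = genome[sv.chrom]
    truncated = False
    out = []
    for bp in (sv.start0, sv.end0):
        lo, hi = bp - flank, bp + flank
        if lo < 0 or hi > len(seq):
            truncated = True
            lo, hi = max(0, lo), min(len(seq), hi)
        out.append((seq[lo:hi], bp - lo))
    (fa, ba), (fb, bb) = out
    return fa, fb, ba, bb, truncated


def classify_mechanism(
    sv: SVRecord,
    genome: Mapping[str, str],
    vntr_track: pd.DataFrame,
    flank: int = 100,
    vntr_cutoff: float = 0.8,
    **block_kwargs,
) -> MechanismCall:
    """VNTR exclusion first (strictly more than ``vntr_cutoff`` coverage),
    then NAHR vs other by breakpoint-flank homology."""
    vf = vntr_fraction(sv, vntr_track)
    if vf > vntr_cutoff:
        return MechanismCall(sv.id, vf, "excluded_vntr")
    # breakpoints closer than the offset band (insertions in particular, whose
    # two junctions coincide on the reference) make the flank-vs-flank test
    # degenerate: the windows overlap themselves and always "align"
    max_offset = block_kwargs.get("max_offset", 20)
    if sv.end0 - sv.start0 <= max_offset:
        return MechanismCall(sv.id, vf, "other")
    fa, fb, ba, bb, truncated = extract_flanks(genome, sv, flank)
    if truncated:
        log.warning("SV %s: breakpoint within %d bp of chromosome end; flanks truncated",
                    sv.id, flank)
    blocks = find_homology_blocks(fa, fb, ba, bb, **block_kwargs)
    if blocks:
        best = max(blocks, key=lambda blk: (blk.length, blk.identity))
        return MechanismCall(sv.id, vf, "NAHR", best, truncated)
    return MechanismCall(sv.id, vf, "other", None, truncated)


def classify_all(
    svs: Sequence[SVRecord],
    genome: Mapping[str, str],
    vntr_track: pd.DataFrame,
    **kwargs,
) -> pd.DataFrame:
    """Mechanism calls for a call set as a tidy table."""
    calls = [classify_mechanism(sv, genome, vntr_track, **kwargs) for sv in svs]
    return pd.DataFrame(
        {
            "sv_id": [c.sv_id for c in calls],
            "vntr_fraction": [c.vntr_fraction for c in calls],
            "class": [c.mech_class for c in calls],
            "block_length": [c.best_block.length if c.best_block else 0 for c in calls],
            "block_identity": [
                c.best_block.identity if c.best_block else np.nan for c in calls
            ],
        }
    )


def inverted_repeat_scan(
    seq: str,
    bp1: int,
    bp2: int,
    window: int = 1000,
    min_len: int = 50,
) -> list[tuple[int, int, int]]:
    """Exact reverse-complement repeats >= ``min_len`` shared between the two
    breakpoint windows (each window is +/- window/2 around its breakpoint).

    Returns maximal hits as (pos_in_window1, pos_in_window2, length); an empty
    list means no inverted repeats, the signature distinguishing NHEJ- from
    NAHR-formed inversions.
    """
    half = window // 2
    if abs(bp2 - bp1) < window:
        raise ValueError("breakpoint windows overlap; breakpoints too close")
    bp1, bp2 = sorted((bp1, bp2))
    w1 = seq[max(0, bp1 - half): bp1 + half]
    w2 = seq[max(0, bp2 - half): bp2 + half]
    rc2 = revcomp(w2)
    k = min_len
    index: dict[str, list[int]] = {}
    for i in range(len(w1) - k + 1):
        index.setdefault(w1[i:i + k], []).append(i)
    pairs = set()
    for j in range(len(rc2) - k + 1):
        for i in index.get(rc2[j:j + k], []):
            pairs.add((i, j))
    # merge consecutive k-mer hits along diagonals into maximal matches
    hits = []
    for i, j in sorted(pairs):
        if (i - 1, j - 1) in pairs:
            continue
        length = k
        while (i + length - k + 1, j + length - k + 1) in pairs:
            length += 1
        # report position in w2's forward orientation
        pos2 = len(w2) - (j + length)
        hits.append((i, pos2, length))
    return sorted(hits)


def junction_edits(
    ref_left: str, ref_right: str, observed_junction: str, anchor: int = 20
) -> list[tuple[str, int, str]]:
    """Small indels at an SV joint, the NHEJ mis-repair signature.

    The observed junction must span the joint with >= ``anchor`` bp on each
    side.  Its left end is anchored into ``ref_left`` (sequence ending at the
    joint) and its right end into ``ref_right`` (sequence starting at the
    joint); unmatched reference bases at the joint are reported as deletions
    and unmatched junction bases as an insertion.  Returns a list of
    ("del"|"ins", length, sequence) tuples; clean concatenation gives [].
    """
    j = observed_junction
    if len(j) < 2 * anchor:
        raise ValueError("junction too short to anchor on both sides")
    left_seed = j[:anchor]
    pos = ref_left.find(left_seed)
    if pos < 0:
        raise ValueError("junction left end does not align to the left flank")
    i = pos + anchor
    m = anchor
    while i < len(ref_left) and m < len(j) and ref_left[i] == j[m]:
        i += 1
        m += 1
    left_deleted = ref_left[i:]
    right_seed = j[-anchor:]
    rpos = ref_right.rfind(right_seed)
    if rpos < 0:
        raise ValueError("junction right end does not align to the right flank")
    ri = rpos
    rm = len(j) - anchor
    while ri > 0 and rm > m and ref_right[ri - 1] == j[rm - 1]:
        ri -= 1
        rm -= 1
    right_deleted = ref_right[:ri]
    inserted = j[m:rm]
    edits: list[tuple[str, int, str]] = []
    deleted = left_deleted + right_deleted
    if deleted:
        edits.append(("del", len(deleted), deleted))
    if inserted:
        edits.append(("ins", len(inserted), inserted))
    return edits
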