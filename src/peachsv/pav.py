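"""Window-based presence/absence variation (PAV) detection.

The query genome is cut into 500-bp windows stepping by 100 bp and each
window is mapped to the target genome; windows whose best single-locus
aligned fraction falls below 25% are query-specific, and overlapping specific
windows merge into PAV regions.  Mapping uses a deterministic exact-k-mer
seed (k = 21) plus ungapped extension; it lives behind ``window_coverage`` so
a general-purpose aligner can be swapped in for real assemblies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .annotate import merge_intervals


@dataclass(frozen=True)
class PavRegion:
    chrom: str
    start: int  # 0-based half-open, query coordinates
    end: int
    n_windows: int


def window_genome(
    genome: Mapping[str, str], win: int = 500, step: int = 100
) -> list[tuple[str, int, int]]:
    """Sliding full-length windows per chromosome; a chromosome shorter than
    ``win`` yields one truncated window only if it is at least win/2 long."""
    if win < step:
        raise ValueError("win must be >= step")
    windows = []
    for chrom in genome:
        length = len(genome[chrom])
        if length < win:
            if length >= win / 2:
                windows.append((chrom, 0, length))
            continue
        for s in range(0, length - win + 1, step):
            windows.append((chrom, s, s + win))
    return windows


class KmerIndex:
    """Exact k-mer index over a target genome."""

    def __init__(self, genome: Mapping[str, str], k: int = 21) -> None:
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((chrom, i))
        self.genome = dict(genome)

    def seeds(self, seq: str) -> dict[tuple[str, int], list[tuple[int, int]]]:
        """Seed hits grouped by (chrom, diagonal); each hit is
        (query_pos, target_pos)."""
        by_diag: dict[tuple[str, int], list[tuple[int, int]]] = {}
        for i in range(len(seq) - self.k + 1):
            for chrom, j in self.index.get(seq[i:i + self.k], []):
                by_diag.setdefault((chrom, j - i), []).append((i, j))
        return by_diag


_MAX_CONSECUTIVE_MISMATCH = 3


def _extend(seq: str, target: str, q0: int, q1: int, t0: int) -> tuple[int, int]:
    """Extend a seeded exact interval [q0, q1) on one diagonal in both
    directions, stopping after a run of consecutive mismatches and trimming
    the mismatched tail.  Returns the extended query interval."""
    # rightwards
    q, t, miss, last_match = q1, t0 + (q1 - q0), 0, q1
    while q < len(seq) and t < len(target):
        if seq[q] == target[t]:
            miss = 0
            last_match = q + 1
        else:
            miss += 1
            if miss >= _MAX_CONSECUTIVE_MISMATCH:
                break
        q += 1
        t += 1
    right = last_match
    # leftwards
    q, t, miss, first_match = q0 - 1, t0 - 1, 0, q0
    while q >= 0 and t >= 0:
        if seq[q] == target[t]:
            miss = 0
            first_match = q
        else:
            miss += 1
            if miss >= _MAX_CONSECUTIVE_MISMATCH:
                break
        q -= 1
        t -= 1
    return first_match, right


def window_coverage(window_seq: str, target_index: KmerIndex) -> float:
    """Best single-locus aligned fraction of the window in [0, 1].

    Seeds on one (chrom, diagonal) are chained, each seeded run is extended
    without gaps, and coverage is the merged extended span divided by the
    window length; the best diagonal wins (repeat loci cannot pool coverage
    across placements).
    """
    n = len(window_seq)
    if n < target_index.k:
        return 0.0
    best = 0.0
    for (chrom, diag), hits in target_index.seeds(window_seq).items():
        target = target_index.genome[chrom]
        # group consecutive seed positions into exact runs
        intervals = []
        hits.sort()
        run_start = prev = hits[0][0]
        for qpos, _ in hits[1:]:
            if qpos != prev + 1:
                intervals.append((run_start, prev + target_index.k))
                run_start = qpos
            prev = qpos
        intervals.append((run_start, prev + target_index.k))
        extended = [
            _extend(window_seq, target, q0, q1, q0 + diag) for q0, q1 in intervals
        ]
        covered = sum(e - s for s, e in merge_intervals(extended))
        best = max(best, covered / n)
        if best == 1.0:
            break
    return best


def call_pavs(
    query_genome: Mapping[str, str],
    target_genome: Mapping[str, str],
    win: int = 500,
    step: int = 100,
    min_coverage: float = 0.25,
    k: int = 21,
    coverage_fn: Callable[[str, KmerIndex], float] | None = None,
) -> list[PavRegion]:
    """Query-specific regions: windows mapping to the target with coverage
    below ``min_coverage``, merged where they overlap.  Call again with the
    genomes swapped for the symmetric (target-specific) set."""
    index = KmerIndex(target_genome, k=k)
    cov = coverage_fn or window_coverage
    specific: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in window_genome(query_genome, win=win, step=step):
        if cov(query_genome[chrom][s:e], index) < min_coverage:
            specific.setdefault(chrom, []).append((s, e))
    regions = []
    for chrom, wins in specific.items():
        for s, e in merge_intervals(wins):
            n = sum(1 for ws, we in wins if ws >= s and we <= e)
            regions.append(PavRegion(chrom, s, e, n))
    return sorted(regions, key=lambda r: (r.chrom, r.start))
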