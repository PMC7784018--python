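"""Poisson-based SV hotspot detection and feature enrichment.

The genome is tiled into non-overlapping fixed-size intervals (default 30 kb,
final short interval per chromosome kept).  Under a homogeneous null the
per-interval SV count is Poisson with mean lambda = total SVs / number of
intervals; an interval is a hotspot when its count reaches the smallest
integer c with CDF(c - 1; lambda) >= quantile (default the 99th percentile).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sv_io import SVRecord


@dataclass
class HotspotModel:
    interval_size: int
    intervals: list[tuple[str, int, int]]       # (chrom, start0, end0)
    counts: np.ndarray
    lam: float | None = None
    quantile: float = 0.99
    threshold: int | None = None
    flags: np.ndarray | None = None

    @property
    def n_hotspots(self) -> int:
        return 0 if self.flags is None else int(self.flags.sum())

    @property
    def hotspot_span(self) -> int:
        if self.flags is None:
            return 0
        return sum(
            e - s for (c, s, e), f in zip(self.intervals, self.flags) if f
        )


def tile_genome(
    chrom_lengths: Sequence[tuple[str, int]],
    interval_size: int = 30_000,
    drop_short_tail: bool = False,
) -> list[tuple[str, int, int]]:
    """Non-overlapping half-open tiling; the trailing short interval is kept
    unless ``drop_short_tail``."""
    tiles = []
    for chrom, length in chrom_lengths:
        for s in range(0, length, interval_size):
            e = min(s + interval_size, length)
            if e - s < interval_size and drop_short_tail:
                continue
            tiles.append((chrom, s, e))
    return tiles


def interval_counts(
    chrom_lengths: Sequence[tuple[str, int]],
    svs: Sequence[SVRecord],
    interval_size: int = 30_000,
    anchor: str = "midpoint",
    drop_short_tail: bool = False,
) -> HotspotModel:
    """Count SVs per tile; each SV is assigned to exactly one interval by its
    anchor coordinate (default: midpoint, the SVs-as-points convention)."""
    lengths = dict(chrom_lengths)
    tiles = tile_genome(chrom_lengths, interval_size, drop_short_tail)
    index = {(c, s): i for i, (c, s, e) in enumerate(tiles)}
    counts = np.zeros(len(tiles), dtype=int)
    for sv in svs:
        pos = sv.midpoint0 if anchor == "midpoint" else sv.start0
        if sv.chrom not in lengths or not (0 <= pos < lengths[sv.chrom]):
            raise ValueError(f"SV {sv.id}: anchor {pos} off chromosome {sv.chrom}")
        key = (sv.chrom, (pos // interval_size) * interval_size)
        if key not in index:  # anchor in a dropped short tail
            continue
        counts[index[key]] += 1
    return HotspotModel(interval_size=interval_size, intervals=tiles, counts=counts)


def poisson_threshold(lam: float, quantile: float = 0.99) -> int:
    """Smallest integer c >= 1 with Poisson CDF(c - 1; lam) >= quantile."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    return int(stats.poisson.ppf(quantile, lam)) + 1


def call_hotspots(
    model: HotspotModel,
    quantile: float = 0.99,
    lam: float | None = None,
    nonzero_lambda: bool = False,
) -> HotspotModel:
    """Flag hotspot intervals.

    lambda defaults to the mean count over all intervals (zeros included);
    ``nonzero_lambda`` averages over occupied intervals only, and ``lam``
    overrides both when the generating rate is known.
    """
    if lam is None:
        if nonzero_lambda:
            occupied = model.counts[model.counts > 0]
            lam = float(occupied.mean()) if occupied.size else 0.0
        else:
            lam = float(model.counts.mean())
    model.lam = lam
    model.quantile = quantile
    # lam == 0 (no SVs at all): any occupied interval would exceed the null
    model.threshold = poisson_threshold(lam, quantile) if lam > 0 else 1
    model.flags = model.counts >= model.threshold
    return model


def hotspot_bed(model: HotspotModel) -> pd.DataFrame:
    """Hotspot intervals as a BED-style table with count and threshold."""
    rows = [
        (c, s, e, int(n), model.threshold)
        for (c, s, e), n, f in zip(model.intervals, model.counts, model.flags)
        if f
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count", "threshold"])


def hotspot_enrichment(
    model: HotspotModel,
    feature_track: pd.DataFrame | None = None,
    svs: Sequence[SVRecord] | None = None,
    sv_labels: dict[str, bool] | None = None,
) -> dict:
    """2x2 enrichment of hotspots for an interval feature or an SV label.

    Interval level (``feature_track``: BED-like chrom/start/end): hotspot
    status x overlaps-feature.  SV level (``svs`` + ``sv_labels``, e.g. NAHR
    calls): SV-in-hotspot x SV-has-label.  Two-sided Fisher exact test.
    """
    if model.flags is None:
        raise ValueError("call_hotspots first")
    if feature_track is not None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for _, row in feature_track.iterrows():
            by_chrom.setdefault(row["chrom"], []).append((row["start"], row["end"]))
        in_feature = np.array(
            [
                any(s < fe and fs < e for fs, fe in by_chrom.get(c, []))
                for c, s, e in model.intervals
            ]
        )
        a = int(np.sum(model.flags & in_feature))
        b = int(np.sum(model.flags & ~in_feature))
        c_ = int(np.sum(~model.flags & in_feature))
        d = int(np.sum(~model.flags & ~in_feature))
    elif svs is not None and sv_labels is not None:
        hot = set()
        for (chrom, s, e), f in zip(model.intervals, model.flags):
            if f:
                hot.add((chrom, s))
        in_hot = np.array(
            [
                (sv.chrom, (sv.midpoint0 // model.interval_size) * model.interval_size)
                in hot
                for sv in svs
            ]
        )
        lab = np.array([bool(sv_labels.get(sv.id, False)) for sv in svs])
        a = int(np.sum(in_hot & lab))
        b = int(np.sum(in_hot & ~lab))
        c_ = int(np.sum(~in_hot & lab))
        d = int(np.sum(~in_hot & ~lab))
    else:
        raise ValueError("provide feature_track or (svs, sv_labels)")
    table = np.array([[a, b], [c_, d]])
    degenerate = (a + b == 0) or (c_ + d == 0) or (a + c_ == 0) or (b + d == 0)
    if degenerate:
        return {"table": table, "odds_ratio": float("nan"), "p": 1.0, "degenerate": True}
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": float(odds), "p": float(p), "degenerate": False}
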