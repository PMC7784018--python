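"""Mechanism classification: VNTR exclusion, flank-homology blocks, inverted
repeats and junction edits."""

import numpy as np
import pandas as pd
import pytest

from peachsv import mechanism
from peachsv.mechanism import find_homology_blocks, revcomp
from peachsv.sv_io import SVRecord

from conftest import random_seq


def oracle_blocks(fa, fb, bp_a=None, bp_b=None, min_identity=0.85,
                  min_run=20, max_offset=20):
    """Exhaustive enumeration of every window on every allowed diagonal,
    keeping the maximal qualifying window per diagonal (tie: leftmost)."""
    na, nb = len(fa), len(fb)
    if min(na, nb) < 2 * min_run:
        return []
    bp_a = na // 2 if bp_a is None else bp_a
    bp_b = nb // 2 if bp_b is None else bp_b
    out = []
    for d in range(-max_offset, max_offset + 1):
        lo, hi = max(0, -d), min(na, nb - d)
        if hi - lo < min_run:
            continue
        match = [fa[i] == fb[i + d] for i in range(lo, hi)]
        # positions (relative to lo) where an exact run of >= min_run starts
        run_ok = []
        for r in range(len(match) - min_run + 1):
            run_ok.append(all(match[r: r + min_run]))
        if not any(run_ok):
            continue
        best = None
        for s in range(lo, min(bp_a, bp_b - d) + 1):
            for e in range(max(bp_a, bp_b - d) + 1, hi + 1):
                seg = match[s - lo: e - lo]
                ident = sum(seg) / len(seg)
                if ident < min_identity:
                    continue
                if not any(run_ok[r] for r in range(s - lo, e - lo - min_run + 1)):
                    continue
                cand = (e - s, -s)
                if best is None or cand > (best[1] - best[0], -best[0]):
                    best = (s, e, ident)
        if best is not None:
            out.append((d, best[0], best[1] - best[0]))
    return out


def plant_block(rng, n=200, block_len=30, offset=0, mutations=0):
    """Random flank pair sharing one block across both breakpoints."""
    fa = list(random_seq(rng, n))
    fb = list(random_seq(rng, n))
    block = list(random_seq(rng, block_len))
    a0 = n // 2 - block_len // 2
    b0 = a0 + offset
    fa[a0: a0 + block_len] = block
    blk_b = list(block)
    for i in rng.choice(block_len, size=mutations, replace=False):
        blk_b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[blk_b[i]]
    fb[b0: b0 + block_len] = blk_b
    return "".join(fa), "".join(fb)


def test_planted_identical_block_found(rng):
    fa, fb = plant_block(rng, block_len=30, offset=0)
    blocks = find_homology_blocks(fa, fb)
    assert any(b.offset == 0 and b.length >= 30 and b.covers_breakpoint for b in blocks)


def test_short_run_rejected(rng):
    """A 15-bp identical block is below the 20-bp exact-run requirement."""
    fa, fb = plant_block(rng, block_len=15, offset=0)
    assert find_homology_blocks(fa, fb) == []


def test_offset_budget_enforced(rng):
    fa, fb = plant_block(rng, block_len=30, offset=25)
    assert find_homology_blocks(fa, fb, max_offset=20) == []
    fa, fb = plant_block(rng, block_len=30, offset=18)
    assert any(b.offset == 18 for b in find_homology_blocks(fa, fb, max_offset=20))


def test_blocks_match_exhaustive_oracle(rng):
    """Vectorised search equals the brute-force all-windows enumeration on a
    mix of homology-free, threshold-straddling, and clearly homologous pairs."""
    for trial in range(40):
        kind = trial % 4
        if kind == 0:
            fa, fb = random_seq(rng, 200), random_seq(rng, 200)
        elif kind == 1:
            fa, fb = plant_block(rng, block_len=int(rng.integers(18, 24)),
                                 offset=int(rng.integers(-21, 22)))
        elif kind == 2:
            fa, fb = plant_block(rng, block_len=40, offset=0,
                                 mutations=int(rng.integers(0, 4)))
        else:
            fa, fb = plant_block(rng, block_len=60,
                                 offset=int(rng.integers(-5, 6)), mutations=2)
        got = [(b.offset, b.a_start, b.length) for b in find_homology_blocks(fa, fb)]
        assert got == oracle_blocks(fa, fb), f"trial {trial} ({kind})"


def test_flank_swap_symmetry(rng):
    fa, fb = plant_block(rng, block_len=30, offset=7)
    fwd = find_homology_blocks(fa, fb)
    rev = find_homology_blocks(fb, fa)
    assert {(-b.offset, b.length) for b in fwd} == {(b.offset, b.length) for b in rev}


def test_flanks_too_short_logged():
    assert find_homology_blocks("ACGT" * 5, "ACGT" * 5) == []


# --- VNTR fraction ------------------------------------------------------------


def _track(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _del(start0, end0, id="d1"):
    return SVRecord(id, "Chr1", start0 + 1, end0, "DEL", end0 - start0)


def test_vntr_fraction_full_and_boundary():
    track = _track([("Chr1", 100, 500)])
    assert mechanism.vntr_fraction(_del(150, 300), track) == 1.0
    # exactly 80% covered: retained (the exclusion rule is strictly >80%)
    sv = _del(100, 200)
    track80 = _track([("Chr1", 100, 180)])
    assert mechanism.vntr_fraction(sv, track80) == pytest.approx(0.8)
    genome = {"Chr1": random_seq(np.random.default_rng(3), 1000)}
    call = mechanism.classify_mechanism(sv, genome, track80)
    assert call.mech_class != "excluded_vntr"


def test_vntr_fraction_matches_per_base_count(rng):
    track = _track(
        [("Chr1", int(s), int(s) + int(rng.integers(20, 200))) for s in
         sorted(rng.integers(0, 5000, size=8))]
    )
    for _ in range(20):
        s = int(rng.integers(0, 4500))
        sv = _del(s, s + int(rng.integers(30, 400)))
        base_cov = sum(
            any(ts <= pos < te for ts, te in zip(track["start"], track["end"]))
            for pos in range(sv.start0, sv.end0)
        )
        # brute force counts union coverage; equality requires a merged track
        merged = []
        for ts, te in sorted(zip(track["start"], track["end"])):
            if merged and ts <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], te))
            else:
                merged.append((ts, te))
        assert mechanism.vntr_fraction(sv, _track([("Chr1", a, b) for a, b in merged])) \
            == pytest.approx(base_cov / sv.span)


def test_vntr_exclusion_precedes_homology(rng):
    """>80% VNTR coverage wins even over perfect flank homology."""
    seq = list(random_seq(rng, 2000))
    block = random_seq(rng, 40)
    sv = _del(800, 1200, "x")
    seq[785:825] = list(block)
    seq[1185:1225] = list(block)
    genome = {"Chr1": "".join(seq)}
    track = _track([("Chr1", 790, 1190)])  # covers 390/400 bp of the span
    call = mechanism.classify_mechanism(sv, genome, track)
    assert call.vntr_fraction > 0.8
    assert call.mech_class == "excluded_vntr"


def test_study_mechanism_truth(study):
    calls = mechanism.classify_all(study.svs, study.genome, study.vntr_track)
    cl = calls.set_index("sv_id")["class"]
    assert all(cl[i] == "NAHR" for i in study.truth.nahr_sv_ids)
    assert all(cl[i] == "excluded_vntr" for i in study.truth.vntr_sv_ids)
    false_nahr = set(cl[cl == "NAHR"].index) - set(study.truth.nahr_sv_ids)
    assert not false_nahr


# --- inverted repeats ----------------------------------------------------------


def test_inverted_repeat_planted(rng):
    seq = list(random_seq(rng, 20_000))
    rep = random_seq(rng, 100)
    bp1, bp2 = 5_000, 15_000
    seq[bp1 - 50: bp1 + 50] = list(rep)
    seq[bp2 - 50: bp2 + 50] = list(revcomp(rep))
    hits = mechanism.inverted_repeat_scan("".join(seq), bp1, bp2)
    assert hits and max(h[2] for h in hits) >= 100
    # swap invariance of detection
    hits_swapped = mechanism.inverted_repeat_scan("".join(seq), bp2, bp1)
    assert bool(hits) == bool(hits_swapped)


def test_inverted_repeat_absent_on_random(rng):
    seq = random_seq(rng, 20_000)
    assert mechanism.inverted_repeat_scan(seq, 5_000, 15_000) == []


def test_inverted_repeat_windows_overlap_error(rng):
    with pytest.raises(ValueError, match="too close"):
        mechanism.inverted_repeat_scan(random_seq(rng, 5000), 2000, 2500)


# --- junction edits -------------------------------------------------------------


def test_junction_edits(rng):
    left = random_seq(rng, 60)
    right = random_seq(rng, 60)
    assert mechanism.junction_edits(left, right, left[-30:] + right[:30]) == []
    # 2-bp deletion at the joint
    edits = mechanism.junction_edits(left, right, left[-30:-2] + right[:30])
    assert edits == [("del", 2, left[-2:])]
    # 1-bp insertion at the joint
    edits = mechanism.junction_edits(left, right, left[-30:] + "A" + right[:30])
    assert edits == [("ins", 1, "A")]


def test_junction_unalignable(rng):
    with pytest.raises(ValueError, match="align"):
        mechanism.junction_edits(
            random_seq(rng, 60), random_seq(rng, 60), random_seq(rng, 60)
        )
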