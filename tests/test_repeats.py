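"""Repeat detectors against independent brute-force oracles."""

import re

import numpy as np
import pytest

import mitoforms as mf
from mitoforms.genome import CircularSequence, revcomp
from mitoforms.repeats import (
    DEFAULT_SSR_THRESHOLDS,
    classify_orientation,
    find_dispersed_repeats,
    find_repeat_pairs,
    find_ssrs,
)

# ---------------------------------------------------------------------------
# SSR oracle: one backreference regex per motif length, minimal-period filter
# ---------------------------------------------------------------------------


def _minimal_period(s: str) -> int:
    for p in range(1, len(s) + 1):
        if all(s[i] == s[i - p] for i in range(p, len(s))):
            return p
    return len(s)


def ssr_oracle(seq: str, thresholds=DEFAULT_SSR_THRESHOLDS) -> set:
    found = set()
    for m, thr in thresholds.items():
        for match in re.finditer(rf"([ACGT]{{{m}}})\1{{{thr - 1},}}", seq):
            s, e = match.span()
            count = (e - s) // m
            run = seq[s : s + count * m]
            if _minimal_period(run) != m:
                continue
            found.add((s + 1, s + count * m, seq[s : s + m]))
    return found


def test_ssr_below_threshold_not_reported():
    rng = np.random.default_rng(0)
    flank = mf.random_sequence(200, 0.5, rng).replace("C", "A")
    c = CircularSequence("t", flank[:100] + "C" * 9 + flank[100:])
    assert find_ssrs(c) == []


def test_ssr_planted_tetranucleotide():
    # GC-only flanks cannot extend or phase-shift the planted ACGT run
    c = CircularSequence("t", "GGCCGGCCGG" + "ACGT" * 5 + "GGCCGGCCGG")
    recs = find_ssrs(c)
    assert len(recs) == 1
    r = recs[0]
    assert (r.motif, r.repeat_count, r.start, r.end) == ("ACGT", 5, 11, 30)
    assert r.end - r.start + 1 == r.motif_length * r.repeat_count


def test_ssr_run_assigned_shortest_period():
    c = CircularSequence("t", "GGCCGGCC" + "AT" * 8 + "GGCCGGCC")
    recs = find_ssrs(c)
    assert len(recs) == 1
    assert recs[0].motif_length == 2 and recs[0].motif == "AT"


def test_ssr_compound_tagging():
    rng = np.random.default_rng(3)
    gap = "GC" * 25  # 50 bp < default compound_gap
    far = mf.random_sequence(300, 0.5, rng)
    c = CircularSequence("t", "A" * 12 + gap + "TTG" * 6 + far + "CAGT" * 5)
    recs = find_ssrs(c)
    tags = {r.motif: r.compound_id for r in recs}
    assert tags["A"] is not None and tags["A"] == tags["TTG"]
    assert tags["CAGT"] is None


def test_ssr_matches_regex_oracle_on_random_sequences():
    rng = np.random.default_rng(42)
    for seed in range(100):
        seq = mf.random_sequence(5_000, float(rng.uniform(0.3, 0.7)), rng)
        got = {(r.start, r.end, r.motif) for r in find_ssrs(CircularSequence("s", seq))}
        assert got == ssr_oracle(seq), f"seed {seed}"


def test_ssr_empty_sequence_like_input():
    assert find_ssrs(CircularSequence("e", "A")) == []


# ---------------------------------------------------------------------------
# Dispersed repeats: exhaustive diagonal-scan oracle
# ---------------------------------------------------------------------------


def _diagonal_runs(a: np.ndarray, b: np.ndarray, min_len: int):
    """All maximal equal runs between every alignment of a against b."""
    n, m = len(a), len(b)
    for d in range(-(n - 1), m):
        lo = max(0, -d)
        hi = min(n, m - d)
        if hi - lo < min_len:
            continue
        eq = a[lo:hi] == b[lo + d : hi + d]
        # maximal True runs
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for s, e in zip(idx[::2], idx[1::2]):
            if e - s >= min_len:
                yield lo + s, lo + s + d, e - s


def dispersed_oracle(seq: str, min_len: int) -> set:
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(a)
    out = set()

    def emit(a1, b1, a2, b2, cat):
        if (a1, b1) == (a2, b2):
            return
        if (a1, b1) > (a2, b2):
            a1, b1, a2, b2 = a2, b2, a1, b1
        if a2 < b1:
            return
        out.add((a1 + 1, b1, a2 + 1, b2, cat))

    transforms = {
        "forward": seq,
        "palindromic": revcomp(seq),
        "reverse": seq[::-1],
        "complement": seq.translate(str.maketrans("ACGTN", "TGCAN")),
    }
    for cat, t in transforms.items():
        b = np.frombuffer(t.encode(), dtype=np.uint8)
        for i, j, l in _diagonal_runs(a, b, min_len):
            if cat in ("palindromic", "reverse"):
                emit(i, i + l, n - j - l, n - j, cat)
            else:
                emit(i, i + l, j, j + l, cat)
    return out


def test_dispersed_planted_forward_duplication():
    rng = np.random.default_rng(5)
    seq = mf.random_sequence(2_000, 0.45, rng)
    dup = seq[:1200] + seq[500:600] + seq[1300:]
    reps = find_dispersed_repeats(CircularSequence("d", dup), min_len=30)
    fwd = [r for r in reps if r.category == "forward" and r.length >= 100]
    assert len(fwd) == 1
    r = fwd[0]
    assert r.iv1.start <= 501 and r.iv1.end >= 600
    assert r.iv2.start <= 1201 and r.iv2.end >= 1300


def test_dispersed_planted_palindromic_copy():
    rng = np.random.default_rng(6)
    seq = mf.random_sequence(2_000, 0.45, rng)
    dup = seq[:1200] + revcomp(seq[500:600]) + seq[1300:]
    reps = find_dispersed_repeats(CircularSequence("d", dup), min_len=30)
    pal = [r for r in reps if r.category == "palindromic" and r.length >= 100]
    assert len(pal) == 1


def test_dispersed_matches_exhaustive_oracle():
    rng = np.random.default_rng(77)
    for seed in range(50):
        length = int(rng.integers(500, 2_000))
        seq = mf.random_sequence(length, 0.5, rng)
        if seed % 3 == 0:  # plant a longer repeat so non-trivial cases occur
            src = int(rng.integers(0, length - 80))
            dst = int(rng.integers(0, length - 80))
            frag = seq[src : src + 40]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            seq = seq[:dst] + frag + seq[dst + 40 :]
        got = {
            (r.iv1.start, r.iv1.end, r.iv2.start, r.iv2.end, r.category)
            for r in find_dispersed_repeats(CircularSequence("s", seq), min_len=9)
        }
        assert got == dispersed_oracle(seq, 9), f"seed {seed}"


def test_dispersed_sorted_by_length_descending():
    rng = np.random.default_rng(8)
    seq = mf.random_sequence(3_000, 0.45, rng)
    seq = seq[:1000] + seq[200:260] + seq[1060:2000] + seq[500:540] + seq[2040:]
    reps = find_dispersed_repeats(CircularSequence("d", seq), min_len=20)
    lengths = [r.length for r in reps]
    assert lengths == sorted(lengths, reverse=True)


def test_dispersed_min_len_validated():
    with pytest.raises(ValueError):
        find_dispersed_repeats(CircularSequence("x", "ACGT" * 10), min_len=4)


# ---------------------------------------------------------------------------
# Paired repeats (recombination substrates)
# ---------------------------------------------------------------------------


def test_repeat_pairs_recover_planted_direct_pair():
    spec = mf.SimulationSpec(
        seed=21,
        genome_length=40_000,
        gc=0.44,
        repeat_plan=[mf.RepeatPlan(253, 94.0, "direct", 8_000, 25_000)],
    )
    g, _ = mf.generate_genome(spec)
    pairs = find_repeat_pairs(g, evalue_max=1e-5)
    assert len(pairs) == 1
    p = pairs[0]
    assert p.orientation == "direct"
    assert abs(p.identity - 94.0) <= 2.0
    assert p.iv1.start <= 8_000 <= p.iv1.end or p.iv1.start >= 7_900
    assert p.alignment_length >= 250


def test_repeat_pairs_recover_planted_inverted_pair():
    spec = mf.SimulationSpec(
        seed=22,
        genome_length=40_000,
        gc=0.44,
        repeat_plan=[mf.RepeatPlan(150, 97.0, "inverted", 5_000, 30_000)],
    )
    g, _ = mf.generate_genome(spec)
    pairs = find_repeat_pairs(g, evalue_max=1e-5)
    assert len(pairs) == 1
    assert pairs[0].orientation == "inverted"


def test_repeat_pair_spanning_origin_is_found():
    from mitoforms.genome import rotate

    spec = mf.SimulationSpec(
        seed=23,
        genome_length=30_000,
        gc=0.44,
        repeat_plan=[mf.RepeatPlan(200, 98.0, "direct", 10_000, 20_000)],
    )
    g, _ = mf.generate_genome(spec)
    # rotate so the second copy (0-based [19999, 20199)) crosses the origin
    g = CircularSequence("rot", rotate(g.seq, 20_099))
    pairs = find_repeat_pairs(g, evalue_max=1e-5)
    assert len(pairs) == 1
    assert {iv.wraps for p in pairs for iv in (p.iv1, p.iv2)} == {False, True}


def test_repeat_pair_identity_consistent_with_stored_alignment():
    spec = mf.SimulationSpec(
        seed=24,
        genome_length=30_000,
        gc=0.44,
        repeat_plan=[
            mf.RepeatPlan(253, 94.0, "direct", 5_000, 15_000),
            mf.RepeatPlan(100, 96.0, "inverted", 9_000, 22_000),
        ],
    )
    g, _ = mf.generate_genome(spec)
    for p in find_repeat_pairs(g, evalue_max=1e-5):
        cols = len(p.aligned1)
        matches = sum(
            1 for a, b in zip(p.aligned1, p.aligned2) if a == b and a != "-"
        )
        assert cols == p.alignment_length
        assert abs(p.identity - 100.0 * matches / cols) < 0.01
        assert not p.iv1.overlaps(p.iv2, g.length)


def test_classify_orientation_from_strands(planted_genome):
    circle, manifest = planted_genome
    p = mf.repeat_pairs_from_manifest(circle, manifest)[0]
    assert classify_orientation(p) == "direct"
    p.iv2 = mf.GenomeInterval(p.iv2.start, p.iv2.end, "-")
    assert classify_orientation(p) == "inverted"
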