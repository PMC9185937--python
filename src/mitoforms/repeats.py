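"""Repeat discovery on a circular mitogenome.

Three repeat classes matter for organelle genome structure, and each gets
its own detector:

* **Microsatellites (SSRs)** — perfect tandem repeats of 1–6 bp motifs,
  found with MISA-style rules: per-motif-length minimum repeat counts
  (defaults 1-10 2-6 3-5 4-5 5-5 6-5), runs assigned their shortest period,
  and SSRs closer than ``compound_gap`` tagged as one compound.
* **Dispersed repeats** — maximal exact repeated pairs (forward,
  palindromic, reverse, complement), the REPuter categories. These are the
  raw substrate inventory for rearrangement.
* **Paired repeats** — scored local self-alignments of the circle
  (seed-and-extend, e-value filtered). Near-identical copies long enough to
  align significantly are the candidate substrates for repeat-mediated
  homologous recombination; direct pairs can split the circle, inverted
  pairs can flip the intervening segment.

SSR and dispersed-repeat scans treat the sequence as linear (deposited
orientation); paired-repeat search uses a doubled sequence so copies
spanning the origin are still found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import LocalHit, SeedExtendAligner
from .genome import CircularSequence, GenomeInterval, complement, revcomp

__all__ = [
    "SSRRecord",
    "DispersedRepeat",
    "RepeatPair",
    "DEFAULT_SSR_THRESHOLDS",
    "find_ssrs",
    "find_dispersed_repeats",
    "find_repeat_pairs",
    "classify_orientation",
]

DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass
class SSRRecord:
    motif: str
    motif_length: int
    repeat_count: int
    start: int  # 1-based inclusive
    end: int
    compound_id: str | None = None

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class DispersedRepeat:
    iv1: GenomeInterval
    iv2: GenomeInterval
    category: str  # forward | palindromic | reverse | complement
    length: int
    exact: bool = True


@dataclass
class RepeatPair:
    """Two near-identical repeat copies, candidate recombination substrate."""

    name: str
    iv1: GenomeInterval
    iv2: GenomeInterval
    orientation: str  # direct | inverted
    identity: float  # percent
    alignment_length: int  # columns incl. gaps; may exceed coordinate spans
    evalue: float
    score: float
    seq1: str = field(repr=False, default="")
    seq2: str = field(repr=False, default="")
    aligned1: str = field(repr=False, default="")
    aligned2: str = field(repr=False, default="")


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def _minimal_period(s: str) -> int:
    n = len(s)
    for p in range(1, n + 1):
        if all(s[i] == s[i - p] for i in range(p, n)):
            return p
    return n


def find_ssrs(
    c: CircularSequence,
    thresholds: dict[int, int] | None = None,
    compound_gap: int = 100,
) -> list[SSRRecord]:
    """Perfect SSRs (motifs 1–6 bp) under MISA-style minimum-count rules.

    A run is reported at its shortest period only (``ATATATATATAT`` is a
    dinucleotide SSR, never a tetranucleotide one), counted in whole motif
    units, and runs containing N are ignored. SSRs whose gap is at most
    ``compound_gap`` bp share a ``compound_id`` tag (they are tagged, not
    merged). Output is sorted by start.
    """
    thresholds = dict(DEFAULT_SSR_THRESHOLDS if thresholds is None else thresholds)
    s = c.seq
    n = len(s)
    records: list[SSRRecord] = []
    for m in range(1, 7):
        thr = thresholds.get(m)
        if thr is None:
            raise ValueError(f"no SSR threshold for motif length {m}")
        k = m
        while k < n:
            if s[k] != s[k - m] or s[k] == "N":
                k += 1
                continue
            # maximal stretch of positions matching m back
            a = k
            while k < n and s[k] == s[k - m] and s[k] != "N":
                k += 1
            run_start = a - m
            run_len = (k - a) + m
            count = run_len // m
            if count < thr:
                continue
            region = s[run_start : run_start + count * m]
            if "N" in region:
                continue
            if _minimal_period(region) != m:
                continue  # reported at the shorter period
            records.append(
                SSRRecord(
                    motif=s[run_start : run_start + m],
                    motif_length=m,
                    repeat_count=count,
                    start=run_start + 1,
                    end=run_start + count * m,
                )
            )
    records.sort(key=lambda r: (r.start, r.motif_length))
    # compound tagging
    cid = 0
    i = 0
    while i < len(records):
        j = i
        while (
            j + 1 < len(records)
            and records[j + 1].start - records[j].end - 1 <= compound_gap
        ):
            j += 1
        if j > i:
            cid += 1
            for r in records[i : j + 1]:
                r.compound_id = f"c{cid}"
        i = j + 1
    return records


# ---------------------------------------------------------------------------
# Dispersed maximal repeats
# ---------------------------------------------------------------------------


def _maximal_exact_pairs(s: str, t: str, k: int, skip_identity: bool = False):
    """Maximal exact matching segments between s and t (k-mer seeded).

    Yields (i, j, length) triples, each maximal (not extendable either way).
    N never matches. ``skip_identity`` drops i == j seeds — mandatory when
    s is t (self-comparison), where the trivial self-match would otherwise
    extend across the whole sequence from every position.
    """
    index: dict[str, list[int]] = {}
    for j in range(len(t) - k + 1):
        w = t[j : j + k]
        if "N" not in w:
            index.setdefault(w, []).append(j)
    seen: set[tuple[int, int, int]] = set()
    for i in range(len(s) - k + 1):
        w = s[i : i + k]
        if "N" in w:
            continue
        for j in index.get(w, ()):
            if skip_identity and i == j:
                continue
            # extend left
            a, b = i, j
            while a > 0 and b > 0 and s[a - 1] == t[b - 1] and s[a - 1] != "N":
                a -= 1
                b -= 1
            # extend right
            e1, e2 = i + k, j + k
            while (
                e1 < len(s) and e2 < len(t) and s[e1] == t[e2] and s[e1] != "N"
            ):
                e1 += 1
                e2 += 1
            key = (a, b, e1 - a)
            if key not in seen:
                seen.add(key)
                yield key


def find_dispersed_repeats(
    c: CircularSequence,
    min_len: int = 30,
    categories: tuple[str, ...] = ("forward", "palindromic", "reverse", "complement"),
) -> list[DispersedRepeat]:
    """Maximal exact dispersed repeats of length >= ``min_len``.

    Categories follow the REPuter convention: forward (copy on the same
    strand), palindromic (reverse complement), reverse (reversed only) and
    complement (complemented only). Self-matches and pairs whose copies
    overlap (tandem/SSR-internal shifts) are excluded; each unordered pair
    is reported once, sorted by length descending.
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    s = c.seq
    n = len(s)
    out: list[DispersedRepeat] = []
    seen: set[tuple] = set()

    def emit(a1: int, b1: int, a2: int, b2: int, category: str):
        # 0-based half-open -> 1-based inclusive; order copies by start
        if (a1, b1) == (a2, b2):
            return  # self-match
        if (a1, b1) > (a2, b2):
            a1, b1, a2, b2 = a2, b2, a1, b1
        if a2 < b1:
            return  # overlapping copies: tandem-internal, not dispersed
        key = (a1, b1, a2, b2, category)
        if key in seen:
            return
        seen.add(key)
        out.append(
            DispersedRepeat(
                iv1=GenomeInterval(a1 + 1, b1),
                iv2=GenomeInterval(a2 + 1, b2),
                category=category,
                length=b1 - a1,
            )
        )

    for cat in categories:
        if cat == "forward":
            for i, j, l in _maximal_exact_pairs(s, s, min_len, skip_identity=True):
                emit(i, i + l, j, j + l, cat)
        elif cat == "palindromic":
            t = revcomp(s)
            for i, j, l in _maximal_exact_pairs(s, t, min_len):
                emit(i, i + l, n - j - l, n - j, cat)
        elif cat == "reverse":
            t = s[::-1]
            for i, j, l in _maximal_exact_pairs(s, t, min_len):
                emit(i, i + l, n - j - l, n - j, cat)
        elif cat == "complement":
            t = complement(s)
            for i, j, l in _maximal_exact_pairs(s, t, min_len):
                emit(i, i + l, j, j + l, cat)
        else:
            raise ValueError(f"unknown category {cat!r}")
    out.sort(key=lambda r: (-r.length, r.iv1.start, r.iv2.start, r.category))
    return out


# ---------------------------------------------------------------------------
# Paired repeats (recombination substrates)
# ---------------------------------------------------------------------------


def classify_orientation(p: RepeatPair) -> str:
    """direct iff both copies align on the same strand, inverted otherwise."""
    return "direct" if p.iv1.strand == p.iv2.strand else "inverted"


def _mod_interval(start: int, end: int, L: int, strand: str) -> GenomeInterval:
    """Map a 0-based half-open interval on the doubled sequence onto the circle."""
    s = start % L
    e = end % L
    if e == 0:
        e = L
    return GenomeInterval(s + 1, e, strand)


def find_repeat_pairs(
    c: CircularSequence,
    evalue_max: float = 1e-5,
    word_size: int = 11,
    aligner: SeedExtendAligner | None = None,
) -> list[RepeatPair]:
    """Significant repeat pairs from local self-alignment of the circle.

    The circle is compared against its doubled self (so copies spanning the
    origin are found), on both strands; the trivial self-hit is excluded,
    pairs whose copies overlap are dropped, and overlapping candidates for
    the same locus pair are pruned greedily by score. Pairs are named R1,
    R2, ... in score order (ties broken by leftmost coordinate).
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be > 0")
    L = c.length
    s = c.seq
    doubled = s + s
    if aligner is None:
        aligner = SeedExtendAligner(word_size=word_size)
    hits = aligner.search(
        s,
        doubled,
        evalue_max=evalue_max,
        both_strands=True,
        skip_diag=lambda d: d % L == 0,
        m=L,
        n=L,
    )
    candidates: list[RepeatPair] = []
    seen: set[tuple] = set()
    for h in hits:
        iv_q = GenomeInterval(h.q_start + 1, h.q_end, "+")
        iv_t = _mod_interval(h.t_start, h.t_end, L, h.strand)
        # canonical unordered key so each pair appears once
        k1 = (iv_q.start, iv_q.end, iv_q.strand)
        k2 = (iv_t.start, iv_t.end, iv_t.strand)
        key = (min(k1, k2), max(k1, k2))
        if key in seen:
            continue
        seen.add(key)
        iv1, iv2 = (iv_q, iv_t) if k1 <= k2 else (iv_t, iv_q)
        if iv1.overlaps(iv2, L):
            continue
        pair = RepeatPair(
            name="",
            iv1=iv1,
            iv2=iv2,
            orientation="direct" if iv1.strand == iv2.strand else "inverted",
            identity=round(h.identity, 2),
            alignment_length=h.columns,
            evalue=h.evalue,
            score=h.score,
            aligned1=h.aligned_q,
            aligned2=h.aligned_t,
        )
        candidates.append(pair)
    # greedy pruning of overlapping candidate pairs (same locus pair found
    # at different extents): keep the best-scoring representative
    candidates.sort(key=lambda p: (-p.score, p.iv1.start, p.iv2.start))
    kept: list[RepeatPair] = []
    for p in candidates:
        redundant = any(
            (p.iv1.overlaps(q.iv1, L) and p.iv2.overlaps(q.iv2, L))
            or (p.iv1.overlaps(q.iv2, L) and p.iv2.overlaps(q.iv1, L))
            for q in kept
        )
        if not redundant:
            kept.append(p)
    from .genome import extract_subsequence

    for idx, p in enumerate(kept, start=1):
        p.name = f"R{idx}"
        p.seq1 = extract_subsequence(c, p.iv1)
        p.seq2 = extract_subsequence(c, p.iv2)
    return kept
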