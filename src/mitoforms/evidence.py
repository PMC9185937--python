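"""Long-read evidence for repeat-mediated recombination.

For each candidate repeat pair, four template sequences are built: the two
reference arrangements (each copy with its own flanks) and the two
recombinant arrangements obtained by exchanging the downstream flanks:

    ref1 = up1 + R1 + down1        rec1 = up1 + R1 + down2
    ref2 = up2 + R2 + down2        rec2 = up2 + R2 + down1

Flanks default to 1000 bp taken on the circle; when the arc between the two
copies is shorter than the requested flank, the flank is truncated to the
available arc and flagged. A long read supports a template when it aligns
across the entire repeat plus at least ``anchor`` bp of flank on both sides
at sufficient identity — i.e. the read "passes through" the repeat and its
flanking context can discriminate which arrangement it came from. Each read
is assigned to at most one template (its unique best; ties unassigned), so
reference templates cannot absorb recombinant evidence and vice versa. A
repeat pair's recombination is called supported when at least
``min_support`` reads back either recombinant template.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import edlib

from .genome import CircularSequence, revcomp
from .repeats import RepeatPair

__all__ = [
    "TemplateSet",
    "SpanningSupport",
    "build_templates",
    "classify_spanning_reads",
    "classify_spanning_sam",
    "assess_all_pairs",
]

TEMPLATE_KEYS = ("ref1", "ref2", "rec1", "rec2")


@dataclass
class TemplateSet:
    repeat_name: str
    flank: int
    ref1: str
    ref2: str
    rec1: str
    rec2: str
    # per-template (upstream, repeat, downstream) provenance triples
    provenance: dict[str, tuple[str, str, str]] = field(repr=False, default_factory=dict)
    truncated: dict[str, int] = field(default_factory=dict)  # flank label -> realized bp

    def templates(self) -> dict[str, str]:
        return {k: getattr(self, k) for k in TEMPLATE_KEYS}

    def repeat_window(self, key: str, anchor: int) -> str:
        """Repeat ± ``anchor`` bp of a template: its discriminating region."""
        return self.window_parts(key, anchor)[0]

    def window_parts(self, key: str, anchor: int) -> tuple[str, int, int, int]:
        """(window, left-anchor bp, repeat bp, right-anchor bp)."""
        up, rep, down = self.provenance[key]
        la = min(anchor, len(up))
        ra = min(anchor, len(down))
        lo = len(up) - la
        hi = len(up) + len(rep) + ra
        return getattr(self, key)[lo:hi], la, len(rep), ra


@dataclass
class SpanningSupport:
    repeat_name: str
    counts: dict[str, int]
    read_ids: dict[str, list[str]] = field(repr=False, default_factory=dict)
    verdict: str = "unsupported"

    @property
    def recombinant_reads(self) -> int:
        return self.counts["rec1"] + self.counts["rec2"]

    @property
    def reference_reads(self) -> int:
        return self.counts["ref1"] + self.counts["ref2"]


class _CopyFrame:
    """One repeat copy in its repeat-aligned orientation on the circle.

    For a plus-strand copy, upstream/downstream are the genomic arcs before
    and after it; for a minus-strand copy (inverted pairs) the roles swap
    and the arcs are reverse-complemented, so both copies present the same
    local frame to template construction.
    """

    def __init__(self, c: CircularSequence, iv, other_iv):
        from .genome import circular_interval_length, extract_subsequence, GenomeInterval

        L = c.length
        self.repeat = extract_subsequence(c, iv)
        span = circular_interval_length(iv, L)
        start0 = iv.start - 1  # 0-based start on the plus strand
        # arcs to the other copy on either side (genomic orientation)
        other_span = circular_interval_length(other_iv, L)
        other_start0 = other_iv.start - 1
        gap_after = (other_start0 - (start0 + span)) % L
        gap_before = (start0 - ((other_start0 + other_span) % L)) % L
        doubled = c.seq + c.seq
        arc_after = doubled[start0 + span : start0 + span + gap_after]
        before_lo = (start0 - gap_before) % L
        arc_before = doubled[before_lo : before_lo + gap_before]
        if iv.strand == "+":
            self.genomic_up, self.genomic_down = arc_before, arc_after
        else:
            # repeat already oriented by extract_subsequence; arcs swap roles
            self.genomic_up, self.genomic_down = revcomp(arc_after), revcomp(arc_before)

    def up(self, flank: int) -> tuple[str, bool]:
        arc = self.genomic_up
        return arc[-flank:] if flank < len(arc) else arc, flank > len(arc)

    def down(self, flank: int) -> tuple[str, bool]:
        arc = self.genomic_down
        return arc[:flank], flank > len(arc)


def build_templates(c: CircularSequence, pair: RepeatPair, flank: int = 1000) -> TemplateSet:
    """The four reference/recombinant templates for one repeat pair."""
    if flank < 1:
        raise ValueError("flank must be >= 1")
    L = c.length
    if pair.iv1.overlaps(pair.iv2, L):
        raise UnsupportedTemplateError(
            f"repeat pair {pair.name}: overlapping copies have no template geometry"
        )
    f1 = _CopyFrame(c, pair.iv1, pair.iv2)
    f2 = _CopyFrame(c, pair.iv2, pair.iv1)
    up1, t_u1 = f1.up(flank)
    down1, t_d1 = f1.down(flank)
    up2, t_u2 = f2.up(flank)
    down2, t_d2 = f2.down(flank)
    ts = TemplateSet(
        repeat_name=pair.name,
        flank=flank,
        ref1=up1 + f1.repeat + down1,
        ref2=up2 + f2.repeat + down2,
        rec1=up1 + f1.repeat + down2,
        rec2=up2 + f2.repeat + down1,
        provenance={
            "ref1": (up1, f1.repeat, down1),
            "ref2": (up2, f2.repeat, down2),
            "rec1": (up1, f1.repeat, down2),
            "rec2": (up2, f2.repeat, down1),
        },
    )
    for label, truncated, realized in (
        ("up1", t_u1, len(up1)),
        ("down1", t_d1, len(down1)),
        ("up2", t_u2, len(up2)),
        ("down2", t_d2, len(down2)),
    ):
        if truncated:
            ts.truncated[label] = realized
    return ts


class UnsupportedTemplateError(ValueError):
    pass


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _covers_full_window_after_trim(ops) -> bool:
    """Reject alignments whose window bases fall outside the best-scoring
    local segment.

    edlib minimizes edit distance over the *whole* window, so a read that
    stops inside the window can absorb the uncovered bases as scattered
    insertions mixed with chance matches. A score-maximizing local aligner
    would trim that junk away; here the CIGAR runs are scored (match +2,
    mismatch 0, affine gaps −5 −2/bp) and the maximal-scoring run segment
    is found — if any window-consuming run lies outside it, the read does
    not genuinely cover the window end to end.
    """
    scores = []
    for n_str, op in ops:
        n = int(n_str)
        if op in ("=", "M"):
            scores.append(2 * n)
        elif op == "X":
            scores.append(0)
        else:  # I or D
            scores.append(-(5 + 2 * n))
    best_val, bi, bj = float("-inf"), 0, -1
    cur, start = 0, 0
    for idx, s in enumerate(scores):
        if cur < 0:
            cur, start = s, idx
        else:
            cur += s
        if cur >= best_val:
            best_val, bi, bj = cur, start, idx
    for k, (n_str, op) in enumerate(ops):
        if (k < bi or k > bj) and op in ("=", "X", "I", "M"):
            return False
    return True


def _window_alignment_ok(
    cigar: str, la: int, lr: int, ra: int, min_identity: float
) -> bool:
    """Does this window-to-read alignment truly span the repeat?

    Two conditions, walking the edlib CIGAR of window (query) vs read:

    * the window is covered end to end — a terminal run of unmatched window
      bases ('I' at a CIGAR boundary) means the read stopped inside the
      window;
    * each region — left anchor, repeat, right anchor — aligns at identity
      >= ``min_identity`` on its own, so a read cannot buy a mismatching
      flank with surplus identity from a long repeat.
    """
    ops = _CIGAR_RE.findall(cigar)
    if not ops or ops[0][1] == "I" or ops[-1][1] == "I":
        return False
    if not _covers_full_window_after_trim(ops):
        return False
    bounds = (la, la + lr, la + lr + ra)
    edits = [0, 0, 0]
    q = 0
    for n_str, op in ops:
        n = int(n_str)
        if op in ("=", "M"):
            q += n
        elif op in ("X", "I"):
            # split the run across region boundaries by query position
            for _ in range(n):
                region = 0 if q < bounds[0] else (1 if q < bounds[1] else 2)
                edits[region] += 1
                q += 1
        elif op == "D":
            region = 0 if q < bounds[0] else (1 if q < bounds[1] else 2)
            edits[region] += n
    for region, ln in enumerate((la, lr, ra)):
        if ln and 1 - edits[region] / ln < min_identity:
            return False
    return True


def _load_reads(reads) -> list[tuple[str, str]]:
    if isinstance(reads, (str, Path)):
        from .io import read_fastq

        return read_fastq(reads)
    return list(reads)


def classify_spanning_reads(
    reads,
    ts: TemplateSet,
    anchor: int = 100,
    min_identity: float = 0.70,
    min_support: int = 2,
) -> SpanningSupport:
    """Assign spanning reads to the unique template they support.

    ``reads`` is a FASTQ path or an iterable of (id, sequence) pairs. For
    each template the discriminating window (repeat ± anchor) is aligned
    into the read (semi-global, both read strands, edlib); a read is
    eligible for a template when the whole window aligns at identity >=
    ``min_identity``, and it is counted for the single template with the
    lowest edit distance (margin >= 1; ties discard the read).
    """
    if anchor < 1:
        raise ValueError("anchor must be >= 1")
    if not (0 < min_identity <= 1):
        raise ValueError("min_identity must be in (0, 1]")
    windows = {k: ts.window_parts(k, anchor) for k in TEMPLATE_KEYS}
    if any(not w[0] for w in windows.values()):
        raise ValueError("empty template window")
    counts = {k: 0 for k in TEMPLATE_KEYS}
    read_ids: dict[str, list[str]] = {k: [] for k in TEMPLATE_KEYS}
    for rid, seq in _load_reads(reads):
        rc = revcomp(seq)
        dists: dict[str, int] = {}
        for key, (w, la, lr, ra) in windows.items():
            k_max = int((1 - min_identity) * len(w))
            best = -1
            for target in (seq, rc):
                if len(target) < len(w):
                    continue
                res = edlib.align(w, target, mode="HW", task="path", k=k_max)
                d = res["editDistance"]
                if d == -1 or not _window_alignment_ok(
                    res["cigar"], la, lr, ra, min_identity
                ):
                    continue
                if best == -1 or d < best:
                    best = d
            if best != -1:
                dists[key] = best
        if not dists:
            continue
        ranked = sorted(dists.items(), key=lambda kv: (kv[1], kv[0]))
        if len(ranked) > 1 and ranked[1][1] - ranked[0][1] < 1:
            continue  # ambiguous: margin < 1
        winner = ranked[0][0]
        counts[winner] += 1
        read_ids[winner].append(rid)
    support = SpanningSupport(ts.repeat_name, counts, read_ids)
    if counts["rec1"] >= min_support or counts["rec2"] >= min_support:
        support.verdict = "supported"
    return support


def classify_spanning_sam(
    sam_path,
    ts: TemplateSet,
    anchor: int = 100,
    min_identity: float = 0.70,
    min_support: int = 2,
) -> SpanningSupport:
    """Classify precomputed alignments against a pair's templates.

    ``sam_path`` holds reads aligned to the four templates (reference names
    ``<pair>__ref1`` … as written by the ``templates`` command, or plain
    ``ref1`` …). A read supports a template when one of its alignments
    covers the repeat ± anchor region of that template at NM-based identity
    >= ``min_identity``; reads meeting this for more than one template are
    discarded as ambiguous.
    """
    import pysam

    regions = {}
    for key in TEMPLATE_KEYS:
        up, rep, down = ts.provenance[key]
        lo = max(0, len(up) - min(anchor, len(up)))
        hi = len(up) + len(rep) + min(anchor, len(down))
        regions[key] = (lo, hi)
    per_read: dict[str, set[str]] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            key = rec.reference_name.rsplit("__", 1)[-1]
            if key not in regions:
                continue
            lo, hi = regions[key]
            if rec.reference_start > lo or rec.reference_end < hi:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            span = rec.reference_end - rec.reference_start
            if span <= 0 or 1 - nm / span < min_identity:
                continue
            per_read.setdefault(rec.query_name, set()).add(key)
    counts = {k: 0 for k in TEMPLATE_KEYS}
    read_ids: dict[str, list[str]] = {k: [] for k in TEMPLATE_KEYS}
    for rid, keys in sorted(per_read.items()):
        if len(keys) != 1:
            continue
        key = next(iter(keys))
        counts[key] += 1
        read_ids[key].append(rid)
    support = SpanningSupport(ts.repeat_name, counts, read_ids)
    if counts["rec1"] >= min_support or counts["rec2"] >= min_support:
        support.verdict = "supported"
    return support


def assess_all_pairs(
    c: CircularSequence,
    pairs: list[RepeatPair],
    reads,
    flank: int = 1000,
    anchor: int = 100,
    min_identity: float = 0.70,
    min_support: int = 2,
) -> list[SpanningSupport]:
    """Spanning-read support for every repeat pair.

    Returns one SpanningSupport per pair, supported pairs first, sorted by
    recombinant read count descending.
    """
    loaded = _load_reads(reads)
    out = []
    for pair in pairs:
        ts = build_templates(c, pair, flank=flank)
        out.append(
            classify_spanning_reads(
                loaded, ts, anchor=anchor, min_identity=min_identity, min_support=min_support
            )
        )
    out.sort(key=lambda s: (s.verdict != "supported", -s.recombinant_reads, s.repeat_name))
    return out
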