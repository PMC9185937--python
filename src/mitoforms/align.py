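"""Seed-and-extend local alignment with a Karlin–Altschul e-value model.

This is the workhorse behind paired-repeat discovery on a single circle and
mito-vs-chloroplast homology search. The procedure is the classic BLAST-like
pipeline:

1. exact word seeding (``word_size``-mers; words containing N are skipped);
2. ungapped X-drop extension of each seed, with per-diagonal deduplication;
3. clustering of surviving segments across nearby diagonals;
4. banded refinement of each cluster by local Smith–Waterman on a window
   (the DP kernel is Bio.Align.PairwiseAligner);
5. significance filtering with E = K·m·n·exp(−λS).

The scoring system is match +2 / mismatch −3, affine gaps costing
5 + 2·g for a gap of length g, with K = 0.41 and λ = 0.625. These constants
give BLASTN-like behaviour but exact parity with NCBI e-values is not a
goal; the e-value threshold is a tunable significance knob.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

from Bio import Align

from .genome import revcomp

__all__ = ["LocalHit", "SeedExtendAligner", "karlin_altschul_evalue"]


def karlin_altschul_evalue(
    score: float, m: int, n: int, K: float = 0.41, lam: float = 0.625
) -> float:
    """Expected number of chance local alignments scoring >= ``score``."""
    return K * m * n * math.exp(-lam * score)


@dataclass
class LocalHit:
    """One significant local alignment between query and target.

    Coordinates are 0-based half-open on the plus strand of each sequence;
    ``strand`` is the target strand the query matched. ``aligned_q`` /
    ``aligned_t`` store the gapped alignment rows so identity can always be
    recomputed as identities / columns.
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str
    score: float
    matches: int
    columns: int
    evalue: float
    aligned_q: str = field(repr=False, default="")
    aligned_t: str = field(repr=False, default="")

    @property
    def identity(self) -> float:
        """Percent identity over alignment columns (gaps count as columns)."""
        return 100.0 * self.matches / self.columns if self.columns else 0.0


class SeedExtendAligner:
    def __init__(
        self,
        word_size: int = 11,
        match: int = 2,
        mismatch: int = -3,
        gap_open: int = 5,
        gap_extend: int = 2,
        K: float = 0.41,
        lam: float = 0.625,
        xdrop: int = 20,
        ungapped_min_score: int = 28,
        band: int = 16,
        max_gap: int = 120,
        window_pad: int = 40,
        max_window: int = 20000,
    ):
        self.word_size = word_size
        self.match = match
        self.mismatch = mismatch
        self.K = K
        self.lam = lam
        self.xdrop = xdrop
        self.ungapped_min_score = ungapped_min_score
        self.band = band
        self.max_gap = max_gap
        self.window_pad = window_pad
        self.max_window = max_window
        self._sw = Align.PairwiseAligner()
        self._sw.mode = "local"
        self._sw.match_score = match
        self._sw.mismatch_score = mismatch
        self._sw.open_gap_score = -(gap_open + gap_extend)
        self._sw.extend_gap_score = -gap_extend

    # -- seeding ----------------------------------------------------------

    def _index(self, target: str) -> dict[str, list[int]]:
        k = self.word_size
        idx: dict[str, list[int]] = defaultdict(list)
        for j in range(len(target) - k + 1):
            w = target[j : j + k]
            if "N" not in w:
                idx[w].append(j)
        return idx

    def _seeds(self, query: str, index, skip_diag):
        k = self.word_size
        by_diag: dict[int, list[int]] = defaultdict(list)
        for i in range(len(query) - k + 1):
            w = query[i : i + k]
            if "N" in w:
                continue
            for j in index.get(w, ()):
                d = i - j
                if skip_diag is not None and skip_diag(d):
                    continue
                by_diag[d].append(i)
        return by_diag

    # -- ungapped extension -----------------------------------------------

    def _ungapped_extend(self, q: str, t: str, i: int, j: int) -> tuple[int, int, int]:
        """X-drop extend an exact word at (i, j); returns (q_lo, q_hi, score).

        The returned segment is trimmed to the maximum-score prefix/suffix.
        N never scores as a match.
        """
        k = self.word_size
        score = k * self.match
        # right
        best, best_hi = score, i + k
        s = score
        qi, tj = i + k, j + k
        while qi < len(q) and tj < len(t):
            a, b = q[qi], t[tj]
            s += self.match if (a == b and a != "N") else self.mismatch
            if s > best:
                best, best_hi = s, qi + 1
            if best - s > self.xdrop:
                break
            qi += 1
            tj += 1
        # left
        score = best
        best2, best_lo = score, i
        s = score
        qi, tj = i - 1, j - 1
        while qi >= 0 and tj >= 0:
            a, b = q[qi], t[tj]
            s += self.match if (a == b and a != "N") else self.mismatch
            if s > best2:
                best2, best_lo = s, qi
            if best2 - s > self.xdrop:
                break
            qi -= 1
            tj -= 1
        return best_lo, best_hi, best2

    # -- clustering & SW refinement ---------------------------------------

    def _segments(self, q: str, t: str, skip_diag):
        index = self._index(t)
        segments = []  # (diag, q_lo, q_hi, score)
        for d, ilist in sorted(self._seeds(q, index, skip_diag).items()):
            ilist.sort()
            covered_to = -1
            for i in ilist:
                if i < covered_to:
                    continue
                lo, hi, sc = self._ungapped_extend(q, t, i, i - d)
                covered_to = hi
                if sc >= self.ungapped_min_score:
                    segments.append((d, lo, hi, sc))
        return segments

    def _clusters(self, segments):
        """Greedy single-linkage clustering over (diagonal, query-range)."""
        clusters: list[list[tuple[int, int, int, int]]] = []
        for seg in sorted(segments, key=lambda s: (s[1], s[0])):
            d, lo, hi, _ = seg
            placed = False
            for cl in clusters:
                for cd, clo, chi, _ in cl:
                    if abs(d - cd) <= self.band and not (
                        lo > chi + self.max_gap or hi < clo - self.max_gap
                    ):
                        cl.append(seg)
                        placed = True
                        break
                if placed:
                    break
            if not placed:
                clusters.append([seg])
        return clusters

    def _refine(self, q: str, t: str, cluster, m: int, n: int, strand: str):
        pad = self.window_pad + self.band
        q_lo = max(0, min(s[1] for s in cluster) - pad)
        q_hi = min(len(q), max(s[2] for s in cluster) + pad)
        t_lo = max(0, min(s[1] - s[0] for s in cluster) - pad)
        t_hi = min(len(t), max(s[2] - s[0] for s in cluster) + pad)
        if q_hi - q_lo > self.max_window or t_hi - t_lo > self.max_window:
            q_hi = min(q_hi, q_lo + self.max_window)
            t_hi = min(t_hi, t_lo + self.max_window)
        alns = self._sw.align(q[q_lo:q_hi], t[t_lo:t_hi])
        try:
            aln = alns[0]
        except IndexError:
            return None
        if aln.score <= 0 or len(aln.aligned[0]) == 0:
            return None
        counts = aln.counts()
        qa, ta = aln.aligned
        return LocalHit(
            q_start=q_lo + int(qa[0][0]),
            q_end=q_lo + int(qa[-1][1]),
            t_start=t_lo + int(ta[0][0]),
            t_end=t_lo + int(ta[-1][1]),
            strand=strand,
            score=float(aln.score),
            matches=int(counts.identities),
            columns=int(aln.length),
            evalue=karlin_altschul_evalue(aln.score, m, n, self.K, self.lam),
            aligned_q=str(aln[0]),
            aligned_t=str(aln[1]),
        )

    # -- public API --------------------------------------------------------

    def search(
        self,
        query: str,
        target: str,
        evalue_max: float = 1e-5,
        both_strands: bool = True,
        skip_diag=None,
        m: int | None = None,
        n: int | None = None,
    ) -> list[LocalHit]:
        """All local alignments of query vs target with E <= ``evalue_max``.

        ``m``/``n`` override the search-space sizes used in the e-value
        (callers aligning against a doubled circle pass the true lengths).
        ``skip_diag`` masks seed diagonals (i − j values) — used to drop the
        trivial self-match in self-comparison. Minus-strand hits report
        target coordinates on the plus strand.
        """
        m = m if m is not None else len(query)
        n = n if n is not None else len(target)
        hits: list[LocalHit] = []
        jobs = [("+", target, skip_diag)]
        if both_strands:
            jobs.append(("-", revcomp(target), None))
        for strand, tseq, skipper in jobs:
            segs = self._segments(query, tseq, skipper)
            for cl in self._clusters(segs):
                hit = self._refine(query, tseq, cl, m, n, strand)
                if hit is None or hit.evalue > evalue_max:
                    continue
                if strand == "-":
                    # map minus-strand coordinates back to the plus strand
                    hit.t_start, hit.t_end = (
                        len(target) - hit.t_end,
                        len(target) - hit.t_start,
                    )
                hits.append(hit)
        # deduplicate identical spans produced by overlapping clusters
        seen: set[tuple] = set()
        unique = []
        for h in sorted(hits, key=lambda h: (-h.score, h.q_start, h.t_start)):
            key = (h.q_start, h.q_end, h.t_start, h.t_end, h.strand)
            if key not in seen:
                seen.add(key)
                unique.append(h)
        return unique
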