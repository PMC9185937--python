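"""Repeat-mediated recombination algebra on circular molecules.

A plant mitogenome deposited as one master circle can rearrange through
homologous recombination between repeat copies:

* **fission** — crossing over between two *direct* copies on one circle
  splits it into two circles whose sizes are the start-to-start distance
  ``s2 − s1`` and ``L − (s2 − s1)``;
* **fusion** — the reverse: direct copies on two distinct circles merge
  them into one circle of summed length;
* **inversion** — crossing over between *inverted* copies on one circle
  reverse-complements the intervening segment; the circle count is
  unchanged.

Every mode conserves total sequence length. The crossover is placed at the
repeat midpoint (product *sizes* are independent of this choice; it only
fixes the product sequences deterministically). A conformation — a multiset
of circles — is identified by the canonical (rotation- and strand-
invariant) forms of its circles, so states reached by different event
orders deduplicate correctly.

Repeat copies are located on a conformation by near-exact search (edlib)
of the stored copy sequences, which keeps the algebra applicable to
derived conformations whose junction copies are midpoint hybrids of the
two original copies.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import edlib

from .genome import CircularSequence, canonicalize_circle, revcomp, rotate
from .repeats import RepeatPair

__all__ = [
    "Conformation",
    "RecombinationEvent",
    "RepeatLocationError",
    "AmbiguousRepeatError",
    "UnsupportedGeometryError",
    "apply_recombination",
    "enumerate_conformations",
    "conformation_summary",
]


class RepeatLocationError(ValueError):
    """A repeat copy could not be located on the conformation."""


class AmbiguousRepeatError(ValueError):
    """A repeat's copies were found at more than two distinct locations."""


class UnsupportedGeometryError(ValueError):
    """The located geometry admits no recombination mode (e.g. overlapping
    copies, or inverted copies split across two circles)."""


@dataclass(frozen=True)
class RecombinationEvent:
    repeat_name: str
    mode: str  # fission | fusion | inversion
    source_circles: tuple[str, ...]
    crossover_offset: int  # bp within the repeat


@dataclass
class Conformation:
    """A multiset of circular molecules plus the repeats applied to reach it."""

    circles: tuple[CircularSequence, ...]
    applied: frozenset[str] = frozenset()
    events: tuple[RecombinationEvent, ...] = ()
    label: str | None = None
    _key: tuple[str, ...] | None = field(default=None, repr=False, compare=False)

    def key(self) -> tuple[str, ...]:
        """Order-independent identity: sorted canonical circle sequences."""
        if self._key is None:
            self._key = tuple(sorted(_canonical(c.seq) for c in self.circles))
        return self._key

    @property
    def n_circles(self) -> int:
        return len(self.circles)

    def total_length(self) -> int:
        return sum(c.length for c in self.circles)


@functools.lru_cache(maxsize=512)
def _canonical(seq: str) -> str:
    return canonicalize_circle(seq)


# ---------------------------------------------------------------------------
# Copy location
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Site:
    circle_idx: int
    start: int  # 0-based on the circle; site may wrap (start+length > L)
    length: int
    strand: str
    edit_distance: int


def _search_circle(circle_seq: str, copy: str, max_ed: int) -> list[_Site]:
    """Best near-exact matches of ``copy`` on a circle (both strands, wrap-aware)."""
    L = len(circle_seq)
    doubled = circle_seq + circle_seq
    sites: list[tuple[int, int, str, int]] = []
    for strand, target in (("+", doubled), ("-", revcomp(doubled))):
        res = edlib.align(copy, target, mode="HW", task="locations", k=max_ed)
        if res["editDistance"] == -1:
            continue
        for st, en in res["locations"]:
            en += 1  # edlib end is inclusive
            if strand == "-":
                st, en = len(doubled) - en, len(doubled) - st
            sites.append((st % L, en - st, strand, res["editDistance"]))
    # collapse duplicates (the doubled sequence reports each site twice, and
    # edlib may report several optimal end points for one site)
    sites.sort(key=lambda s: (s[0], s[3]))
    merged: list[tuple[int, int, str, int]] = []
    for s in sites:
        if merged and abs(s[0] - merged[-1][0]) < max(len(copy) // 2, 1):
            if s[3] < merged[-1][3]:
                merged[-1] = s
            continue
        merged.append(s)
    return [_Site(-1, st, ln, strand, ed) for (st, ln, strand, ed) in merged]


def _locate_pair(
    conf: Conformation, pair: RepeatPair, max_divergence: float = 0.15
) -> list[_Site]:
    """The two distinct locations of a repeat pair's copies on a conformation."""
    if not pair.seq1 or not pair.seq2:
        raise ValueError(f"repeat pair {pair.name} carries no copy sequences")
    found: list[_Site] = []
    for ci, circ in enumerate(conf.circles):
        for copy in (pair.seq1, pair.seq2):
            if len(copy) > circ.length:
                continue
            max_ed = max(3, int(max_divergence * len(copy)))
            for s in _search_circle(circ.seq, copy, max_ed):
                found.append(replace(s, circle_idx=ci))
    # merge sites found by both copy searches at the same place
    found.sort(key=lambda s: (s.circle_idx, s.start, s.edit_distance))
    distinct: list[_Site] = []
    for s in found:
        if (
            distinct
            and s.circle_idx == distinct[-1].circle_idx
            and abs(s.start - distinct[-1].start) < max(s.length // 2, 1)
        ):
            continue
        distinct.append(s)
    if len(distinct) < 2:
        raise RepeatLocationError(
            f"repeat pair {pair.name}: found {len(distinct)} copy location(s), need 2"
        )
    if len(distinct) > 2:
        raise AmbiguousRepeatError(
            f"repeat pair {pair.name}: found {len(distinct)} copy locations"
        )
    return distinct


# ---------------------------------------------------------------------------
# The three recombination modes
# ---------------------------------------------------------------------------


def apply_recombination(
    conf: Conformation, pair: RepeatPair, max_divergence: float = 0.15
) -> Conformation:
    """Apply one recombination event through ``pair`` and return the new state.

    The mode is dictated by the located geometry: direct copies co-resident
    on one circle recombine by fission, direct copies on two circles by
    fusion, inverted copies on one circle by inversion. Total length is
    conserved in every mode.
    """
    a, b = _locate_pair(conf, pair, max_divergence)
    same_circle = a.circle_idx == b.circle_idx
    direct = a.strand == b.strand
    crossover = min(a.length, b.length) // 2
    if same_circle:
        circ = conf.circles[a.circle_idx]
        L = circ.length
        # rotate so the first copy starts at 0 and neither site wraps
        first, second = (a, b) if a.start <= b.start else (b, a)
        seq = rotate(circ.seq, first.start)
        s2 = (second.start - first.start) % L
        if s2 < first.length or s2 + second.length > L:
            raise UnsupportedGeometryError(
                f"repeat pair {pair.name}: overlapping copies"
            )
        others = [c for i, c in enumerate(conf.circles) if i != a.circle_idx]
        if direct:
            mode = "fission"
            c = crossover
            arc1 = seq[c : s2 + c]
            arc2 = seq[s2 + c :] + seq[:c]
            products = [
                CircularSequence(f"{circ.id}|{pair.name}.a", arc1),
                CircularSequence(f"{circ.id}|{pair.name}.b", arc2),
            ]
        else:
            mode = "inversion"
            c = crossover
            e2 = s2 + second.length
            inverted = seq[:c] + revcomp(seq[c : e2 - c]) + seq[e2 - c :]
            products = [CircularSequence(f"{circ.id}|{pair.name}.inv", inverted)]
        event = RecombinationEvent(pair.name, mode, (circ.id,), crossover)
        new_circles = tuple(others + products)
    else:
        if not direct:
            raise UnsupportedGeometryError(
                f"repeat pair {pair.name}: inverted copies on two circles "
                "cannot recombine into a circular product"
            )
        mode = "fusion"
        ca, cb = conf.circles[a.circle_idx], conf.circles[b.circle_idx]
        fused_seq = rotate(ca.seq, (a.start + crossover) % ca.length) + rotate(
            cb.seq, (b.start + crossover) % cb.length
        )
        fused = CircularSequence(f"{ca.id}+{cb.id}|{pair.name}", fused_seq)
        others = [
            c
            for i, c in enumerate(conf.circles)
            if i not in (a.circle_idx, b.circle_idx)
        ]
        event = RecombinationEvent(pair.name, mode, (ca.id, cb.id), crossover)
        new_circles = tuple(others + [fused])
    new = Conformation(
        circles=new_circles,
        applied=conf.applied ^ {pair.name},
        events=conf.events + (event,),
    )
    assert new.total_length() == conf.total_length(), "length not conserved"
    return new


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def enumerate_conformations(
    master: CircularSequence,
    pairs: list[RepeatPair],
    max_events: int = 8,
) -> list[Conformation]:
    """Breadth-first closure of recombination events from the master circle.

    States are deduplicated by canonical circle multiset, so the walk
    terminates even though fission/fusion events invert each other. Each
    state is annotated with the subset of repeats applied along the first
    (breadth-first) path that reached it. Returns a deterministically
    ordered list, master state first.
    """
    start = Conformation(circles=(master,), applied=frozenset(), label="M1")
    states: dict[tuple, Conformation] = {start.key(): start}
    frontier = [start]
    for _ in range(max_events):
        nxt: list[Conformation] = []
        for conf in frontier:
            for pair in sorted(pairs, key=lambda p: p.name):
                try:
                    new = apply_recombination(conf, pair)
                except (RepeatLocationError, AmbiguousRepeatError, UnsupportedGeometryError):
                    continue
                if new.key() not in states:
                    states[new.key()] = new
                    nxt.append(new)
        if not nxt:
            break
        frontier = nxt
    out = sorted(
        states.values(), key=lambda c: (len(c.applied), tuple(sorted(c.applied)), c.key())
    )
    return out


def conformation_summary(conf: Conformation) -> dict:
    """Circle count, sizes (descending) and total length of a conformation."""
    sizes = sorted((c.length for c in conf.circles), reverse=True)
    return {
        "n_circles": conf.n_circles,
        "sizes": sizes,
        "total": sum(sizes),
        "repeats_applied": sorted(conf.applied),
        "label": conf.label,
    }
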