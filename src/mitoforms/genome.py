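"""Circular-genome primitives.

Plant mitochondrial genomes are conventionally deposited as a single
"master circle" even though the molecule population in vivo is a mixture of
circular isoforms. Everything downstream (repeat discovery, recombination
modelling, template construction) manipulates coordinates on such circles,
so this module fixes the coordinate conventions once:

* user-facing coordinates are 1-based inclusive (GenBank/table convention);
  internal arithmetic is 0-based half-open with conversion at the boundary;
* an interval with ``start > end`` wraps the origin (crosses position
  ``L -> 1``); negative coordinates are never used;
* non-ACGT characters are normalized to ``N``; ``N`` never matches in any
  alignment or repeat operation elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CircularSequence",
    "GenomeInterval",
    "CoordinateError",
    "revcomp",
    "complement",
    "normalize_seq",
    "circular_interval_length",
    "canonicalize_circle",
    "extract_subsequence",
    "rotate",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


class CoordinateError(ValueError):
    """A coordinate fell outside ``[1, L]`` for its circle."""


def normalize_seq(seq: str) -> str:
    """Uppercase and map every non-ACGT character to N."""
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    return "".join(ch if ch in _VALID else "N" for ch in s)


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def rotate(seq: str, k: int) -> str:
    """Rotate so the base at 0-based offset ``k`` becomes position 1."""
    k %= len(seq)
    return seq[k:] + seq[:k]


@dataclass(frozen=True)
class GenomeInterval:
    """1-based inclusive interval on a circle; ``start > end`` wraps the origin."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"coordinates must be >= 1, got {self.start}-{self.end}"
            )

    def validate(self, length: int) -> None:
        if not (1 <= self.start <= length and 1 <= self.end <= length):
            raise CoordinateError(
                f"interval {self.start}-{self.end} outside [1, {length}]"
            )

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, circle_length: int) -> int:
        return circular_interval_length(self, circle_length)

    def overlaps(self, other: "GenomeInterval", circle_length: int) -> bool:
        """True if the two intervals share at least one position on the circle."""
        mine = set(self.positions(circle_length))
        return any(p in mine for p in other.positions(circle_length))

    def positions(self, circle_length: int):
        """Yield the 1-based positions covered, in 5'->3' order on the + strand."""
        self.validate(circle_length)
        if not self.wraps:
            yield from range(self.start, self.end + 1)
        else:
            yield from range(self.start, circle_length + 1)
            yield from range(1, self.end + 1)


@dataclass
class CircularSequence:
    """A named circular DNA molecule."""

    id: str
    seq: str
    meta: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("CircularSequence requires a non-empty sequence")
        self.seq = normalize_seq(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def canonical(self) -> str:
        return canonicalize_circle(self)

    def gc(self) -> float:
        """GC fraction over non-N bases."""
        acgt = sum(self.seq.count(b) for b in "ACGT")
        if acgt == 0:
            return 0.0
        return (self.seq.count("G") + self.seq.count("C")) / acgt


def circular_interval_length(iv: GenomeInterval, L: int) -> int:
    """Inclusive span of ``iv`` on a circle of length ``L`` (wrap-aware)."""
    iv.validate(L)
    if iv.start <= iv.end:
        return iv.end - iv.start + 1
    return L - iv.start + 1 + iv.end


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation, O(n)."""
    n = len(s)
    d = s + s
    f = [-1] * (2 * n)
    k = 0
    for j in range(1, 2 * n):
        sj = d[j]
        i = f[j - k - 1]
        while i != -1 and sj != d[k + i + 1]:
            if sj < d[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != d[k + i + 1]:
            if sj < d[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonicalize_circle(c: "CircularSequence | str") -> str:
    """Rotation- and strand-invariant canonical form of a circular sequence.

    Returns the lexicographically smallest string among all rotations of the
    sequence and of its reverse complement, so two circles compare equal iff
    they are the same molecule up to rotation and strand flip.
    """
    s = c.seq if isinstance(c, CircularSequence) else normalize_seq(c)
    if not s:
        raise ValueError("cannot canonicalize an empty sequence")
    k1 = _least_rotation(s)
    fwd = (s + s)[k1 : k1 + len(s)]
    rc = revcomp(s)
    k2 = _least_rotation(rc)
    rev = (rc + rc)[k2 : k2 + len(s)]
    return min(fwd, rev)


def extract_subsequence(c: CircularSequence, iv: GenomeInterval) -> str:
    """Bases of ``iv`` in 5'->3' order on the requested strand (wrap-aware)."""
    L = c.length
    iv.validate(L)
    if iv.start <= iv.end:
        sub = c.seq[iv.start - 1 : iv.end]
    else:
        sub = c.seq[iv.start - 1 :] + c.seq[: iv.end]
    return revcomp(sub) if iv.strand == "-" else sub
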