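"""Synthetic data with full ground-truth manifests.

Every input the pipeline consumes can be generated here: a circular
mitogenome with planted repeat pairs, a weighted mixture of recombined
conformations sampled as nanopore-like long reads, RNA-seq reads over
coding sequences with planted C-to-U (and other) edits at specified
per-site efficiencies, and chloroplast tracts inserted into the mitogenome.

Defaults mirror the sweet potato mitogenome system this package models: a
270,304 bp circle at 44.08% GC, long-read lengths lognormal around a 10 kb mean (gTube
fragmenting), nanopore-like error rates (substitution 0.05, insertion
0.025, deletion 0.025). All randomness flows from a single integer seed
through ``numpy.random.default_rng`` (PCG64); the same seed reproduces the
same bytes on any platform. Each generator returns a manifest sufficient
to compute the expected output of every downstream stage without
re-reading the sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genome import CircularSequence, GenomeInterval, revcomp

__all__ = [
    "SimulationSpec",
    "RepeatPlan",
    "generate_genome",
    "simulate_long_reads",
    "simulate_rnaseq",
    "plant_cp_fragments",
    "random_sequence",
    "repeat_pairs_from_manifest",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class PlacementError(ValueError):
    """A planted feature does not fit the genome plan."""


@dataclass(frozen=True)
class RepeatPlan:
    """One repeat pair to plant: copy length, percent identity, orientation
    and the two 1-based start positions."""

    length: int
    identity: float  # percent
    orientation: str  # direct | inverted
    pos1: int
    pos2: int


@dataclass
class SimulationSpec:
    seed: int = 0
    genome_length: int = 270_304
    gc: float = 0.4408
    repeat_plan: list[RepeatPlan] = field(default_factory=list)
    mixture: dict[str, float] = field(default_factory=dict)  # circle id -> weight
    long_read: dict = field(
        default_factory=lambda: dict(
            n=1000, length_mean=10_000.0, length_sd=5_000.0,
            sub_rate=0.05, ins_rate=0.025, del_rate=0.025,
        )
    )
    rnaseq: dict = field(
        default_factory=lambda: dict(depth=50, error_rate=0.01, read_len=100, edit_table=[])
    )
    cp_insert_plan: list[tuple[GenomeInterval, int]] = field(default_factory=list)

    def __post_init__(self):
        if self.mixture:
            total = sum(self.mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture weights must sum to 1, got {total}")
        for rate in ("sub_rate", "ins_rate", "del_rate"):
            r = self.long_read.get(rate, 0.0)
            if not (0 <= r < 1):
                raise ValueError(f"{rate} must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        """Load a simulation spec from a YAML file.

        ``repeat_plan`` rows are [length, identity, orientation, pos1, pos2];
        ``cp_insert_plan`` rows are [cp_start, cp_end, strand, mt_pos];
        ``rnaseq.edit_table`` rows are [gene, pos, base, efficiency];
        scalar fields mirror the dataclass.
        """
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {
            k: raw[k]
            for k in ("seed", "genome_length", "gc", "mixture")
            if k in raw
        }
        if "repeat_plan" in raw:
            kwargs["repeat_plan"] = [
                RepeatPlan(int(r[0]), float(r[1]), str(r[2]), int(r[3]), int(r[4]))
                for r in raw["repeat_plan"]
            ]
        if "long_read" in raw:
            base = cls().long_read | dict(raw["long_read"])
            kwargs["long_read"] = base
        if "rnaseq" in raw:
            base = cls().rnaseq | dict(raw["rnaseq"])
            base["edit_table"] = [
                (str(g), int(p), str(b), float(e))
                for g, p, b, e in base.get("edit_table", [])
            ]
            kwargs["rnaseq"] = base
        if "cp_insert_plan" in raw:
            kwargs["cp_insert_plan"] = [
                (GenomeInterval(int(r[0]), int(r[1]), str(r[2])), int(r[3]))
                for r in raw["cp_insert_plan"]
            ]
        return cls(**kwargs)


def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """I.i.d. random DNA at the requested GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def _mutate_to_identity(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Scatter point substitutions so the copy matches at ~``identity`` percent."""
    n_mut = round(len(seq) * (1 - identity / 100.0))
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_genome(
    spec: SimulationSpec, seed: int | None = None
) -> tuple[CircularSequence, dict]:
    """A circular genome with planted repeat pairs, plus its truth manifest."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    L = spec.genome_length
    seq = list(random_sequence(L, spec.gc, rng))
    occupied: list[tuple[int, int]] = []
    manifest: dict = {"genome_length": L, "gc": spec.gc, "repeats": []}
    for i, plan in enumerate(spec.repeat_plan, start=1):
        for pos in (plan.pos1, plan.pos2):
            if not (1 <= pos and pos + plan.length - 1 <= L):
                raise PlacementError(f"repeat copy at {pos} does not fit")
        s1, s2 = plan.pos1 - 1, plan.pos2 - 1
        for s in (s1, s2):
            for o1, o2 in occupied + [(t, t + plan.length) for t in (s1, s2) if t != s]:
                if s < o2 and s + plan.length > o1:
                    raise PlacementError("planted repeats overlap")
        occupied += [(s1, s1 + plan.length), (s2, s2 + plan.length)]
        copy1 = "".join(seq[s1 : s1 + plan.length])
        copy2 = _mutate_to_identity(copy1, plan.identity, rng)
        if plan.orientation == "inverted":
            placed = revcomp(copy2)
        elif plan.orientation == "direct":
            placed = copy2
        else:
            raise ValueError(f"orientation must be direct or inverted: {plan.orientation}")
        seq[s2 : s2 + plan.length] = placed
        manifest["repeats"].append(
            {
                "name": f"R{i}",
                "length": plan.length,
                "identity": plan.identity,
                "orientation": plan.orientation,
                "iv1": (plan.pos1, plan.pos1 + plan.length - 1),
                "iv2": (plan.pos2, plan.pos2 + plan.length - 1),
                "seq1": copy1,
                "seq2": copy2,
            }
        )
    circle = CircularSequence("synthetic_mt", "".join(seq))
    manifest["realized_gc"] = circle.gc()
    return circle, manifest


def repeat_pairs_from_manifest(circle: CircularSequence, manifest: dict):
    """Ground-truth RepeatPair objects from a generate_genome manifest.

    Lets downstream stages (templates, conformations, evidence) run on the
    planted truth without re-detecting the repeats.
    """
    from .genome import extract_subsequence
    from .repeats import RepeatPair

    pairs = []
    for r in manifest["repeats"]:
        iv1 = GenomeInterval(*r["iv1"], "+")
        iv2 = GenomeInterval(
            *r["iv2"], "-" if r["orientation"] == "inverted" else "+"
        )
        pairs.append(
            RepeatPair(
                name=r["name"],
                iv1=iv1,
                iv2=iv2,
                orientation=r["orientation"],
                identity=r["identity"],
                alignment_length=r["length"],
                evalue=0.0,
                score=0.0,
                seq1=extract_subsequence(circle, iv1),
                seq2=extract_subsequence(circle, iv2),
            )
        )
    return pairs


# ---------------------------------------------------------------------------
# Long reads
# ---------------------------------------------------------------------------


def _apply_errors(
    seq: str, sub: float, ins: float, del_: float, rng: np.random.Generator
) -> str:
    if sub == ins == del_ == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1")
    u = rng.random(len(arr))
    out: list[bytes] = []
    bases = _BASES
    for i, ch in enumerate(arr):
        r = u[i]
        if r < del_:
            continue
        if r < del_ + ins:
            out.append(bases[rng.integers(4)])
            out.append(ch)
        elif r < del_ + ins + sub:
            alt = bases[rng.integers(4)]
            while alt == ch:
                alt = bases[rng.integers(4)]
            out.append(alt)
        else:
            out.append(ch)
    return b"".join(out).decode()


def simulate_long_reads(
    circles: list[CircularSequence],
    weights: list[float],
    n: int = 1000,
    length_mean: float = 10_000.0,
    length_sd: float = 5_000.0,
    sub_rate: float = 0.05,
    ins_rate: float = 0.025,
    del_rate: float = 0.025,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict]:
    """Nanopore-like reads from a weighted mixture of circular molecules.

    Each read picks a source circle by weight, a uniform start, a lognormal
    length (capped at the circle length; reads wrap the origin) and a
    uniform strand, then substitution/insertion/deletion errors at the
    stated per-base rates. Returns (reads, manifest); the manifest records
    the source circle, start, strand and error-free length per read.
    """
    if len(circles) != len(weights) or not circles:
        raise ValueError("need one weight per circle")
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
        raise ValueError("weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    sigma2 = math.log(1 + (length_sd / length_mean) ** 2)
    mu = math.log(length_mean) - sigma2 / 2
    src = rng.choice(len(circles), size=n, p=w)
    lengths = np.exp(rng.normal(mu, math.sqrt(sigma2), size=n))
    reads: list[tuple[str, str]] = []
    manifest: dict = {"reads": []}
    for i in range(n):
        circ = circles[src[i]]
        L = circ.length
        ln = int(min(max(lengths[i], 50), L))
        start = int(rng.integers(L))
        doubled = circ.seq + circ.seq
        frag = doubled[start : start + ln]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        obs = _apply_errors(frag, sub_rate, ins_rate, del_rate, rng)
        rid = f"read{i:05d}"
        reads.append((rid, obs))
        manifest["reads"].append(
            {"id": rid, "source": circ.id, "start": start + 1, "strand": strand, "length": ln}
        )
    return reads, manifest


# ---------------------------------------------------------------------------
# RNA-seq
# ---------------------------------------------------------------------------


def simulate_rnaseq(
    gene_seqs: dict[str, str],
    edit_table: list[tuple[str, int, str, float]],
    depth: int = 50,
    error_rate: float = 0.01,
    read_len: int = 100,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict]:
    """RNA-seq reads over coding sequences with planted editing events.

    ``edit_table`` rows are (gene, 1-based position, edited base, efficiency);
    each read covering a planted site carries the edited base independently
    with probability equal to the site's efficiency. Read starts are uniform
    over ``[-(read_len-1), gene_len-1]`` and clipped to the gene, giving
    near-uniform expected coverage ``depth`` across the whole gene.
    Substitution errors are then added at ``error_rate`` per base.
    """
    rng = np.random.default_rng(seed)
    edits: dict[str, list[tuple[int, str, float]]] = {}
    for gene, pos, base, eff in edit_table:
        if gene not in gene_seqs:
            raise KeyError(f"unknown gene {gene!r} in edit table")
        if not (1 <= pos <= len(gene_seqs[gene])):
            raise ValueError(f"edit position {pos} outside gene {gene}")
        edits.setdefault(gene, []).append((pos - 1, base, eff))
    reads: list[tuple[str, str]] = []
    manifest: dict = {"per_read_edits": {}, "edit_table": list(edit_table)}
    ridx = 0
    for gene in sorted(gene_seqs):
        gseq = gene_seqs[gene]
        Lg = len(gseq)
        n_reads = math.ceil(depth * (Lg + read_len - 1) / read_len)
        starts = rng.integers(-(read_len - 1), Lg, size=n_reads)
        for s in starts:
            lo, hi = max(int(s), 0), min(int(s) + read_len, Lg)
            if hi - lo < 20:
                continue
            frag = list(gseq[lo:hi])
            carried = []
            for p0, base, eff in edits.get(gene, ()):
                if lo <= p0 < hi and rng.random() < eff:
                    frag[p0 - lo] = base
                    carried.append((gene, p0 + 1))
            if error_rate > 0:
                errs = np.nonzero(rng.random(len(frag)) < error_rate)[0]
                for p in errs:
                    choices = [b for b in "ACGT" if b != frag[p]]
                    frag[p] = choices[rng.integers(3)]
            rid = f"rna{ridx:06d}"
            ridx += 1
            reads.append((rid, "".join(frag)))
            if carried:
                manifest["per_read_edits"][rid] = carried
    return reads, manifest


# ---------------------------------------------------------------------------
# Chloroplast fragment planting
# ---------------------------------------------------------------------------


def plant_cp_fragments(
    mt: CircularSequence,
    cp: CircularSequence,
    plan: list[tuple[GenomeInterval, int]],
    forbidden: list[tuple[int, int]] | None = None,
) -> tuple[CircularSequence, dict]:
    """Insert chloroplast tracts into the mitogenome.

    ``plan`` rows are (chloroplast interval, 1-based mt insertion point);
    stated positions refer to the input coordinate system (the cumulative
    shift from earlier inserts is tracked internally; manifest coordinates
    are on the final genome). ``forbidden`` (1-based inclusive spans, e.g.
    planted repeat copies) raises PlacementError on overlap. The manifest
    records both coordinate systems for every insert.
    """
    from .genome import extract_subsequence

    for iv, pos in plan:
        if not (1 <= pos <= mt.length + 1):
            raise PlacementError(f"insertion point {pos} outside the mitogenome")
        for a, b in forbidden or ():
            if a <= pos <= b:
                raise PlacementError(f"insertion at {pos} hits a protected span {a}-{b}")
    seq = mt.seq
    manifest: dict = {"inserts": []}
    shift = 0
    # apply left-to-right, tracking the cumulative shift of later positions
    for iv, pos in sorted(plan, key=lambda x: x[1]):
        frag = extract_subsequence(cp, iv)
        at = pos - 1 + shift
        seq = seq[:at] + frag + seq[at:]
        manifest["inserts"].append(
            {
                "cp_iv": (iv.start, iv.end, iv.strand),
                "mt_start": at + 1,
                "mt_end": at + len(frag),
                "length": len(frag),
            }
        )
        shift += len(frag)
    manifest["final_length"] = len(seq)
    return CircularSequence(mt.id + "_with_cp", seq), manifest
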