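"""RNA-editing site calling from RNA-seq pileups over coding sequences.

Plant mitochondrial transcripts are edited post-transcriptionally, mostly
C-to-U. Sites are called from per-position base counts ("pileup columns")
over each protein-coding gene:

* reads are aligned to the coding sequences (internal edlib mapper, or a
  SAM file); alignments below an identity floor are discarded, and bases
  within ±2 bp of a read indel are excluded from counts;
* a column is called a site when depth is strictly greater than
  ``min_depth`` (default 10, i.e. the "> 10x" rule), and the modal
  non-reference base reaches ``min_edited`` reads and ``min_frac`` of the
  column;
* editing efficiency is the two-allele fraction
  edited / (edited + reference), the binomial MLE of the per-transcript
  editing probability;
* substitution types are reported in transcript space, DNA T written as U
  (so a genomic C→T change is a "C-to-U" event); there are 12 possible
  ordered types.

Antisense alignments are complemented before counting, so counts are
always in coding-strand orientation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib

from .genome import revcomp

__all__ = [
    "PileupColumn",
    "EditingSite",
    "build_pileup",
    "call_editing_sites",
    "summarize_editing",
    "EDIT_TYPES",
]

_BASES = "ACGT"


def _rna(base: str) -> str:
    return "U" if base == "T" else base


#: the 12 ordered substitution types, transcript space
EDIT_TYPES = tuple(
    f"{_rna(a)}-to-{_rna(b)}" for a in _BASES for b in _BASES if a != b
)


@dataclass
class PileupColumn:
    gene: str
    pos: int  # 1-based position in the coding sequence
    ref: str
    depth: int
    base_counts: dict[str, int]


@dataclass
class EditingSite:
    gene: str
    pos: int
    ref_base: str
    edited_base: str
    type: str  # e.g. "C-to-U"
    depth: int
    edited_count: int
    efficiency: float  # edited / (edited + ref)
    multiallelic: bool = False
    start_codon: bool = False  # falls in codon 1 (the rps10 ACG-start question)


# ---------------------------------------------------------------------------
# Pileup construction
# ---------------------------------------------------------------------------


def _cigar_steps(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _count_alignment(counts, read_seq: str, gene_pos: int, cigar: str, indel_pad: int = 2):
    """Add one aligned read into per-position counts, masking around indels.

    ``cigar`` uses edlib's extended symbols: = (match), X (mismatch),
    I (insertion to read), D (deletion from read).
    """
    events = []  # (gene_pos, base) aligned columns
    masked: set[int] = set()
    g, r = gene_pos, 0
    for n, op in _cigar_steps(cigar):
        if op in ("=", "X", "M"):
            for i in range(n):
                events.append((g + i, read_seq[r + i]))
            g += n
            r += n
        elif op == "I":
            masked.update(range(g - indel_pad, g + indel_pad))
            r += n
        elif op == "D":
            masked.update(range(g - indel_pad, g + n + indel_pad))
            g += n
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")
    for pos, base in events:
        if pos in masked or base not in _BASES:
            continue
        counts[pos][base] += 1


def _map_read(seq: str, gene_seqs: dict[str, str], min_identity: float):
    """Best gene/strand placement of one read (edlib semi-global)."""
    best = None
    k_max = int((1 - min_identity) * len(seq))
    for gene, gseq in gene_seqs.items():
        for strand, rs in (("+", seq), ("-", revcomp(seq))):
            if len(rs) > len(gseq):
                continue
            res = edlib.align(rs, gseq, mode="HW", task="path", k=k_max)
            d = res["editDistance"]
            if d == -1:
                continue
            if best is None or d < best[0]:
                start = res["locations"][0][0]
                best = (d, gene, strand, start, res["cigar"], rs)
    return best


def build_pileup(
    gene_seqs: dict[str, str],
    reads=None,
    alignments=None,
    sam_path=None,
    min_identity: float = 0.75,
    indel_pad: int = 2,
) -> list[PileupColumn]:
    """Per-position base counts over coding sequences, transcript orientation.

    Exactly one of the input channels is used:

    * ``reads`` — (id, seq) pairs mapped internally with edlib;
    * ``alignments`` — precomputed (gene, start0, cigar, read_seq) tuples
      (read_seq already in gene orientation);
    * ``sam_path`` — a SAM/BAM file whose reference names are gene ids.

    Columns with zero coverage are omitted.
    """
    counts: dict[str, dict[int, Counter]] = {
        g: {} for g in gene_seqs
    }

    def gene_counts(gene: str):
        if gene not in counts:
            raise KeyError(f"unknown gene id {gene!r}")
        return counts[gene]

    def add(gene, start0, cigar, rs):
        col = gene_counts(gene)
        # lazily create columns touched by this read
        class _View:
            def __getitem__(self, pos):
                if pos not in col:
                    col[pos] = Counter()
                return col[pos]

        _count_alignment(_View(), rs, start0, cigar, indel_pad)

    if alignments is not None:
        for gene, start0, cigar, rs in alignments:
            add(gene, start0, cigar, rs)
    elif sam_path is not None:
        import pysam

        with pysam.AlignmentFile(str(sam_path), check_sq=False) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.query_sequence is None:
                    continue
                nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
                if 1 - nm / max(len(rec.query_sequence), 1) < min_identity:
                    continue
                add(
                    rec.reference_name,
                    rec.reference_start,
                    rec.cigarstring,
                    rec.query_sequence,
                )
    elif reads is not None:
        for _, seq in reads:
            hit = _map_read(seq, gene_seqs, min_identity)
            if hit is None:
                continue
            _, gene, _, start, cigar, rs = hit
            add(gene, start, cigar, rs)
    else:
        raise ValueError("provide reads, alignments or sam_path")

    columns: list[PileupColumn] = []
    for gene in sorted(gene_seqs):
        gseq = gene_seqs[gene]
        for pos0 in sorted(counts[gene]):
            if not (0 <= pos0 < len(gseq)):
                continue  # read ran past the annotated gene end
            bc = counts[gene][pos0]
            depth = sum(bc.values())
            if depth == 0:
                continue
            columns.append(
                PileupColumn(
                    gene=gene,
                    pos=pos0 + 1,
                    ref=gseq[pos0],
                    depth=depth,
                    base_counts={b: bc.get(b, 0) for b in _BASES},
                )
            )
    return columns


# ---------------------------------------------------------------------------
# Site calling and summaries
# ---------------------------------------------------------------------------


def call_editing_sites(
    pileup: list[PileupColumn],
    min_depth: int = 10,
    min_edited: int = 3,
    min_frac: float = 0.05,
) -> list[EditingSite]:
    """Editing sites from pileup columns.

    Depth must be strictly greater than ``min_depth`` (a column at exactly
    10x is not called under the default). The modal non-reference base must
    reach ``min_edited`` reads and ``min_frac`` of the column; a second
    non-reference base over the same thresholds flags the site
    multiallelic. Sites are ordered by (gene, pos).
    """
    if min_depth < 0 or min_edited <= 0 or min_frac <= 0:
        raise ValueError("thresholds must be positive")
    sites: list[EditingSite] = []
    for col in pileup:
        if col.depth <= min_depth or col.ref not in _BASES:
            continue
        alts = sorted(
            ((b, n) for b, n in col.base_counts.items() if b != col.ref),
            key=lambda bn: (-bn[1], bn[0]),
        )
        if not alts:
            continue
        alt, n_alt = alts[0]
        if n_alt < min_edited or n_alt / col.depth < min_frac:
            continue
        n_ref = col.base_counts.get(col.ref, 0)
        sites.append(
            EditingSite(
                gene=col.gene,
                pos=col.pos,
                ref_base=col.ref,
                edited_base=alt,
                type=f"{_rna(col.ref)}-to-{_rna(alt)}",
                depth=col.depth,
                edited_count=n_alt,
                efficiency=n_alt / (n_alt + n_ref),
                multiallelic=(
                    len(alts) > 1
                    and alts[1][1] >= min_edited
                    and alts[1][1] / col.depth >= min_frac
                ),
                start_codon=col.pos <= 3,
            )
        )
    sites.sort(key=lambda s: (s.gene, s.pos))
    return sites


def summarize_editing(sites: list[EditingSite]) -> dict:
    """Per-gene counts, efficiency histogram and substitution-type shares.

    The efficiency histogram uses ten decile bins plus a dedicated bin for
    sites at exactly 100% efficiency. Type shares are percentages of total
    sites, rounded to 0.1.
    """
    per_gene = Counter(s.gene for s in sites)
    hist = {f"{10 * i}-{10 * (i + 1)}%": 0 for i in range(10)}
    hist["=100%"] = 0
    for s in sites:
        if s.efficiency == 1.0:
            hist["=100%"] += 1
        else:
            i = min(int(s.efficiency * 10), 9)
            hist[f"{10 * i}-{10 * (i + 1)}%"] += 1
    type_counts = {t: 0 for t in EDIT_TYPES}
    for s in sites:
        type_counts[s.type] += 1
    total = len(sites)
    type_shares = {
        t: round(100.0 * n / total, 1) if total else 0.0 for t, n in type_counts.items()
    }
    return {
        "n_sites": total,
        "per_gene": dict(sorted(per_gene.items())),
        "efficiency_histogram": hist,
        "type_counts": type_counts,
        "type_shares": type_shares,
    }
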