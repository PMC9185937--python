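"""Format plumbing: FASTA/FASTQ, interval TSV, manifests.

All tables are tab-separated with a fixed header row and 1-based inclusive
coordinates. FASTA output is wrapped at 70 columns.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import CircularSequence, GenomeInterval

FASTA_WRAP = 70


def read_fasta(path: str | Path) -> list[CircularSequence]:
    """Read a (multi-)FASTA file into CircularSequence records."""
    records = [
        CircularSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, seqs: Iterable[CircularSequence]) -> None:
    recs = [SeqRecord(Seq(c.seq), id=c.id, description="") for c in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(recs)


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTQ into (read_id, sequence) tuples."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], qual: int = 20) -> None:
    """Write reads with a constant PHRED quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{chr(qual + 33) * len(seq)}\n")


def write_tsv(path: str | Path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        w.writerows(rows)


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        rows = list(r)
    if not rows:
        raise ValueError(f"empty TSV {path}")
    return rows[0], rows[1:]


def read_interval_tsv(path: str | Path) -> list[tuple[str, GenomeInterval]]:
    """Interval table: columns circle_id, start, end, strand (1-based inclusive)."""
    header, rows = read_tsv(path)
    expected = ["circle_id", "start", "end", "strand"]
    if [h.strip() for h in header[:4]] != expected:
        raise ValueError(f"interval TSV must start with columns {expected}, got {header}")
    return [
        (row[0], GenomeInterval(int(row[1]), int(row[2]), row[3])) for row in rows
    ]


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
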