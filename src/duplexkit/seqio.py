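"""Sequence I/O for the duplex consensus pipeline.

Readers and writers for the formats the pipeline touches: paired FASTQ input
(Sanger/+33 Phred only), the six-column family table that carries reads between
pipeline stages, and FASTA/FASTQ consensus output.  Gzip is handled
transparently by extension; a path of ``"-"`` means stdin/stdout.

The family table is deliberately a plain TSV whose column order
``(canonical_barcode, tag_order, mate, read_name, seq, qual)`` makes an
ordinary lexicographic sort of the file equivalent to grouping reads by
fragment and strand.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Sequence, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator

log = logging.getLogger(__name__)

PHRED_OFFSET = 33

FAMILY_TABLE_COLUMNS = ("canonical_barcode", "tag_order", "mate", "read_name", "seq", "qual")


class FastqFormatError(ValueError):
    """Raised for malformed or inconsistent paired FASTQ input."""


@dataclass
class ReadPair:
    """One paired-end read: both mates, sequence and Sanger-encoded quality."""

    name: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.name!r}: sequence/quality length mismatch")


@dataclass
class FamilyTableRow:
    """One mate of one read pair, annotated with its canonical barcode."""

    canonical_barcode: str
    tag_order: str  # "AB" or "BA"
    mate: int  # 1 or 2
    read_name: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"row {self.read_name!r}: seq/qual length mismatch")
        if self.tag_order not in ("AB", "BA"):
            raise ValueError(f"bad tag_order {self.tag_order!r}")
        if self.mate not in (1, 2):
            raise ValueError(f"bad mate {self.mate!r}")

    def sort_key(self) -> tuple:
        return (self.canonical_barcode, self.tag_order, self.mate, self.read_name)


def phred_scores(qual: str) -> list[int]:
    """Decode a Sanger (+33) quality string to integer Phred scores."""
    return [ord(c) - PHRED_OFFSET for c in qual]


def phred_string(scores: Sequence[int]) -> str:
    return "".join(chr(q + PHRED_OFFSET) for q in scores)


def open_text(path, mode: str = "rt") -> IO[str]:
    """Open plain or gzipped text by extension; '-' is stdin/stdout."""
    if hasattr(path, "read") or hasattr(path, "write"):
        return path
    path = str(path)
    if path == "-":
        return sys.stdin if "r" in mode else sys.stdout
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _strip_mate_suffix(name: str) -> str:
    name = name.split()[0]
    if name.endswith("/1") or name.endswith("/2"):
        return name[:-2]
    return name


def read_paired_fastq(path1, path2) -> Iterator[ReadPair]:
    """Stream mate-synchronised read pairs from two FASTQ files.

    Mates must appear in the same order in both files; names are compared
    after stripping a trailing ``/1``/``/2``.  Unequal record counts or a
    name mismatch abort with an error naming the offending record.
    """
    with open_text(path1) as fh1, open_text(path2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        n = 0
        while True:
            try:
                rec1 = next(it1, None)
            except ValueError as exc:
                raise FastqFormatError(f"{path1}: malformed FASTQ at record {n + 1}: {exc}") from exc
            try:
                rec2 = next(it2, None)
            except ValueError as exc:
                raise FastqFormatError(f"{path2}: malformed FASTQ at record {n + 1}: {exc}") from exc
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                short = path2 if rec2 is None else path1
                raise FastqFormatError(
                    f"unequal mate counts: {short} ran out at record {n + 1}"
                )
            n += 1
            name1 = _strip_mate_suffix(rec1[0])
            name2 = _strip_mate_suffix(rec2[0])
            if name1 != name2:
                raise FastqFormatError(
                    f"mate name mismatch at record {n}: {name1!r} vs {name2!r}"
                )
            yield ReadPair(name1, rec1[1].upper(), rec1[2], rec2[1].upper(), rec2[2])


def write_paired_fastq(pairs: Iterable[ReadPair], path1, path2) -> int:
    """Write read pairs to two mate-synchronised FASTQ files. Returns pair count."""
    n = 0
    with open_text(path1, "wt") as fh1, open_text(path2, "wt") as fh2:
        for p in pairs:
            fh1.write(f"@{p.name}/1\n{p.seq1}\n+\n{p.qual1}\n")
            fh2.write(f"@{p.name}/2\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
    return n


def write_family_table(rows: Iterable[FamilyTableRow], path) -> int:
    """Write family-table rows as headerless TSV; returns the row count."""
    n = 0
    with open_text(path, "wt") as fh:
        for row in rows:
            if len(row.seq) != len(row.qual):
                raise ValueError(f"row {row.read_name!r}: seq/qual length mismatch")
            fh.write(
                f"{row.canonical_barcode}\t{row.tag_order}\t{row.mate}\t"
                f"{row.read_name}\t{row.seq}\t{row.qual}\n"
            )
            n += 1
    return n


def read_family_table(path) -> Iterator[FamilyTableRow]:
    with open_text(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise ValueError(f"family table line {i}: expected 6 columns, got {len(fields)}")
            bc, order, mate, name, seq, qual = fields
            yield FamilyTableRow(bc, order, int(mate), name, seq, qual)


def _header_name(name: str) -> str:
    # FASTA/FASTQ headers treat whitespace as a field separator.
    return name.replace(" ", "_")


def write_fasta(records: Iterable[Tuple[str, str]], path) -> int:
    """Write (name, seq) records as single-line-sequence FASTA; empty seqs skipped."""
    n = 0
    with open_text(path, "wt") as fh:
        for name, seq in records:
            if not seq:
                log.warning("skipping empty sequence %r", name)
                continue
            fh.write(f">{_header_name(name)}\n{seq}\n")
            n += 1
    return n


def write_fastq(records: Iterable[Tuple[str, str]], path, fixed_qual: int = 40) -> int:
    """Write (name, seq) records as FASTQ with a fixed Phred quality at every base.

    Consensus sequences carry no per-base qualities of their own, so a single
    user-chosen value is assigned uniformly (the FASTA+QUAL-to-FASTQ
    conversion step of the workflow).
    """
    qchar = chr(fixed_qual + PHRED_OFFSET)
    n = 0
    with open_text(path, "wt") as fh:
        for name, seq in records:
            if not seq:
                log.warning("skipping empty sequence %r", name)
                continue
            fh.write(f"@{_header_name(name)}\n{seq}\n+\n{qchar * len(seq)}\n")
            n += 1
    return n


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into a list of (name, uppercase sequence)."""
    from Bio import SeqIO

    with open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fasta")]
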