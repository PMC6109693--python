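"""Shared sequence containers and FASTA/FASTQ/SAM plumbing.

Sequences are held in a light :class:`SequenceRecord`; conversion to and
from Biopython happens only at file boundaries.  SAM files are written as
plain text (the synthetic generator emits match-only CIGARs) and read back
through :mod:`pysam`, so anything a real mapper produces is equally
acceptable downstream.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqRecord import SeqRecord

from mgspipe.errors import MgsDataError

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PHRED_OFFSET = 33


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence with optional per-base quality."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise MgsDataError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def phred(self) -> list[int]:
        """Quality values decoded as Phred+33."""
        if self.qual is None:
            raise MgsDataError(f"record {self.id!r} has no quality string")
        return [ord(c) - PHRED_OFFSET for c in self.qual]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield SequenceRecord(rec.id, str(rec.seq))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    with _open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield SequenceRecord(title.split()[0], seq, qual)


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> int:
    n = 0
    with _open_text(path, "wt") as fh:
        for rec in records:
            if rec.qual is None:
                raise MgsDataError(f"record {rec.id!r} has no quality for FASTQ output")
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
            n += 1
    return n


def to_biopython(rec: SequenceRecord) -> SeqRecord:
    return SeqRecord(Seq(rec.seq), id=rec.id, description="")


@dataclass(frozen=True)
class SamAlignment:
    """One SAM line (minimal fields, match-only CIGAR for synthetic truth)."""

    qname: str
    flag: int
    rname: str
    pos: int  # 0-based leftmost mapped base
    mapq: int
    cigar: str
    rnext: str = "="
    pnext: int = 0
    tlen: int = 0

    def to_sam_line(self, seq: str = "*", qual: str = "*") -> str:
        return "\t".join(
            [
                self.qname,
                str(self.flag),
                self.rname,
                str(self.pos + 1),
                str(self.mapq),
                self.cigar,
                self.rnext,
                str(self.pnext + 1),
                str(self.tlen),
                seq,
                qual,
            ]
        )


def write_sam(
    alignments: Iterable[SamAlignment],
    references: list[tuple[str, int]],
    path: str | Path,
) -> int:
    """Write a headered plain-text SAM file; returns alignment count."""
    n = 0
    with open(path, "wt") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, length in references:
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for aln in alignments:
            fh.write(aln.to_sam_line() + "\n")
            n += 1
    return n
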