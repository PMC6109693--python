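"""Paired-read quality filtering.

Three whole-read rejection rules are applied, in this order:

1. **low-quality** — more than ``max_low_quality_bases`` (default 40) bases
   with Phred quality ≤ ``low_quality_threshold`` (default 38);
2. **N content** — more than ``max_n_bases`` (default 10) N/n bases;
3. **adapter** — an overlap with any adapter longer than
   ``max_adapter_overlap`` nt (default 15), where overlap is either the
   longest read suffix equal to an adapter prefix (read-through into the
   adapter) or the longest adapter substring found anywhere in the read.

Reads are kept or dropped whole — no trimming.  A pair is dropped when
either mate fails, which preserves pairing for insert-mode coverage
downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from mgspipe.errors import MgsDataError
from mgspipe.io import SequenceRecord, read_fastq, write_fastq

RULE_LOW_QUALITY = "low_quality"
RULE_N_BASES = "n_bases"
RULE_ADAPTER = "adapter"
RULES = (RULE_LOW_QUALITY, RULE_N_BASES, RULE_ADAPTER)

#: 33-nt synthetic adapter used by the read simulator and as default screen.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"


@dataclass(frozen=True)
class ReadFilterParams:
    """Thresholds for the three rejection rules (counts are strict: a read
    fails only when it *exceeds* the threshold)."""

    max_low_quality_bases: int = 40
    low_quality_threshold: int = 38
    max_n_bases: int = 10
    max_adapter_overlap: int = 15
    adapters: tuple[str, ...] = (DEFAULT_ADAPTER,)

    def __post_init__(self) -> None:
        for name in ("max_low_quality_bases", "max_n_bases", "max_adapter_overlap"):
            if getattr(self, name) < 0:
                raise MgsDataError(f"{name} must be >= 0")


def adapter_overlap(seq: str, adapter: str) -> int:
    """Longest overlap between ``seq`` and ``adapter``.

    The maximum of (a) the longest suffix of the read equal to a prefix of
    the adapter and (b) the longest substring of the adapter occurring
    anywhere in the read.
    """
    seq = seq.upper()
    adapter = adapter.upper()
    best = 0
    for k in range(min(len(seq), len(adapter)), 0, -1):
        if seq.endswith(adapter[:k]):
            best = k
            break
    for k in range(min(len(seq), len(adapter)), best, -1):
        if any(adapter[i : i + k] in seq for i in range(len(adapter) - k + 1)):
            return k
    return best


def filter_read(read: SequenceRecord, params: ReadFilterParams) -> tuple[bool, str | None]:
    """Apply the three rules; return ``(keep, first_failing_rule)``."""
    if read.qual is None or len(read.qual) != len(read.seq):
        raise MgsDataError(f"read {read.id!r}: quality/sequence length mismatch")
    n_lowq = sum(1 for q in read.phred() if q <= params.low_quality_threshold)
    if n_lowq > params.max_low_quality_bases:
        return False, RULE_LOW_QUALITY
    n_n = read.seq.count("N") + read.seq.count("n")
    if n_n > params.max_n_bases:
        return False, RULE_N_BASES
    for adapter in params.adapters:
        if adapter_overlap(read.seq, adapter) > params.max_adapter_overlap:
            return False, RULE_ADAPTER
    return True, None


@dataclass
class FilterSummary:
    """Exact per-rule accounting of a paired filtering pass."""

    pairs_in: int = 0
    pairs_kept: int = 0
    pairs_dropped: int = 0
    reads_in: int = 0
    reads_kept: int = 0
    rejected_by_rule: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULES})

    def as_dict(self) -> dict:
        return {
            "pairs_in": self.pairs_in,
            "pairs_kept": self.pairs_kept,
            "pairs_dropped": self.pairs_dropped,
            "reads_in": self.reads_in,
            "reads_kept": self.reads_kept,
            "rejected_by_rule": dict(self.rejected_by_rule),
        }


def filter_pairs(
    reads1: Iterable[SequenceRecord],
    reads2: Iterable[SequenceRecord],
    params: ReadFilterParams,
) -> tuple[list[tuple[SequenceRecord, SequenceRecord]], FilterSummary]:
    """Filter mate streams in matched order; drop whole pairs.

    Both mates of every pair are always evaluated so the per-rule rejection
    counts are exact (each rejected read is attributed to its first failing
    rule).  Output order is input order.
    """
    summary = FilterSummary()
    kept: list[tuple[SequenceRecord, SequenceRecord]] = []
    sentinel = object()
    for r1, r2 in itertools.zip_longest(reads1, reads2, fillvalue=sentinel):
        if r1 is sentinel or r2 is sentinel:
            raise MgsDataError("unequal number of reads in the two mate streams")
        summary.pairs_in += 1
        summary.reads_in += 2
        keep_pair = True
        for mate in (r1, r2):
            keep, rule = filter_read(mate, params)  # type: ignore[arg-type]
            if keep:
                summary.reads_kept += 1
            else:
                summary.rejected_by_rule[rule] += 1  # type: ignore[index]
                keep_pair = False
        if keep_pair:
            summary.pairs_kept += 1
            kept.append((r1, r2))  # type: ignore[arg-type]
        else:
            summary.pairs_dropped += 1
    return kept, summary


def filter_fastq_files(
    fastq_r1: str | Path,
    fastq_r2: str | Path,
    params: ReadFilterParams,
    out_prefix: str | Path,
) -> FilterSummary:
    """File-level wrapper: read paired FASTQ, write filtered pairs to
    ``<prefix>.R1.fastq`` / ``<prefix>.R2.fastq``."""
    kept, summary = filter_pairs(read_fastq(fastq_r1), read_fastq(fastq_r2), params)
    out_prefix = Path(out_prefix)
    write_fastq((p[0] for p in kept), out_prefix.with_suffix(".R1.fastq"))
    write_fastq((p[1] for p in kept), out_prefix.with_suffix(".R2.fastq"))
    return summary


def iter_pairs(
    fastq_r1: str | Path, fastq_r2: str | Path
) -> Iterator[tuple[SequenceRecord, SequenceRecord]]:
    sentinel = object()
    for r1, r2 in itertools.zip_longest(read_fastq(fastq_r1), read_fastq(fastq_r2), fillvalue=sentinel):
        if r1 is sentinel or r2 is sentinel:
            raise MgsDataError("unequal number of reads in the two mate files")
        yield r1, r2  # type: ignore[misc]
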