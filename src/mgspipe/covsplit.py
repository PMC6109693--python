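"""Scaftig construction and chimeric-contig correction by coverage difference.

A metagenomic co-assembly can join sequence from two organisms into one
contig.  Such chimeras betray themselves by an abrupt change in read
coverage: the two source populations are present at different abundances.
The correction scans adjacent fixed-width windows of the per-base coverage
profile and computes the coverage difference

    CD = |m1 - m2| / min(m1, m2)

where ``m1`` and ``m2`` are the mean coverages of the two adjacent windows.
A contig is broken at every window boundary where CD exceeds 0.75, whether
the profile was computed in read mode (each aligned read covers its own
bases) or insert mode (each properly-paired fragment covers its full outer
span) — either signal suffices.

Coordinates are 0-based half-open internally; BED output is 0-based
half-open; FASTA fragment ids carry 1-based inclusive ranges.
"""

from __future__ import annotations

import math
import re
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from mgspipe.errors import MgsDataError
from mgspipe.io import SamAlignment, SequenceRecord

MODE_READ = "read"
MODE_INSERT = "insert"

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_REF_CONSUMING = {"M", "D", "N", "=", "X"}


@dataclass(frozen=True)
class CoverageProfile:
    """Windowed mean per-base coverage of one contig."""

    contig_id: str
    mode: str
    window_size: int
    window_means: np.ndarray
    contig_length: int

    def __post_init__(self) -> None:
        expected = max(1, math.ceil(self.contig_length / self.window_size))
        if len(self.window_means) != expected:
            raise MgsDataError(
                f"{self.contig_id}: {len(self.window_means)} windows, expected {expected}"
            )


@dataclass(frozen=True)
class Breakpoint:
    """A putative chimeric junction at a window boundary (0-based nt)."""

    contig_id: str
    position: int
    cd_value: float
    mode: str


def make_scaftigs(
    scaffolds: Iterable[SequenceRecord], min_length: int = 500
) -> Iterator[SequenceRecord]:
    """Break scaffolds at every run of N into gap-free scaftigs.

    Pieces shorter than ``min_length`` are dropped.  A scaffold containing
    no N is emitted unchanged under its own id; otherwise piece ids are
    ``<scaffold>_scaftig<k>:<start1>-<end1>`` (1-based inclusive original
    coordinates).
    """
    for scaffold in scaffolds:
        if not scaffold.seq:
            print(f"warning: empty scaffold {scaffold.id!r} skipped", file=sys.stderr)
            continue
        pieces = [
            (m.start(), m.end())
            for m in re.finditer(r"[^Nn]+", scaffold.seq)
        ]
        if len(pieces) == 1 and pieces[0] == (0, len(scaffold.seq)):
            if len(scaffold.seq) >= min_length:
                yield scaffold
            continue
        for k, (start, end) in enumerate(pieces, start=1):
            if end - start >= min_length:
                yield SequenceRecord(
                    f"{scaffold.id}_scaftig{k}:{start + 1}-{end}",
                    scaffold.seq[start:end],
                )


def cigar_reference_length(cigar: str) -> int:
    return sum(int(n) for n, op in _CIGAR_RE.findall(cigar) if op in _REF_CONSUMING)


def _iter_sam(alignments, contig_id: str | None = None):
    """Yield (rname, pos, ref_end, tlen, is_proper, is_paired) for primary
    mapped alignments from a pysam file/path or SamAlignment iterable,
    optionally restricted to one contig."""
    if isinstance(alignments, (str, Path)):
        import pysam

        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if contig_id is not None and aln.reference_name != contig_id:
                    continue
                yield (
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    aln.template_length,
                    aln.is_proper_pair,
                    aln.is_paired,
                )
        return
    for aln in alignments:
        if isinstance(aln, SamAlignment):
            if aln.flag & 0x4 or aln.flag & 0x100 or aln.flag & 0x800:
                continue
            if contig_id is not None and aln.rname != contig_id:
                continue
            yield (
                aln.rname,
                aln.pos,
                aln.pos + cigar_reference_length(aln.cigar),
                aln.tlen,
                bool(aln.flag & 0x2),
                bool(aln.flag & 0x1),
            )
        else:  # pysam AlignedSegment stream
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if contig_id is not None and aln.reference_name != contig_id:
                continue
            yield (
                aln.reference_name,
                aln.reference_start,
                aln.reference_end,
                aln.template_length,
                aln.is_proper_pair,
                aln.is_paired,
            )


def coverage_intervals(
    alignments, contig_id: str, mode: str = MODE_READ
) -> tuple[list[tuple[int, int]], int]:
    """Reduce alignments on one contig to covered intervals.

    Read mode: one interval per aligned read (its reference span).  Insert
    mode: one interval per properly-paired fragment, from the leftmost
    mapped base of the pair to the rightmost (taken from the mate with
    positive template length so each fragment counts once); alignments that
    are unpaired or not properly paired are skipped and counted.
    Returns ``(intervals, n_skipped)``.
    """
    intervals: list[tuple[int, int]] = []
    skipped = 0
    for _, pos, ref_end, tlen, proper, paired in _iter_sam(alignments, contig_id):
        if mode == MODE_READ:
            intervals.append((pos, ref_end))
        elif mode == MODE_INSERT:
            if not (paired and proper):
                skipped += 1
                continue
            if tlen > 0:
                intervals.append((pos, pos + tlen))
        else:
            raise MgsDataError(f"unknown coverage mode {mode!r}")
    return intervals, skipped


def per_base_coverage(intervals: Sequence[tuple[int, int]], length: int) -> np.ndarray:
    """Depth at every base from half-open intervals, by difference array."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for start, end in intervals:
        if start < 0 or end > length:
            raise MgsDataError(
                f"alignment interval [{start},{end}) outside contig of length {length}"
            )
        diff[start] += 1
        diff[end] -= 1
    return np.cumsum(diff[:-1])


def windowed_means(coverage: np.ndarray, window_size: int) -> np.ndarray:
    """Mean coverage per window; the final partial window uses its true length."""
    length = len(coverage)
    starts = np.arange(0, length, window_size)
    sums = np.add.reduceat(coverage, starts)
    widths = np.minimum(starts + window_size, length) - starts
    return sums / widths


def window_coverage(
    alignments,
    contig: SequenceRecord,
    window_size: int = 1000,
    mode: str = MODE_READ,
) -> CoverageProfile:
    """Windowed mean coverage of ``contig`` from a SAM source.

    ``alignments`` may be a SAM path, a pysam stream, or an iterable of
    :class:`~mgspipe.io.SamAlignment`.
    """
    intervals, _ = coverage_intervals(alignments, contig.id, mode)
    cov = per_base_coverage(intervals, len(contig))
    return CoverageProfile(
        contig_id=contig.id,
        mode=mode,
        window_size=window_size,
        window_means=windowed_means(cov, window_size),
        contig_length=len(contig),
    )


def coverage_profiles(
    alignments,
    contigs: Iterable[SequenceRecord],
    window_size: int = 1000,
    mode: str = MODE_READ,
) -> dict[str, CoverageProfile]:
    """Windowed coverage of many contigs in a single pass over the
    alignments (equivalent to :func:`window_coverage` per contig)."""
    if mode not in (MODE_READ, MODE_INSERT):
        raise MgsDataError(f"unknown coverage mode {mode!r}")
    contigs = list(contigs)
    by_contig: dict[str, list[tuple[int, int]]] = {c.id: [] for c in contigs}
    for rname, pos, ref_end, tlen, proper, paired in _iter_sam(alignments):
        if rname not in by_contig:
            continue
        if mode == MODE_READ:
            by_contig[rname].append((pos, ref_end))
        elif paired and proper and tlen > 0:
            by_contig[rname].append((pos, pos + tlen))
    profiles = {}
    for contig in contigs:
        cov = per_base_coverage(by_contig[contig.id], len(contig))
        profiles[contig.id] = CoverageProfile(
            contig_id=contig.id,
            mode=mode,
            window_size=window_size,
            window_means=windowed_means(cov, window_size),
            contig_length=len(contig),
        )
    return profiles


def compute_cd(m1: float, m2: float) -> float:
    """Coverage difference |m1-m2|/min(m1,m2).

    Both zero → 0 (no evidence of change); exactly one zero → +inf (a
    one-sided dropout, resolved against ``min_cov`` by the breakpoint
    scan).
    """
    if m1 < 0 or m2 < 0:
        raise MgsDataError("window means must be non-negative")
    if m1 == 0 and m2 == 0:
        return 0.0
    lo = min(m1, m2)
    if lo == 0:
        return math.inf
    return abs(m1 - m2) / lo


def find_breakpoints(
    profile: CoverageProfile, threshold: float = 0.75, min_cov: float = 5.0
) -> list[Breakpoint]:
    """Scan adjacent window pairs for CD above ``threshold``.

    Pairs whose larger mean is below ``min_cov`` are suppressed (coverage
    too low to call); an infinite CD (one window at zero) counts only when
    the nonzero mean is at least ``min_cov``.
    """
    means = profile.window_means
    out: list[Breakpoint] = []
    for i in range(len(means) - 1):
        m1, m2 = float(means[i]), float(means[i + 1])
        if max(m1, m2) < min_cov:
            continue
        cd = compute_cd(m1, m2)
        if cd > threshold:
            out.append(
                Breakpoint(
                    contig_id=profile.contig_id,
                    position=(i + 1) * profile.window_size,
                    cd_value=cd,
                    mode=profile.mode,
                )
            )
    return out


def split_contigs(
    contigs: Iterable[SequenceRecord],
    breakpoints_read: Sequence[Breakpoint],
    breakpoints_insert: Sequence[Breakpoint],
    min_length: int = 500,
) -> tuple[list[SequenceRecord], list[tuple[str, int, int, str]], int]:
    """Cut contigs at the union of read- and insert-mode breakpoints.

    Either mode's signal suffices, so the cut set is the positional union.
    Fragments shorter than ``min_length`` are dropped.  Returns
    ``(fragments, bed_rows, n_dropped)`` where each BED row marks a cut as
    the first base of the right-hand fragment (0-based half-open).
    """
    contigs = list(contigs)
    known = {c.id for c in contigs}
    by_contig: dict[str, set[int]] = {}
    for bp in list(breakpoints_read) + list(breakpoints_insert):
        if bp.contig_id not in known:
            raise MgsDataError(f"breakpoint for unknown contig {bp.contig_id!r}")
        by_contig.setdefault(bp.contig_id, set()).add(bp.position)

    fragments: list[SequenceRecord] = []
    bed_rows: list[tuple[str, int, int, str]] = []
    n_dropped = 0
    for contig in contigs:
        cuts = sorted(p for p in by_contig.get(contig.id, set()) if 0 < p < len(contig))
        for pos in cuts:
            bed_rows.append((contig.id, pos, pos + 1, "cut"))
        if not cuts:
            fragments.append(contig)
            continue
        bounds = [0] + cuts + [len(contig)]
        for start, end in zip(bounds[:-1], bounds[1:]):
            if end - start >= min_length:
                fragments.append(
                    SequenceRecord(f"{contig.id}:{start + 1}-{end}", contig.seq[start:end])
                )
            else:
                n_dropped += 1
    return fragments, bed_rows, n_dropped
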