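"""Complete-and-nonredundant (CNR) gene catalog construction.

Only *complete* ORFs — start codon, stop codon, and neither end flush with
a contig edge — enter the catalog.  Redundancy is removed by greedy
incremental clustering in the CD-HIT style: sequences are visited longest
first and each joins the first existing cluster whose representative it
matches at ≥95% identity over ≥90% of the shorter sequence, otherwise it
founds a new cluster.  Identity is computed from a deterministic
semi-global alignment (the shorter sequence against the representative,
end gaps in the representative free), not a heuristic word filter, so every
decision is reproducible and oracle-checkable.

Gene abundance is length-normalised read density:

    a_i = (r_i / L_i) / sum_j (r_j / L_j)

with ``r_i`` the number of reads whose primary alignment is to gene ``i``
and ``L_i`` its length.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib

from mgspipe.errors import MgsDataError
from mgspipe.io import SamAlignment, SequenceRecord, revcomp

START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class OrfRecord:
    """An ORF on a contig, 0-based half-open, strand-aware.

    The completeness flags are tri-state: ``None`` means the gene caller
    did not report them and they are derived from the sequence.
    """

    orf_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    has_start_codon: bool | None = None
    has_stop_codon: bool | None = None
    edge_truncated: bool | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise MgsDataError(f"ORF {self.orf_id}: invalid interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise MgsDataError(f"ORF {self.orf_id}: strand must be + or -")


@dataclass(frozen=True)
class CatalogEntry:
    """One CNR gene: the cluster representative with its members, mapped
    read count ``r`` and relative abundance ``a``."""

    gene_id: str
    length: int
    members: tuple[str, ...]
    mapped_read_count: int = 0
    relative_abundance: float = 0.0


@dataclass
class Cluster:
    representative: str
    members: list[str] = field(default_factory=list)


def orf_sequence(orf: OrfRecord, contig: SequenceRecord) -> str:
    """Extract the coding-strand nucleotide sequence of an ORF."""
    if orf.end > len(contig):
        raise MgsDataError(
            f"ORF {orf.orf_id} end {orf.end} beyond contig {contig.id} length {len(contig)}"
        )
    seq = contig.seq[orf.start : orf.end].upper()
    return revcomp(seq) if orf.strand == "-" else seq


def classify_orf_completeness(
    orf: OrfRecord, contig: SequenceRecord
) -> tuple[bool, str]:
    """Decide completeness; returns ``(complete, reason)``.

    Caller-provided flags win; missing flags are derived by codon
    inspection (start ∈ {ATG,GTG,TTG}, stop ∈ {TAA,TAG,TGA}) and by
    checking whether either ORF end coincides with a contig end.
    """
    seq = orf_sequence(orf, contig)
    edge = orf.edge_truncated
    if edge is None:
        edge = orf.start == 0 or orf.end == len(contig)
    if edge:
        return False, "edge_truncated"
    has_start = orf.has_start_codon
    if has_start is None:
        has_start = seq[:3] in START_CODONS
    if not has_start:
        return False, "no_start_codon"
    has_stop = orf.has_stop_codon
    if has_stop is None:
        has_stop = len(seq) >= 6 and len(seq) % 3 == 0 and seq[-3:] in STOP_CODONS
    if not has_stop:
        return False, "no_stop_codon"
    return True, "complete"


def align_identity(query: str, target: str) -> tuple[float, float]:
    """Identity and query coverage of ``query`` (the shorter sequence)
    aligned semi-globally within ``target``.

    Identity = matches / alignment columns (end gaps in the target are
    free and excluded); coverage = fraction of the query aligned to target
    residues rather than gaps.
    """
    if len(query) > len(target):
        query, target = target, query
    res = edlib.align(query, target, mode="HW", task="path")
    ops = _CIGAR_RE.findall(res["cigar"])
    matches = sum(int(n) for n, op in ops if op == "=")
    columns = sum(int(n) for n, op in ops)
    aligned_query = sum(int(n) for n, op in ops if op in "=X")
    if columns == 0:
        return 0.0, 0.0
    return matches / columns, aligned_query / len(query)


def cluster_genes(
    sequences: Mapping[str, str] | Iterable[SequenceRecord],
    identity_threshold: float = 0.95,
    coverage_threshold: float = 0.90,
) -> list[Cluster]:
    """Greedy incremental redundancy clustering.

    Sequences are sorted by length descending (ties by id); each joins the
    first existing cluster (in founding order) whose representative it
    matches at ``identity_threshold`` over ``coverage_threshold`` of the
    shorter sequence, else it founds a new cluster.  Because of the sort
    order the founder is always the longest member and stays
    representative.
    """
    if isinstance(sequences, Mapping):
        items = list(sequences.items())
    else:
        items = [(rec.id, rec.seq) for rec in sequences]
    ids = [i for i, _ in items]
    if len(set(ids)) != len(ids):
        raise MgsDataError("duplicate sequence ids in clustering input")
    seqs = dict(items)
    order = sorted(ids, key=lambda i: (-len(seqs[i]), i))

    clusters: list[Cluster] = []
    for sid in order:
        seq = seqs[sid]
        placed = False
        for cluster in clusters:
            ident, cov = align_identity(seq, seqs[cluster.representative])
            if ident >= identity_threshold and cov >= coverage_threshold:
                cluster.members.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative=sid, members=[sid]))
    return clusters


def build_cnr_catalog(
    orfs: Sequence[OrfRecord],
    contigs: Iterable[SequenceRecord],
    identity_threshold: float = 0.95,
    coverage_threshold: float = 0.90,
) -> tuple[list[CatalogEntry], dict[str, str]]:
    """Complete-ORF extraction + redundancy clustering.

    Returns the catalog entries (one per cluster, representative id as
    gene id) and the representative sequences keyed by gene id.
    """
    contig_map = {c.id: c for c in contigs}
    complete: dict[str, str] = {}
    for orf in orfs:
        if orf.contig_id not in contig_map:
            raise MgsDataError(f"ORF {orf.orf_id} references unknown contig {orf.contig_id!r}")
        ok, _ = classify_orf_completeness(orf, contig_map[orf.contig_id])
        if ok:
            complete[orf.orf_id] = orf_sequence(orf, contig_map[orf.contig_id])
    if not complete:
        return [], {}
    clusters = cluster_genes(complete, identity_threshold, coverage_threshold)
    entries = [
        CatalogEntry(
            gene_id=cl.representative,
            length=len(complete[cl.representative]),
            members=tuple(cl.members),
        )
        for cl in clusters
    ]
    return entries, {cl.representative: complete[cl.representative] for cl in clusters}


def _count_primary(alignments, known: set[str]) -> dict[str, int]:
    counts = {g: 0 for g in known}
    if isinstance(alignments, (str, Path)):
        import pysam

        with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as fh:
            for aln in fh:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                ref = aln.reference_name
                if ref not in counts:
                    raise MgsDataError(f"alignment to unknown gene {ref!r}")
                counts[ref] += 1
        return counts
    for aln in alignments:
        if isinstance(aln, SamAlignment):
            if aln.flag & (0x4 | 0x100 | 0x800):
                continue
            ref = aln.rname
        else:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            ref = aln.reference_name
        if ref not in counts:
            raise MgsDataError(f"alignment to unknown gene {ref!r}")
        counts[ref] += 1
    return counts


def relative_abundance(
    entries: Sequence[CatalogEntry], gene_alignments
) -> list[CatalogEntry]:
    """Fill mapped read counts and length-normalised relative abundances.

    ``r_i`` counts primary alignments only (no multi-mapping fractions);
    ``a_i = (r_i/L_i) / Σ_j (r_j/L_j)``.  With zero mapped reads the
    abundances are undefined and set to 0 with a warning.
    """
    counts = _count_primary(gene_alignments, {e.gene_id for e in entries})
    densities = {e.gene_id: counts[e.gene_id] / e.length for e in entries}
    total = sum(densities.values())
    if total == 0:
        warnings.warn("no reads mapped to any catalog gene; abundances set to 0")
        return [replace(e, mapped_read_count=0, relative_abundance=0.0) for e in entries]
    return [
        replace(
            e,
            mapped_read_count=counts[e.gene_id],
            relative_abundance=densities[e.gene_id] / total,
        )
        for e in entries
    ]


def read_orfs_gff3(path: str | Path) -> list[OrfRecord]:
    """Ingest external gene-caller output (GFF3 CDS/gene features).

    Recognises a Prodigal-style ``partial=XY`` attribute (X: 5' truncated,
    Y: 3' truncated); when absent the completeness flags stay ``None`` and
    are derived later by codon inspection.
    """
    orfs: list[OrfRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise MgsDataError(f"{path}:{lineno}: expected 9 GFF3 columns")
            contig, _, ftype, start, end, _, strand, _, attrs = fields
            if ftype not in ("CDS", "gene"):
                continue
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            orf_id = attr_map.get("ID", f"{contig}_{lineno}")
            partial = attr_map.get("partial")
            has_start = has_stop = edge = None
            if partial is not None and len(partial) == 2:
                has_start = partial[0] == "0"
                has_stop = partial[1] == "0"
                edge = partial != "00"
            orfs.append(
                OrfRecord(
                    orf_id=orf_id,
                    contig_id=contig,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    has_start_codon=has_start,
                    has_stop_codon=has_stop,
                    edge_truncated=edge,
                )
            )
    return orfs


def write_catalog_tsv(entries: Sequence[CatalogEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlength\tn_members\tmembers\tmapped_reads\trelative_abundance\n")
        for e in entries:
            fh.write(
                f"{e.gene_id}\t{e.length}\t{len(e.members)}\t{','.join(e.members)}\t"
                f"{e.mapped_read_count}\t{e.relative_abundance:.10g}\n"
            )
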