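"""Functional and taxonomic annotation of catalog genes.

Functional assignment is best-hit: tabular (outfmt6-style) alignments are
filtered at E ≤ 1e-5 and the minimum-E hit wins (ties broken by bit score,
then subject id).  CAZy family labels attached to subjects via a sidecar
metadata table are tallied per family and rolled up into agarlytic enzyme
classes: GH16/GH50/GH86 are β-agarases, GH96 α-agarases, GH117 the
α-1,3-neoagarobiose hydrolases (NABH); everything else is non-agarlytic.

Taxonomy uses the near-best-hit LCA rule: for each sequence only hits with
E-value within a factor (default 10×) of that sequence's minimum E-value
are retained, and the assignment is the deepest taxonomy node ancestral to
(or equal to) every retained hit's taxon — the node "before the first
branch" of the retained lineages.

Genome bins are labelled by rank-wise majority vote over their classified
sequences, and candidate bins are gated on single-copy marker completeness
(strictly above 75% of the marker set present).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from mgspipe.errors import MgsConfigError, MgsDataError

#: Standard rank ladder, most general first.
RANKS = ("superkingdom", "phylum", "class", "order", "family", "genus", "species")

BETA_AGARASE_FAMILIES = {"GH16", "GH50", "GH86"}
ALPHA_AGARASE_FAMILIES = {"GH96"}
NABH_FAMILIES = {"GH117"}
AGARLYTIC_FAMILIES = BETA_AGARASE_FAMILIES | ALPHA_AGARASE_FAMILIES | NABH_FAMILIES

CLASS_BETA = "beta-agarase"
CLASS_ALPHA = "alpha-agarase"
CLASS_NABH = "NABH"
CLASS_NONE = "non-agarlytic"


@dataclass(frozen=True)
class HitRecord:
    """One tabular alignment hit (DIAMOND/BLAST outfmt6 essentials)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    bitscore: float
    taxon_id: int | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0 or self.bitscore < 0:
            raise MgsDataError(
                f"hit {self.query_id}->{self.subject_id}: negative E-value or bit score"
            )


def read_outfmt6(
    path: str | Path,
    subject_meta: Mapping[str, tuple[str, int | None]] | None = None,
) -> dict[str, list[HitRecord]]:
    """Parse a 12-column outfmt6 TSV into hits grouped by query.

    ``subject_meta`` (subject id → (family, taxon id)) attaches taxon ids;
    malformed lines raise with their line number.
    """
    hits: dict[str, list[HitRecord]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise MgsDataError(f"{path}:{lineno}: expected 12 tab-separated columns")
            try:
                rec = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                    taxon_id=(
                        subject_meta[fields[1]][1]
                        if subject_meta and fields[1] in subject_meta
                        else None
                    ),
                )
            except ValueError as exc:
                raise MgsDataError(f"{path}:{lineno}: {exc}") from exc
            hits.setdefault(rec.query_id, []).append(rec)
    return hits


def read_subject_metadata(path: str | Path) -> dict[str, tuple[str, int | None]]:
    """Sidecar TSV: subject id, family label, optional taxon id."""
    meta: dict[str, tuple[str, int | None]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise MgsDataError(f"{path}:{lineno}: expected >=2 columns")
            taxid = int(fields[2]) if len(fields) > 2 and fields[2] else None
            meta[fields[0]] = (fields[1], taxid)
    return meta


def assign_best_hit(
    hits: Sequence[HitRecord], e_cutoff: float = 1e-5
) -> HitRecord | None:
    """Best surviving hit for one query, or ``None`` if unassigned.

    Hits above the E-value cutoff are discarded; among survivors the
    minimum E-value wins, ties broken by maximum bit score, then
    lexicographically smallest subject id.
    """
    survivors = [h for h in hits if h.evalue <= e_cutoff]
    if not survivors:
        return None
    return min(survivors, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))


def classify_agarlytic(family: str) -> str:
    """Map a CAZy family label to its agarlytic enzyme class."""
    fam = family.replace(" ", "").upper()
    if fam in BETA_AGARASE_FAMILIES:
        return CLASS_BETA
    if fam in ALPHA_AGARASE_FAMILIES:
        return CLASS_ALPHA
    if fam in NABH_FAMILIES:
        return CLASS_NABH
    return CLASS_NONE


@dataclass
class FamilyTally:
    """Per-family gene counts with the agarlytic class rollup."""

    family_counts: dict[str, int] = field(default_factory=dict)
    class_counts: dict[str, int] = field(
        default_factory=lambda: {CLASS_BETA: 0, CLASS_ALPHA: 0, CLASS_NABH: 0, CLASS_NONE: 0}
    )
    total: int = 0


def tally_families(assignments: Mapping[str, str]) -> FamilyTally:
    """Count queries per family label and roll up agarlytic classes."""
    tally = FamilyTally()
    for family in assignments.values():
        fam = family.replace(" ", "").upper()
        tally.family_counts[fam] = tally.family_counts.get(fam, 0) + 1
        tally.class_counts[classify_agarlytic(fam)] += 1
        tally.total += 1
    return tally


class TaxonomyTree:
    """A rooted taxonomy in NCBI dump style (node id, parent id, rank, name).

    The root is its own parent (as in nodes.dmp).  Exactly one root is
    required and every node must be reachable from it.
    """

    def __init__(self, nodes: Mapping[int, tuple[int, str, str]]):
        self.parent: dict[int, int] = {}
        self.rank: dict[int, str] = {}
        self.name: dict[int, str] = {}
        roots = []
        for taxid, (parent, rank, name) in nodes.items():
            self.parent[taxid] = parent
            self.rank[taxid] = rank
            self.name[taxid] = name
            if parent == taxid:
                roots.append(taxid)
        if len(roots) != 1:
            raise MgsDataError(f"taxonomy must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for taxid in self.parent:
            if self.parent[taxid] not in self.parent:
                raise MgsDataError(f"taxon {taxid} has unknown parent {self.parent[taxid]}")
        # reachability check doubles as a cycle guard
        for taxid in self.parent:
            self.lineage(taxid)

    @classmethod
    def from_taxdump(cls, nodes_path: str | Path, names_path: str | Path) -> "TaxonomyTree":
        """Load an NCBI-style nodes.dmp / names.dmp pair (scientific names)."""
        nodes: dict[int, tuple[int, str, str]] = {}
        with open(nodes_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
                if len(fields) < 3:
                    raise MgsDataError(f"malformed nodes.dmp line: {line!r}")
                nodes[int(fields[0])] = (int(fields[1]), fields[2], "")
        names: dict[int, str] = {}
        with open(names_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
                if len(fields) >= 4 and fields[3] == "scientific name":
                    names[int(fields[0])] = fields[1]
                elif int(fields[0]) not in names and len(fields) >= 2:
                    names.setdefault(int(fields[0]), fields[1])
        full = {
            taxid: (parent, rank, names.get(taxid, str(taxid)))
            for taxid, (parent, rank, _) in nodes.items()
        }
        return cls(full)

    def lineage(self, taxid: int) -> list[int]:
        """Root-to-node path, inclusive."""
        if taxid not in self.parent:
            raise MgsDataError(f"taxon id {taxid} not in tree")
        path = []
        node = taxid
        seen = set()
        while True:
            if node in seen:
                raise MgsDataError(f"cycle in taxonomy at taxon {node}")
            seen.add(node)
            path.append(node)
            parent = self.parent[node]
            if parent == node:
                break
            node = parent
        return path[::-1]

    def lca(self, taxids: Iterable[int]) -> int:
        """Deepest node ancestral to (or equal to) all given taxa."""
        taxids = list(taxids)
        if not taxids:
            raise MgsDataError("lca of an empty taxon set")
        lineages = [self.lineage(t) for t in taxids]
        anc = self.root
        for nodes in zip(*lineages):
            if len(set(nodes)) == 1:
                anc = nodes[0]
            else:
                break
        return anc

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        for node in self.lineage(taxid):
            if self.rank[node] == rank:
                return node
        return None


def lca_assign(
    hits: Sequence[HitRecord], tree: TaxonomyTree, factor: float = 10.0
) -> int | None:
    """Near-best-hit LCA taxon for one sequence.

    Hits with E-value within ``factor`` × the sequence's minimum E-value
    are retained (keep-the-near-best reading of the filter); the result is
    the LCA of their taxa — the node before the first branch of the
    retained lineages.  No retained hits → ``None`` (unclassified).
    """
    with_taxa = [h for h in hits if h.taxon_id is not None]
    if not with_taxa:
        return None
    for h in with_taxa:
        if h.taxon_id not in tree.parent:
            raise MgsDataError(f"hit taxon id {h.taxon_id} missing from taxonomy tree")
    min_e = min(h.evalue for h in with_taxa)
    retained = [h for h in with_taxa if h.evalue <= factor * min_e]
    if not retained:
        return None
    return tree.lca(h.taxon_id for h in retained)


@dataclass
class GenomeAnnotation:
    """Rank-wise majority annotation of one genome bin."""

    per_rank: dict[str, tuple[int | None, float]]
    chosen_rank: str | None
    chosen_taxon: int | None


def annotate_genome(
    sequence_taxa: Sequence[int | None],
    tree: TaxonomyTree,
    majority: float = 0.50,
) -> GenomeAnnotation:
    """Label a genome bin from its per-sequence taxon assignments.

    At each rank the most frequent rank-level ancestor among classified
    sequences is found; the chosen label is the most specific rank where
    that top taxon's fraction of classified sequences exceeds ``majority``.
    """
    classified = [t for t in sequence_taxa if t is not None]
    per_rank: dict[str, tuple[int | None, float]] = {}
    if not classified:
        return GenomeAnnotation(per_rank={r: (None, 0.0) for r in RANKS},
                                chosen_rank=None, chosen_taxon=None)
    chosen_rank: str | None = None
    chosen_taxon: int | None = None
    for rank in RANKS:
        ancestors = [tree.ancestor_at_rank(t, rank) for t in classified]
        counts = Counter(a for a in ancestors if a is not None)
        if not counts:
            per_rank[rank] = (None, 0.0)
            continue
        top, top_n = counts.most_common(1)[0]
        frac = top_n / len(classified)
        per_rank[rank] = (top, frac)
        if frac > majority:  # most specific passing rank wins (ranks scanned general->specific)
            chosen_rank, chosen_taxon = rank, top
    return GenomeAnnotation(per_rank=per_rank, chosen_rank=chosen_rank, chosen_taxon=chosen_taxon)


def marker_completeness(
    cluster_annotations: Iterable[str],
    marker_set: Sequence[str],
    threshold: float = 0.75,
) -> tuple[float, bool]:
    """Single-copy marker completeness of a bin and its selection verdict.

    Fraction = distinct marker families present / marker set size; a bin
    is selected only when the fraction is strictly above ``threshold``.
    """
    if not marker_set:
        raise MgsConfigError("marker set must be non-empty")
    present = set(cluster_annotations) & set(marker_set)
    fraction = len(present) / len(set(marker_set))
    return fraction, fraction > threshold


def write_tally_tsv(tally: FamilyTally, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tclass\tcount\n")
        for fam in sorted(tally.family_counts):
            fh.write(f"{fam}\t{classify_agarlytic(fam)}\t{tally.family_counts[fam]}\n")
        fh.write(f"TOTAL\t-\t{tally.total}\n")
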