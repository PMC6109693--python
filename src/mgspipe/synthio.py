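"""Seeded synthetic communities with ground truth for every pipeline stage.

The generator emulates the study design that the downstream stages were
built for, without any downloads:

* several source "genomes" at distinct fold-coverages (the condition that
  makes chimeric junctions detectable by coverage difference);
* chimeric contigs concatenating one segment from each of two sources
  with different depths, junction positions recorded;
* uniform-coverage contigs as negative controls;
* paired reads with planted quality-filter failures (low-quality
  stretches, N runs, adapter read-through) at stated rates, plus truth
  alignments written directly as SAM so no external mapper is needed;
* gene-bearing contigs with planted complete and incomplete ORFs,
  organised into redundancy groups of known within-group identity;
* a small NCBI-style taxonomy and taxon-labelled hit tables;
* proteins with and without planted Sec signal-peptide motifs (built to
  match or violate the heuristic caller's n/h/c rules).

Everything is driven by one integer seed; identical seed and config give
byte-identical files.  Reads are error-free substrings by default (an
optional substitution rate is available) — identity clustering and
mapping tests need controllable noise, not a realistic error model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from mgspipe.annotate import AGARLYTIC_FAMILIES, HitRecord, TaxonomyTree
from mgspipe.catalog import OrfRecord, STOP_CODONS
from mgspipe.errors import MgsConfigError
from mgspipe.io import SamAlignment, SequenceRecord, revcomp, write_fasta, write_fastq, write_sam
from mgspipe.readqc import DEFAULT_ADAPTER

_BASES = np.array(list("ACGT"))
_AA20 = "ACDEFGHIKLMNPQRSTVWY"
# residues that are polar/acidic and never satisfy the hydrophobic-core or
# cleavage-site rules: used to build guaranteed-negative protein N-termini
_POLAR_ACIDIC = "DENQ"
_HYDROPHOBIC = "LIVF"

# rng stream labels so each stage draws independently of call order
_S_GENOME, _S_CHIMERA, _S_READS, _S_GENES, _S_PROT, _S_TAX, _S_HITS = range(7)


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters (the defaults are the study conditions the
    synthetic community emulates: 400-bp insert libraries, 150-nt reads,
    10–40× source depths, ~0.97 within-group gene identity)."""

    n_sources: int = 4
    genome_length: int = 40_000
    gc: float = 0.5
    # cyclic chimera pairing gives junction depth ratios 4, 2, 4 and 8 —
    # all in the >=2x regime the coverage-difference correction targets
    depths: tuple[float, ...] = (10.0, 40.0, 20.0, 80.0)
    n_chimeras: int = 4
    chimera_segments: tuple[int, int] = (5000, 3000)
    n_uniform_contigs: int = 4
    uniform_contig_length: int = 8000
    window_size: int = 1000
    read_length: int = 150
    insert_mean: int = 400
    insert_sd: int = 40
    substitution_rate: float = 0.0
    qc_failure_rates: dict[str, float] = field(
        default_factory=lambda: {"low_quality": 0.02, "n_bases": 0.02, "adapter": 0.02}
    )
    adapter: str = DEFAULT_ADAPTER
    n_redundancy_groups: int = 3
    group_size: int = 2
    within_group_identity: float = 0.97
    n_singleton_genes: int = 4
    n_incomplete_orfs: int = 3
    n_proteins: int = 40
    sp_fraction: float = 0.4
    n_phyla: int = 2
    n_genera_per_phylum: int = 2
    n_species_per_genus: int = 2

    def validate(self) -> None:
        if self.n_sources < 1 or len(self.depths) < self.n_sources:
            raise MgsConfigError("need a depth for every source")
        if any(d < 0 for d in self.depths):
            raise MgsConfigError("depths must be non-negative")
        if self.genome_length <= 0 or self.uniform_contig_length <= 0:
            raise MgsConfigError("lengths must be positive")
        if min(self.chimera_segments) < 2 * self.window_size:
            raise MgsConfigError("chimera segments must each span >= 2 windows")
        if self.insert_mean <= self.read_length:
            raise MgsConfigError("insert_mean must exceed read_length")
        if not all(0 <= r <= 1 for r in self.qc_failure_rates.values()):
            raise MgsConfigError("qc failure rates must lie in [0, 1]")
        if sum(self.qc_failure_rates.values()) > 1:
            raise MgsConfigError("qc failure rates must sum to <= 1")
        if not 0 <= self.sp_fraction <= 1:
            raise MgsConfigError("sp_fraction must lie in [0, 1]")
        if not 0 < self.within_group_identity <= 1:
            raise MgsConfigError("within_group_identity must lie in (0, 1]")
        if self.group_size < 2:
            raise MgsConfigError("redundancy groups need >= 2 members")


@dataclass(frozen=True)
class Source:
    source_id: str
    seq: str
    depth: float


@dataclass
class TruthSet:
    """Ground truth for one synthetic community."""

    config: SynthConfig
    seed: int
    sources: list[Source]
    contigs: list[SequenceRecord]  # assembly contigs: chimeras + uniform controls
    contig_depths: dict[str, float | tuple[float, float]]
    chimera_junctions: list[tuple[str, int]]  # (contig id, 0-based junction)
    gene_contigs: list[SequenceRecord]
    planted_orfs: list[OrfRecord]
    orf_complete_truth: dict[str, bool]
    redundancy_groups: list[frozenset[str]]
    gene_seqs: dict[str, str]
    proteins: dict[str, str]
    sp_truth: dict[str, bool]
    taxonomy: TaxonomyTree
    species_ids: list[int]

    def validate(self) -> None:
        lengths = {c.id: len(c) for c in self.contigs}
        for cid, pos in self.chimera_junctions:
            if not 0 < pos < lengths[cid]:
                raise MgsConfigError(f"junction {pos} not strictly inside contig {cid}")
        for grp in self.redundancy_groups:
            if len(grp) < 2:
                raise MgsConfigError("redundancy group with < 2 members")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def random_genome(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


# ---------------------------------------------------------------------------
# chimeras and assembly contigs

def plant_chimeras(truth: TruthSet) -> tuple[list[SequenceRecord], list[tuple[str, int]]]:
    """Construct chimeric contigs joining segments of two depth-distinct
    sources; the junction sits at the concatenation point.

    Deterministic given the truth set's seed (its own rng stream), so a
    repeated call reproduces the same contigs.
    """
    cfg = truth.config
    rng = _rng(truth.seed, _S_CHIMERA)
    contigs: list[SequenceRecord] = []
    junctions: list[tuple[str, int]] = []
    if cfg.n_chimeras == 0:
        return contigs, junctions
    if len({s.depth for s in truth.sources}) < 2:
        raise MgsConfigError("chimeras need >= 2 sources with distinct depths")
    seg1, seg2 = cfg.chimera_segments
    n_src = len(truth.sources)
    for k in range(cfg.n_chimeras):
        a = truth.sources[k % n_src]
        b = truth.sources[(k + 1) % n_src]
        if a.depth == b.depth:
            b = next(s for s in truth.sources if s.depth != a.depth)
        start_a = int(rng.integers(0, len(a.seq) - seg1 + 1))
        start_b = int(rng.integers(0, len(b.seq) - seg2 + 1))
        cid = f"chimera_{k:04d}"
        contigs.append(
            SequenceRecord(cid, a.seq[start_a : start_a + seg1] + b.seq[start_b : start_b + seg2])
        )
        junctions.append((cid, seg1))
        truth.contig_depths[cid] = (a.depth, b.depth)
    return contigs, junctions


def _uniform_contigs(truth: TruthSet) -> list[SequenceRecord]:
    cfg = truth.config
    rng = _rng(truth.seed, _S_CHIMERA + 100)
    out = []
    for k in range(cfg.n_uniform_contigs):
        src = truth.sources[k % len(truth.sources)]
        length = min(cfg.uniform_contig_length, len(src.seq))
        start = int(rng.integers(0, len(src.seq) - length + 1))
        cid = f"uniform_{k:04d}"
        out.append(SequenceRecord(cid, src.seq[start : start + length]))
        truth.contig_depths[cid] = src.depth
    return out


# ---------------------------------------------------------------------------
# genes, ORFs, proteins, taxonomy

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random internal non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute at ``rate`` of the internal positions (first and last
    codons untouched so completeness is preserved)."""
    if rate <= 0:
        return seq
    chars = list(seq)
    internal = np.arange(3, len(seq) - 3)
    n_mut = int(round(rate * len(internal)))
    for pos in rng.choice(internal, size=min(n_mut, len(internal)), replace=False):
        old = chars[pos]
        choices = [b for b in "ACGT" if b != old]
        chars[pos] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


def _gen_genes(truth: TruthSet) -> None:
    cfg = truth.config
    rng = _rng(truth.seed, _S_GENES)
    gene_seqs: dict[str, str] = {}
    groups: list[frozenset[str]] = []
    for g in range(cfg.n_redundancy_groups):
        n_codons = int(rng.integers(200, 500))
        base = _random_cds(rng, n_codons)
        ids = []
        for m in range(cfg.group_size):
            gid = f"grp{g:02d}_m{m}"
            gene_seqs[gid] = base if m == 0 else _mutate(
                rng, base, 1.0 - cfg.within_group_identity
            )
            ids.append(gid)
        groups.append(frozenset(ids))
    for s in range(cfg.n_singleton_genes):
        n_codons = int(rng.integers(200, 500))
        gene_seqs[f"single{s:02d}"] = _random_cds(rng, n_codons)

    contigs: list[SequenceRecord] = []
    orfs: list[OrfRecord] = []
    complete_truth: dict[str, bool] = {}
    for gid, seq in gene_seqs.items():
        flank_l = random_genome(rng, 60, cfg.gc)
        flank_r = random_genome(rng, 60, cfg.gc)
        strand = "+" if rng.random() < 0.5 else "-"
        embedded = seq if strand == "+" else revcomp(seq)
        cid = f"genectg_{gid}"
        contigs.append(SequenceRecord(cid, flank_l + embedded + flank_r))
        orfs.append(OrfRecord(orf_id=gid, contig_id=cid, start=60, end=60 + len(seq), strand=strand))
        complete_truth[gid] = True
    # planted incomplete ORFs: edge-truncated or missing the stop codon
    for k in range(cfg.n_incomplete_orfs):
        n_codons = int(rng.integers(200, 400))
        seq = _random_cds(rng, n_codons)
        gid = f"incomplete{k:02d}"
        cid = f"genectg_{gid}"
        if k % 2 == 0:  # flush with the contig start -> edge-truncated
            contigs.append(SequenceRecord(cid, seq + random_genome(rng, 60, cfg.gc)))
            orfs.append(OrfRecord(gid, cid, 0, len(seq), "+"))
        else:  # stop codon broken
            broken = seq[:-3] + "CCC"
            contigs.append(
                SequenceRecord(cid, random_genome(rng, 60, cfg.gc) + broken + random_genome(rng, 60, cfg.gc))
            )
            orfs.append(OrfRecord(gid, cid, 60, 60 + len(broken), "+"))
        complete_truth[gid] = False

    truth.gene_seqs = gene_seqs
    truth.redundancy_groups = groups
    truth.gene_contigs = contigs
    truth.planted_orfs = orfs
    truth.orf_complete_truth = complete_truth


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA20), size=length))


def _positive_protein(rng: np.random.Generator) -> str:
    """N-terminus engineered to satisfy all three caller rules."""
    n_region = "M" + "KK" + _random_protein(rng, 2).replace("D", "N").replace("E", "Q")
    h_region = "".join(rng.choice(list(_HYDROPHOBIC), size=int(rng.integers(8, 13))))
    cleav = int(rng.integers(18, 31))
    core = n_region + h_region
    pad = "S" * max(0, cleav - 3 - len(core))
    sp = (core + pad)[: cleav - 3] + "A" + "H" + "A"  # -3 A, -1 A
    mature = _random_protein(rng, int(rng.integers(80, 200)))
    return sp + mature


def _negative_protein(rng: np.random.Generator) -> str:
    """N-terminus engineered to violate the caller rules."""
    kind = int(rng.integers(0, 3))
    mature = _random_protein(rng, int(rng.integers(80, 200)))
    if kind == 0:  # acidic, polar N-terminus: fails charge and hydropathy
        head = "M" + "".join(rng.choice(list(_POLAR_ACIDIC), size=44))
        return head + mature
    if kind == 1:  # charged + hydrophobic but no small-neutral cleavage residues
        head = "M" + "KK" + "".join(rng.choice(list("LIVFKRNQ"), size=42))
        return head + mature
    return "V" + mature  # does not start with M


def _gen_proteins(truth: TruthSet) -> None:
    cfg = truth.config
    rng = _rng(truth.seed, _S_PROT)
    proteins: dict[str, str] = {}
    sp_truth: dict[str, bool] = {}
    n_pos = int(round(cfg.n_proteins * cfg.sp_fraction))
    for k in range(cfg.n_proteins):
        pid = f"prot_{k:04d}"
        if k < n_pos:
            proteins[pid] = _positive_protein(rng)
            sp_truth[pid] = True
        else:
            proteins[pid] = _negative_protein(rng)
            sp_truth[pid] = False
    truth.proteins = proteins
    truth.sp_truth = sp_truth


def _gen_taxonomy(cfg: SynthConfig) -> tuple[TaxonomyTree, list[int]]:
    """A small ladder taxonomy branching at phylum, genus and species."""
    nodes: dict[int, tuple[int, str, str]] = {1: (1, "no rank", "root")}
    nodes[2] = (1, "superkingdom", "Bacteria")
    next_id = 3
    species: list[int] = []
    for p in range(cfg.n_phyla):
        ids = {}
        for rank in ("phylum", "class", "order", "family"):
            parent = 2 if rank == "phylum" else ids[prev]
            nodes[next_id] = (parent, rank, f"{rank.capitalize()}_{p}")
            ids[rank] = next_id
            prev = rank
            next_id += 1
        for g in range(cfg.n_genera_per_phylum):
            nodes[next_id] = (ids["family"], "genus", f"Genus_{p}_{g}")
            genus_id = next_id
            next_id += 1
            for s in range(cfg.n_species_per_genus):
                nodes[next_id] = (genus_id, "species", f"Species_{p}_{g}_{s}")
                species.append(next_id)
                next_id += 1
    return TaxonomyTree(nodes), species


# ---------------------------------------------------------------------------
# read simulation

@dataclass
class ReadSimResult:
    pairs: list[tuple[SequenceRecord, SequenceRecord]]
    alignments: list[SamAlignment]
    references: list[tuple[str, int]]
    planted_failures: dict[str, str]  # read id -> rule
    pairs_per_contig: dict[str, int]


def _plant_failure(
    seq: str, qual: str, rule: str, adapter: str
) -> tuple[str, str]:
    if rule == "low_quality":
        # 41 bases at Q20 (> 40 bases at quality <= 38)
        n = min(41, len(qual))
        pos = max(0, (len(qual) - n) // 2)
        qual = qual[:pos] + chr(20 + 33) * n + qual[pos + n :]
    elif rule == "n_bases":
        n = min(11, len(seq))
        pos = max(0, (len(seq) - n) // 2)
        seq = seq[:pos] + "N" * n + seq[pos + n :]
    elif rule == "adapter":
        k = 16  # overlap of 16 nt (> 15)
        seq = seq[: len(seq) - k] + adapter[:k]
    return seq, qual


def simulate_reads(
    truth: TruthSet,
    read_length: int | None = None,
    insert_mean: int | None = None,
    insert_sd: int | None = None,
    qc_failure_rates: dict[str, float] | None = None,
    seed: int | None = None,
) -> ReadSimResult:
    """Paired-end reads from the truth contigs with truth SAM alignments.

    Pair counts follow depth × length / (2 × read length) per contig (per
    segment for chimeras).  Fragments are drawn within a segment, FR
    orientation, flat Q40 quality except planted failures.  Truth
    alignments are written directly — no mapper involved — and cover every
    emitted pair, including those carrying planted QC failures.
    """
    cfg = truth.config
    rl = read_length or cfg.read_length
    imean = insert_mean or cfg.insert_mean
    isd = insert_sd if insert_sd is not None else cfg.insert_sd
    rates = qc_failure_rates if qc_failure_rates is not None else cfg.qc_failure_rates
    if imean <= rl:
        raise MgsConfigError("insert_mean must exceed read_length")
    if not all(0 <= r <= 1 for r in rates.values()):
        raise MgsConfigError("qc failure rates must lie in [0, 1]")
    rng = _rng(seed if seed is not None else truth.seed, _S_READS)

    rules = list(rates)
    cum = np.cumsum([rates[r] for r in rules])
    base_qual = chr(40 + 33) * rl

    pairs: list[tuple[SequenceRecord, SequenceRecord]] = []
    alignments: list[SamAlignment] = []
    planted: dict[str, str] = {}
    per_contig: dict[str, int] = {}
    references = [(c.id, len(c)) for c in truth.contigs]

    def segments_of(contig: SequenceRecord):
        depth = truth.contig_depths[contig.id]
        if isinstance(depth, tuple):
            junction = next(p for cid, p in truth.chimera_junctions if cid == contig.id)
            return [(0, junction, depth[0]), (junction, len(contig), depth[1])]
        return [(0, len(contig), depth)]

    for contig in truth.contigs:
        per_contig[contig.id] = 0
        for seg_start, seg_end, depth in segments_of(contig):
            seg_len = seg_end - seg_start
            n_pairs = int(round(depth * seg_len / (2 * rl)))
            if depth <= 0 or n_pairs == 0:
                continue
            flens = np.clip(
                np.rint(rng.normal(imean, isd, size=n_pairs)).astype(int), rl, seg_len
            )
            # stratified (low-discrepancy) fragment starts: windowed coverage
            # concentrates at the target depth instead of carrying full
            # Poisson sampling noise, so threshold tests probe the detection
            # rules rather than Lander-Waterman fluctuations
            jitter = rng.random(n_pairs)
            starts = seg_start + (
                (np.arange(n_pairs) + jitter) / n_pairs * (seg_len - flens + 1)
            ).astype(int)
            for i in range(n_pairs):
                start, flen = int(starts[i]), int(flens[i])
                end = start + flen
                qname = f"{contig.id}|p{per_contig[contig.id]:06d}"
                per_contig[contig.id] += 1
                s1 = contig.seq[start : start + rl]
                s2 = revcomp(contig.seq[end - rl : end])
                q1 = q2 = base_qual
                if cfg.substitution_rate > 0:
                    s1 = _substitute(rng, s1, cfg.substitution_rate)
                    s2 = _substitute(rng, s2, cfg.substitution_rate)
                for mate, (s, q) in enumerate(((s1, q1), (s2, q2))):
                    u = rng.random()
                    idx = int(np.searchsorted(cum, u, side="right"))
                    if idx < len(rules):
                        rule = rules[idx]
                        s, q = _plant_failure(s, q, rule, cfg.adapter)
                        planted[f"{qname}/{mate + 1}"] = rule
                    if mate == 0:
                        s1, q1 = s, q
                    else:
                        s2, q2 = s, q
                pairs.append(
                    (
                        SequenceRecord(f"{qname}/1", s1, q1),
                        SequenceRecord(f"{qname}/2", s2, q2),
                    )
                )
                alignments.append(
                    SamAlignment(qname, 99, contig.id, start, 60, f"{rl}M", "=", end - rl, flen)
                )
                alignments.append(
                    SamAlignment(qname, 147, contig.id, end - rl, 60, f"{rl}M", "=", start, -flen)
                )
    return ReadSimResult(pairs, alignments, references, planted, per_contig)


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != chars[i]]
            chars[i] = choices[int(rng.integers(0, 3))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# hit tables

def gen_hit_table(
    truth: TruthSet, queries: Sequence[str] | None = None
) -> tuple[dict[str, list[HitRecord]], dict[str, tuple[str, int | None]], dict[str, str], dict[str, int]]:
    """Taxon-labelled hit tables with known truth.

    Each query gets a true CAZy family and a true species; the best hit
    (lowest E) points at the true species, with near-best hits (within the
    10× E-value band) to the same species and one far hit (outside the
    band) to a different genus — so best-hit family assignment recovers the
    family truth and LCA recovers the species truth.
    Returns (hits by query, subject metadata, family truth, taxon truth).
    """
    rng = _rng(truth.seed, _S_HITS)
    if queries is None:
        queries = sorted(truth.gene_seqs)
    fam_pool = sorted(AGARLYTIC_FAMILIES) + ["GH13", "GH3", "GH10"]
    hits: dict[str, list[HitRecord]] = {}
    meta: dict[str, tuple[str, int | None]] = {}
    fam_truth: dict[str, str] = {}
    tax_truth: dict[str, int] = {}
    for q in queries:
        family = fam_pool[int(rng.integers(0, len(fam_pool)))]
        species = truth.species_ids[int(rng.integers(0, len(truth.species_ids)))]
        other = truth.species_ids[int(rng.integers(0, len(truth.species_ids)))]
        fam_truth[q] = family
        tax_truth[q] = species
        exp = int(rng.integers(20, 60))
        best_e = 10.0 ** (-exp)
        rows = [
            (f"{family}|ref|{q}|0", family, species, best_e, 200.0),
            (f"{family}|ref|{q}|1", family, species, 5 * best_e, 180.0),
            (f"{family}|ref|{q}|2", fam_pool[0], other, 1000 * best_e, 90.0),
        ]
        hits[q] = []
        for sid, fam, taxid, ev, bs in rows:
            meta[sid] = (fam, taxid)
            hits[q].append(
                HitRecord(
                    query_id=q,
                    subject_id=sid,
                    percent_identity=float(rng.integers(45, 99)),
                    alignment_length=len(truth.gene_seqs.get(q, "x" * 300)) // 3,
                    evalue=ev,
                    bitscore=bs,
                    taxon_id=taxid,
                )
            )
    return hits, meta, fam_truth, tax_truth


# ---------------------------------------------------------------------------
# top level

def gen_truth_set(config: SynthConfig | None = None, seed: int = 0) -> TruthSet:
    """Generate a full synthetic community; deterministic in (config, seed)."""
    cfg = config or SynthConfig()
    cfg.validate()
    rng = _rng(seed, _S_GENOME)
    sources = [
        Source(f"src_{k:02d}", random_genome(rng, cfg.genome_length, cfg.gc), float(cfg.depths[k]))
        for k in range(cfg.n_sources)
    ]
    taxonomy, species = _gen_taxonomy(cfg)
    truth = TruthSet(
        config=cfg,
        seed=seed,
        sources=sources,
        contigs=[],
        contig_depths={},
        chimera_junctions=[],
        gene_contigs=[],
        planted_orfs=[],
        orf_complete_truth={},
        redundancy_groups=[],
        gene_seqs={},
        proteins={},
        sp_truth={},
        taxonomy=taxonomy,
        species_ids=species,
    )
    chimeras, junctions = plant_chimeras(truth)
    uniform = _uniform_contigs(truth)
    truth.contigs = chimeras + uniform
    truth.chimera_junctions = junctions
    _gen_genes(truth)
    _gen_proteins(truth)
    truth.validate()
    return truth


def write_taxdump(tree: TaxonomyTree, outdir: str | Path) -> tuple[Path, Path]:
    """Write the taxonomy as NCBI-style nodes.dmp / names.dmp."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes_path = outdir / "nodes.dmp"
    names_path = outdir / "names.dmp"
    with open(nodes_path, "w") as fh:
        for taxid in sorted(tree.parent):
            fh.write(f"{taxid}\t|\t{tree.parent[taxid]}\t|\t{tree.rank[taxid]}\t|\n")
    with open(names_path, "w") as fh:
        for taxid in sorted(tree.name):
            fh.write(f"{taxid}\t|\t{tree.name[taxid]}\t|\t\t|\tscientific name\t|\n")
    return nodes_path, names_path


def write_all(truth: TruthSet, outdir: str | Path) -> dict[str, str]:
    """Materialise the community on disk; returns a manifest of paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_reads(truth)
    paths: dict[str, str] = {}

    write_fasta(truth.contigs, outdir / "contigs.fasta")
    write_fasta(truth.gene_contigs, outdir / "gene_contigs.fasta")
    write_fastq((p[0] for p in sim.pairs), outdir / "reads.R1.fastq")
    write_fastq((p[1] for p in sim.pairs), outdir / "reads.R2.fastq")
    write_sam(sim.alignments, sim.references, outdir / "truth_alignments.sam")

    with open(outdir / "orfs.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for orf in truth.planted_orfs:
            fh.write(
                f"{orf.contig_id}\tsynthio\tCDS\t{orf.start + 1}\t{orf.end}\t.\t{orf.strand}\t0\tID={orf.orf_id}\n"
            )
    with open(outdir / "junctions.tsv", "w") as fh:
        fh.write("contig_id\tjunction\n")
        for cid, pos in truth.chimera_junctions:
            fh.write(f"{cid}\t{pos}\n")
    write_fasta(
        (SequenceRecord(pid, seq) for pid, seq in sorted(truth.proteins.items())),
        outdir / "proteins.fasta",
    )
    with open(outdir / "sp_truth.tsv", "w") as fh:
        fh.write("protein_id\thas_sp\n")
        for pid in sorted(truth.sp_truth):
            fh.write(f"{pid}\t{'Y' if truth.sp_truth[pid] else 'N'}\n")
    write_taxdump(truth.taxonomy, outdir / "taxonomy")

    hits, meta, fam_truth, tax_truth = gen_hit_table(truth)
    with open(outdir / "hits.outfmt6.tsv", "w") as fh:
        for q in sorted(hits):
            for h in hits[q]:
                fh.write(
                    f"{h.query_id}\t{h.subject_id}\t{h.percent_identity:.1f}\t{h.alignment_length}"
                    f"\t0\t0\t1\t{h.alignment_length}\t1\t{h.alignment_length}"
                    f"\t{h.evalue:.3g}\t{h.bitscore:.1f}\n"
                )
    with open(outdir / "subjects.tsv", "w") as fh:
        for sid in sorted(meta):
            fam, taxid = meta[sid]
            fh.write(f"{sid}\t{fam}\t{taxid if taxid is not None else ''}\n")
    with open(outdir / "config.yaml", "w") as fh:
        cfg = truth.config
        yaml.safe_dump(
            {
                "seed": truth.seed,
                "n_sources": cfg.n_sources,
                "depths": list(cfg.depths),
                "n_chimeras": cfg.n_chimeras,
                "adapter": cfg.adapter,
            },
            fh,
            sort_keys=True,
        )
    for name in (
        "contigs.fasta", "gene_contigs.fasta", "reads.R1.fastq", "reads.R2.fastq",
        "truth_alignments.sam", "orfs.gff3", "junctions.tsv", "proteins.fasta",
        "sp_truth.tsv", "hits.outfmt6.tsv", "subjects.tsv", "config.yaml",
    ):
        paths[name] = str(outdir / name)
    paths["nodes.dmp"] = str(outdir / "taxonomy" / "nodes.dmp")
    paths["names.dmp"] = str(outdir / "taxonomy" / "names.dmp")
    return paths
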