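# Methods

`mgspipe` implements the bespoke computational stages of a deep
metagenomic survey of a sediment microbial community: read quality
filtering, chimeric-contig correction by coverage discontinuity,
construction of a complete-and-nonredundant (CNR) gene catalog with
length-normalised abundance, CAZy family tallying with an agarlytic class
rollup, near-best-hit LCA taxonomy, single-copy-marker bin gating, and
signal-peptide ratio statistics. This note records the models and rules,
their parameters, the synthetic-data design, and the numerical choices
made where the design was genuinely open.

## Read quality filtering (`readqc`)

Whole paired reads are kept or dropped — never trimmed — by three rules
evaluated in order:

1. more than 40 bases with Phred quality ≤ 38;
2. more than 10 N bases;
3. an adapter overlap longer than 15 nt.

All counts are strict ("more than"), so a read with exactly 40 low-quality
bases, 10 Ns and a 15-nt overlap passes. Qualities are decoded as
Phred+33. "Adapter overlap" is defined as the longest read suffix equal to
an adapter prefix (read-through into the adapter at the 3′ end) or the
longest adapter substring found anywhere in the read, whichever is longer;
this mimics conventional adapter-contamination screens while staying fully
deterministic. A pair is dropped when either mate fails — pairing is
preserved for insert-mode coverage downstream, which needs both mates.
Both mates are always evaluated so per-rule rejection counts are exact.

## Chimera correction (`covsplit`)

Co-assembly of a community can fuse sequence from two organisms into one
contig. Because the organisms occur at different abundances, the fused
contig shows a step in read coverage at the junction. Scaffolds are first
broken at every N run into gap-free scaftigs; pieces shorter than 500 nt
are discarded. Coverage is then profiled in non-overlapping windows
(default 1000 nt) in two modes: *read* mode, where each aligned read
covers its own bases, and *insert* mode, where each properly paired
fragment covers its full outer span. For each adjacent window pair with
mean coverages m1 and m2 the coverage difference is

    CD = |m1 − m2| / min(m1, m2)

and the contig is cut at every window boundary where CD > 0.75 in either
mode (the union of the two cut sets — either signal suffices). Fragments
shorter than 500 nt after cutting are discarded.

Numerical choices:

* **Window size 1000 nt** (configurable). Smaller windows localise the
  junction better but inflate the variance of the window mean; 1000 nt
  balances the two at 10–80× depth. Windows do not overlap; breakpoints
  are placed at window boundaries, not refined within windows, since the
  rule operates on adjacent-window means only.
* **Zero coverage.** CD(0, 0) is defined as 0 (no evidence) and CD with
  exactly one zero as +∞. A minimum-coverage floor (`min_cov`, default 5)
  suppresses pairs whose larger mean is below the floor, so low-coverage
  tails do not produce division-by-near-zero cuts; an infinite CD only
  counts when the nonzero mean is at least the floor.
* Consecutive supra-threshold pairs each produce a cut (no merging).
* Coordinates are 0-based half-open internally and in BED output; FASTA
  fragment ids carry 1-based inclusive ranges for readability.

Known limitation: with iid (Poissonian) read sampling at ~10× depth,
adjacent 1000-nt window means fluctuate enough that CD occasionally
exceeds 0.75 on perfectly uniform contigs (a few events per ~10³ window
pairs). The threshold rule is therefore only reliable at moderate depth
or with smoother coverage; see the synthetic-data section below for how
the generator handles this. The method also shows elevated CD at contig
ends and at partial final windows (coverage ramps), which the default
window/contig geometry avoids but arbitrary inputs may not.

## CNR gene catalog (`catalog`)

Only *complete* ORFs enter the catalog: a start codon (ATG/GTG/TTG), a
stop codon (TAA/TAG/TGA), and neither end flush with a contig edge.
Gene-caller flags (e.g. Prodigal's `partial=XY`) are honoured when
present; otherwise the flags are derived by strand-aware codon inspection,
since GFF dialects differ in how they mark partial genes.

Redundancy is removed by greedy incremental clustering in the CD-HIT
style: sequences sorted by length descending (ties by id), each joining
the first existing cluster whose representative it matches, else founding
a new cluster. Thresholds default to 95% identity over 90% of the shorter
sequence — common gene-catalog practice. Unlike heuristic word filtering,
identity here is computed from a deterministic semi-global alignment
(edlib; the shorter sequence aligned within the representative with free
end gaps): identity = matches / alignment columns, coverage = fraction of
the shorter sequence aligned to residues rather than gaps. This makes
every clustering decision reproducible and checkable against a
dynamic-programming oracle. Because of the length sort the founder is
always the longest member and remains representative; re-clustering the
representatives is a fixed point.

Gene abundance is length-normalised read density:

    a_i = (r_i / L_i) / Σ_j (r_j / L_j)

where r_i counts reads whose *primary* alignment is to gene i (no
multi-mapping fractions, no MAPQ filter) — the simplest auditable counting
rule. Abundances sum to 1 whenever any read maps; with zero mapped reads
they are undefined and reported as 0 with a warning.

## Annotation (`annotate`)

**Best hit.** Tabular protein alignments (outfmt6) are filtered at
E ≤ 1e-5; the minimum-E hit wins, ties broken by maximum bit score, then
lexicographically smallest subject id. One family label per query (the
best hit's), even for multi-domain proteins.

**Agarlytic classes.** GH16, GH50 and GH86 are β-agarases (cleaving the
β-1,4 linkages of agarose), GH96 the α-agarases (α-1,3 linkages), and
GH117 the α-1,3-neoagarobiose hydrolases (NABH); all other families are
non-agarlytic. Family tallies count queries per label and roll up these
classes.

**LCA taxonomy.** For each sequence, hits with E-value within 10× of that
sequence's minimum E-value are retained — the near-best band standard in
MEGAN-style LCA workflows — and the assignment is the deepest taxonomy
node ancestral to (or equal to) every retained hit's taxon: the node
before the first branch of the retained lineages. Reference databases are
not bundled; the module consumes precomputed tabular hits plus a sidecar
TSV mapping subject ids to family and taxon, keeping the artifact
download-free and database-version-independent. The taxonomy itself is an
NCBI-style nodes.dmp/names.dmp pair.

**Genome bins.** A bin is labelled by rank-wise majority vote over its
classified sequences: at each rank the most frequent rank-level ancestor
is found, and the chosen label is the most specific rank whose top
fraction exceeds the majority threshold (default 0.50, configurable —
the voting fraction is the principle; the cutoff is an open parameter).
Candidate bins are gated on single-copy marker completeness: the fraction
of the marker set present must be *strictly* above 0.75.

## Signal peptides (`sigpep`)

Secretion requires an N-terminal Sec signal peptide. Production analyses
ingest an external predictor's per-protein calls from TSV. For synthetic
ground-truth testing the package ships a deterministic stand-in caller
implementing the classical n/h/c-region rules (it is explicitly not a
reimplementation of any trained predictor): positive charge (≥ +1 net
K/R−D/E over residues 2–6), a hydrophobic core (some 7-residue window in
residues 3–25 with mean Kyte–Doolittle hydropathy ≥ 1.6), and an A-X-A
style cleavage site at position 15–45 with small neutral residues
(A/G/S/C/T) at −3 and −1. Proteins shorter than 15 residues or not
starting with M are negative.

The secretion statistic per group is the ratio of proteins with a signal
peptide to those without, reported at 2 decimals (full precision is kept
internally); ratio and percent-with are consistent by construction,
ratio = p/(100−p). A ratio can also be reconstructed from a published
percentage: given the group size, counts are recovered as rounded
integers first — the way a printed percentage arises from real counts —
which matters at 2-dp precision (64.6% of 424 gives 274/150 = 1.83,
whereas 64.6/35.4 alone rounds to 1.82).

Group differences are tested on the 2×2 with/without table using the
chi-square test with continuity correction, substituting Fisher's exact
test when any expected cell count is below 5 or a margin is zero (the
standard 2×2 procedure; the choice of test is a package decision, as is
reporting two-sided p-values).

## Synthetic communities (`synthio`)

The generator emulates the study design with known ground truth, driven
by a single integer seed (identical seed + config reproduce every file
byte-identically; each stage draws from its own seeded stream so stages
are order-independent).

* **Sources and depths.** Four source genomes (40 kb, GC 0.5) at 10×,
  40×, 20× and 80×. Chimeric contigs pair sources cyclically, so junction
  depth ratios are 4, 2, 4 and 8 — all in the ≥ 2× regime the CD rule
  targets, with every depth at least the 10× working floor. Segments are
  5 kb + 3 kb (each ≥ 2 windows), junction recorded at the concatenation
  point; uniform 8-kb contigs serve as negative controls.
* **Reads.** 150-nt pairs, 400 ± 40 nt inserts (the short-insert library
  geometry), FR orientation, flat Q40 quality, error-free substrings by
  default with an optional substitution rate. Per-segment pair counts are
  depth × length / (2 × read length). Truth alignments are written
  directly as SAM (match-only CIGARs) rather than produced by a mapper,
  removing an external-tool dependency.
* **Fragment placement is stratified**, not iid: fragment k of n starts
  uniformly within the k-th of n equal strata of the admissible start
  range. Windowed coverage therefore concentrates within ~5% of the
  target depth instead of carrying full Lander–Waterman noise, whose
  tails at 10× would by themselves cross the CD threshold a few times per
  thousand window pairs. This is a deliberate non-feature, in line with
  the generator's other simplifications (no error profiles, no GC bias,
  no strain microdiversity): passing tests demonstrate the correctness of
  the detection rules under their intended signal, not robustness to
  low-coverage sampling noise on real data.
* **QC failures** are planted per read at configured rates (2% each):
  41 bases at Q20, an 11-base N run, or a 16-nt adapter suffix (the fixed
  33-nt synthetic adapter) — each a minimal violation of one rule.
* **Genes** are random codon sequences (ATG … TAA, 600–1500 nt) organised
  into redundancy groups mutated to 97% within-group identity (first and
  last codons untouched), plus singletons and planted incomplete ORFs
  (edge-truncated or stop-less), each embedded in a flanked gene contig.
  Between-group identity of random sequences is ≈ 25%, far below the 80%
  the recovery property assumes as its upper bound.
* **Proteins** are built to match or violate the heuristic caller's rules
  (positive: charged n-region + LIVF core + A-X-A site at 18–30;
  negative: acidic/polar head, or no small-neutral residues in the
  cleavage window, or no initial M), 40% positives by default.
* **Taxonomy and hits.** A small ladder taxonomy (root → Bacteria →
  2 phyla → … → 2 genera × 2 species each) written as nodes.dmp/names.dmp;
  hit tables give each query a best hit and a near-best hit (within the
  10× band) to its true species and one far hit outside the band, so
  best-hit and LCA assignment have exact expected outcomes.

## Pipeline and determinism

`run_pipeline` executes readqc → covsplit → catalog → annotate → sigpep
on a synthetic community, echoes every threshold into the JSON report,
and is bitwise deterministic in (config, seed); timestamps are excluded.
Chimera correction runs on the assembly contigs while the catalog runs on
the separate gene-bearing contigs, because ORF coordinates from the
(external) gene caller refer to the uncut sequences.

## Problem sizes

The default community (4 sources, 8 assembly contigs, ~5600 read pairs,
13 ORFs, 40 proteins) exercises every stage in seconds. The recovery
statistics in `scripts/acceptance.py` use 50 chimeras + 50 uniform
contigs (~100k read pairs), 10 redundancy groups + 10 singletons, and 200
proteins — large enough for stable proportions while keeping a full run
under half a minute on one core.
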