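"""End-to-end orchestration from a single config.

Stages run in pipeline order — read QC → chimera correction → CNR catalog
→ annotation → signal peptides — over either user-supplied files or a
seeded synthetic community.  The run report echoes every threshold
verbatim and records counts at each stage; identical config + seed give
an identical report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from mgspipe import annotate, catalog, covsplit, readqc, sigpep, synthio
from mgspipe.errors import MgsConfigError, MgsError
from mgspipe.io import write_fasta


@dataclass
class PipelineConfig:
    """All tunables in one place; every value is echoed into the report."""

    seed: int = 0
    workdir: str = "mgs_run"
    # read QC
    max_low_quality_bases: int = 40
    low_quality_threshold: int = 38
    max_n_bases: int = 10
    max_adapter_overlap: int = 15
    # scaftigs / chimera correction
    min_scaftig_length: int = 500
    window_size: int = 1000
    cd_threshold: float = 0.75
    min_cov: float = 5.0
    # catalog
    cluster_identity: float = 0.95
    cluster_coverage: float = 0.90
    # annotation
    e_cutoff: float = 1e-5
    lca_factor: float = 10.0
    marker_threshold: float = 0.75
    majority: float = 0.50
    # synthetic input
    synth: synthio.SynthConfig = field(default_factory=synthio.SynthConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_raw = raw.pop("synth", {})
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise MgsConfigError(f"unknown config keys: {sorted(unknown)}")
        if synth_raw:
            if "depths" in synth_raw:
                synth_raw["depths"] = tuple(synth_raw["depths"])
            if "chimera_segments" in synth_raw:
                synth_raw["chimera_segments"] = tuple(synth_raw["chimera_segments"])
            cfg.synth = synthio.SynthConfig(**synth_raw)
        return cfg

    def params_echo(self) -> dict:
        d = asdict(self)
        d.pop("synth")
        d["synth"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(self.synth).items()
        }
        return d


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic community; returns the run report.

    The report is JSON-serialisable, timestamp-free and fully determined
    by (config, seed).
    """
    try:
        return _run(config)
    except MgsError:
        raise
    except Exception as exc:  # annotate failures with the stage if possible
        raise MgsError(f"pipeline failed: {exc}") from exc


def _run(config: PipelineConfig) -> dict:
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": config.params_echo(), "stages": {}}

    # --- synthesize
    truth = synthio.gen_truth_set(config.synth, seed=config.seed)
    paths = synthio.write_all(truth, workdir / "synth")
    sim = synthio.simulate_reads(truth)
    report["stages"]["synth"] = {
        "sources": len(truth.sources),
        "contigs": len(truth.contigs),
        "chimera_junctions": len(truth.chimera_junctions),
        "gene_contigs": len(truth.gene_contigs),
        "planted_orfs": len(truth.planted_orfs),
        "proteins": len(truth.proteins),
        "read_pairs": len(sim.pairs),
    }

    # --- read QC
    params = readqc.ReadFilterParams(
        max_low_quality_bases=config.max_low_quality_bases,
        low_quality_threshold=config.low_quality_threshold,
        max_n_bases=config.max_n_bases,
        max_adapter_overlap=config.max_adapter_overlap,
        adapters=(truth.config.adapter,),
    )
    kept, summary = readqc.filter_pairs(
        (p[0] for p in sim.pairs), (p[1] for p in sim.pairs), params
    )
    report["stages"]["readqc"] = summary.as_dict()

    # --- chimera correction on assembly contigs using truth alignments
    scaftigs = list(covsplit.make_scaftigs(truth.contigs, config.min_scaftig_length))
    bp_read: list[covsplit.Breakpoint] = []
    bp_insert: list[covsplit.Breakpoint] = []
    for mode, store in ((covsplit.MODE_READ, bp_read), (covsplit.MODE_INSERT, bp_insert)):
        profiles = covsplit.coverage_profiles(
            sim.alignments, scaftigs, config.window_size, mode
        )
        for profile in profiles.values():
            store.extend(
                covsplit.find_breakpoints(profile, config.cd_threshold, config.min_cov)
            )
    fragments, bed_rows, n_dropped = covsplit.split_contigs(
        scaftigs, bp_read, bp_insert, config.min_scaftig_length
    )
    write_fasta(fragments, workdir / "corrected_contigs.fasta")
    with open(workdir / "cuts.bed", "w") as fh:
        for row in bed_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    report["stages"]["covsplit"] = {
        "scaftigs": len(scaftigs),
        "breakpoints_read": len(bp_read),
        "breakpoints_insert": len(bp_insert),
        "cut_positions": len({(r[0], r[1]) for r in bed_rows}),
        "fragments": len(fragments),
        "fragments_dropped": n_dropped,
    }

    # --- CNR catalog from gene-bearing contigs and planted ORF calls
    entries, rep_seqs = catalog.build_cnr_catalog(
        truth.planted_orfs,
        truth.gene_contigs,
        config.cluster_identity,
        config.cluster_coverage,
    )
    gene_alns = [
        synthio.SamAlignment(f"gr_{gid}_{i}", 0, gid, 0, 60, f"{min(100, len(seq))}M")
        for gid, seq in sorted(rep_seqs.items())
        for i in range(max(1, len(seq) // 300))
    ]
    entries = catalog.relative_abundance(entries, gene_alns)
    catalog.write_catalog_tsv(entries, workdir / "catalog.tsv")
    n_complete = sum(len(e.members) for e in entries)
    report["stages"]["catalog"] = {
        "orfs_in": len(truth.planted_orfs),
        "complete_orfs": n_complete,
        "entries": len(entries),
        "abundance_sum": sum(e.relative_abundance for e in entries),
    }

    # --- annotation
    hits, meta, fam_truth, tax_truth = synthio.gen_hit_table(
        truth, queries=sorted(rep_seqs)
    )
    assignments = {}
    for q, qhits in hits.items():
        best = annotate.assign_best_hit(qhits, config.e_cutoff)
        if best is not None:
            assignments[q] = meta[best.subject_id][0]
    tally = annotate.tally_families(assignments)
    annotate.write_tally_tsv(tally, workdir / "family_tally.tsv")
    taxa = [
        annotate.lca_assign(qhits, truth.taxonomy, config.lca_factor)
        for qhits in hits.values()
    ]
    genome = annotate.annotate_genome(taxa, truth.taxonomy, config.majority)
    report["stages"]["annotate"] = {
        "queries": len(hits),
        "assigned": len(assignments),
        "tally_total": tally.total,
        "class_counts": dict(tally.class_counts),
        "lca_classified": sum(1 for t in taxa if t is not None),
        "genome_rank": genome.chosen_rank,
        "genome_taxon": (
            truth.taxonomy.name[genome.chosen_taxon] if genome.chosen_taxon else None
        ),
    }

    # --- signal peptides
    calls = [
        sigpep.call_signal_peptide(seq, pid, "synthetic")
        for pid, seq in sorted(truth.proteins.items())
    ]
    ratio = sigpep.group_ratio("synthetic", calls)
    sigpep.write_ratio_tsv([ratio], workdir / "sp_ratio.tsv")
    correct = sum(
        1 for c in calls if c.has_sp == truth.sp_truth[c.protein_id]
    )
    report["stages"]["sigpep"] = {
        "proteins": len(calls),
        "n_with": ratio.n_with,
        "n_without": ratio.n_without,
        "percent_with": ratio.percent_with,
        "label_accuracy": correct / len(calls),
    }

    report["outputs"] = {
        "synth": paths,
        "corrected_contigs": str(workdir / "corrected_contigs.fasta"),
        "cuts_bed": str(workdir / "cuts.bed"),
        "catalog": str(workdir / "catalog.tsv"),
        "family_tally": str(workdir / "family_tally.tsv"),
        "sp_ratio": str(workdir / "sp_ratio.tsv"),
    }
    with open(workdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
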