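"""Best-hit assignment, family tallies, LCA taxonomy, marker gating."""

import numpy as np
import pytest

from mgspipe import annotate, synthio
from mgspipe.annotate import (
    FamilyTally,
    HitRecord,
    TaxonomyTree,
    annotate_genome,
    assign_best_hit,
    classify_agarlytic,
    lca_assign,
    marker_completeness,
    tally_families,
)
from mgspipe.errors import MgsConfigError, MgsDataError


def _hit(q="q", s="s", e=1e-10, bits=100.0, taxid=None):
    return HitRecord(q, s, 90.0, 100, e, bits, taxid)


class TestBestHit:
    def test_minimum_evalue_wins(self):
        best = assign_best_hit([_hit(s="a", e=1e-8), _hit(s="b", e=1e-10)])
        assert best.subject_id == "b"

    def test_cutoff_excludes_weak_hits(self):
        assert assign_best_hit([_hit(e=1e-4)]) is None
        assert assign_best_hit([_hit(e=1e-5)]) is not None  # at the cutoff survives

    def test_tie_broken_by_bitscore_then_subject(self):
        best = assign_best_hit([_hit(s="a", e=1e-20, bits=180), _hit(s="b", e=1e-20, bits=250)])
        assert best.subject_id == "b"
        best = assign_best_hit([_hit(s="b", e=1e-20, bits=250), _hit(s="a", e=1e-20, bits=250)])
        assert best.subject_id == "a"

    def test_never_returns_hit_above_cutoff(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            hits = [_hit(s=str(i), e=10.0 ** -rng.integers(2, 12)) for i in range(5)]
            best = assign_best_hit(hits)
            if best is not None:
                assert best.evalue <= 1e-5


class TestAgarlyticClasses:
    @pytest.mark.parametrize(
        "family,cls",
        [
            ("GH16", annotate.CLASS_BETA),
            ("GH50", annotate.CLASS_BETA),
            ("GH86", annotate.CLASS_BETA),
            ("GH96", annotate.CLASS_ALPHA),
            ("GH117", annotate.CLASS_NABH),
            ("GH13", annotate.CLASS_NONE),
            ("CBM6", annotate.CLASS_NONE),
        ],
    )
    def test_family_class_map(self, family, cls):
        assert classify_agarlytic(family) == cls

    def test_spaced_labels_normalised(self):
        assert classify_agarlytic("GH 117") == annotate.CLASS_NABH


class TestTally:
    def _assignments(self, counts):
        out = {}
        k = 0
        for fam, n in counts.items():
            for _ in range(n):
                out[f"q{k}"] = fam
                k += 1
        return out

    def test_control_group_family_counts_total(self):
        """Per-family counts 204/17/3/4/34 over GH16/50/86/96/117 total 262
        complete nonredundant agarlytic genes."""
        counts = {"GH16": 204, "GH50": 17, "GH86": 3, "GH96": 4, "GH117": 34}
        tally = tally_families(self._assignments(counts))
        assert tally.family_counts == counts
        assert tally.total == 262
        assert tally.class_counts[annotate.CLASS_BETA] == 224
        assert tally.class_counts[annotate.CLASS_NABH] == 34

    def test_empty_assignments(self):
        tally = tally_families({})
        assert tally.total == 0 and tally.family_counts == {}

    def test_nabh_only_rollup(self):
        tally = tally_families(self._assignments({"GH117": 5}))
        assert tally.class_counts[annotate.CLASS_NABH] == 5
        assert tally.class_counts[annotate.CLASS_BETA] == 0

    def test_total_equals_assigned_queries(self, truth):
        hits, meta, fam_truth, _ = synthio.gen_hit_table(truth)
        assignments = {}
        for q, qhits in hits.items():
            best = assign_best_hit(qhits)
            if best:
                assignments[q] = meta[best.subject_id][0]
        tally = tally_families(assignments)
        assert tally.total == len(assignments)
        # best hits recover the planted family truth
        assert assignments == fam_truth


def _ladder_tree():
    # root 1 -> kingdom 2 -> genus 10 -> species 11, 12 ; genus 20 -> species 21
    nodes = {
        1: (1, "no rank", "root"),
        2: (1, "superkingdom", "Bacteria"),
        3: (2, "family", "Fam"),
        10: (3, "genus", "G1"),
        11: (10, "species", "G1 s1"),
        12: (10, "species", "G1 s2"),
        20: (3, "genus", "G2"),
        21: (20, "species", "G2 s1"),
    }
    return TaxonomyTree(nodes)


class TestLca:
    def test_single_species_assigned_directly(self):
        tree = _ladder_tree()
        hits = [_hit(e=1e-30, taxid=11), _hit(e=2e-30, taxid=11)]
        assert lca_assign(hits, tree) == 11

    def test_two_species_same_genus_gives_genus(self):
        tree = _ladder_tree()
        hits = [_hit(e=1e-30, taxid=11), _hit(e=2e-30, taxid=12)]
        assert lca_assign(hits, tree) == 10

    def test_near_best_filter_excludes_distant_evalues(self):
        """min E = 1e-50; hits at 1e-50 and 2e-50 to species X retained,
        the 1e-30 hit to species Y falls outside the 10x band."""
        tree = _ladder_tree()
        hits = [
            _hit(s="a", e=1e-50, taxid=11),
            _hit(s="b", e=2e-50, taxid=11),
            _hit(s="c", e=1e-30, taxid=21),
        ]
        assert lca_assign(hits, tree) == 11

    def test_no_taxon_hits_unclassified(self):
        assert lca_assign([_hit(taxid=None)], _ladder_tree()) is None

    def test_missing_taxon_raises(self):
        with pytest.raises(MgsDataError):
            lca_assign([_hit(taxid=999)], _ladder_tree())

    def test_matches_lineage_intersection_oracle_on_random_trees(self):
        """Exact agreement with a naive oracle (intersect full root-to-leaf
        lineages of retained hits, take the last common node) on 100 random
        trees of up to 200 nodes."""
        rng = np.random.default_rng(123)
        for _ in range(100):
            n = int(rng.integers(5, 200))
            nodes = {1: (1, "no rank", "root")}
            for tid in range(2, n + 1):
                parent = int(rng.integers(1, tid))
                nodes[tid] = (parent, "no rank", f"n{tid}")
            tree = TaxonomyTree(nodes)
            taxa = rng.integers(1, n + 1, size=int(rng.integers(1, 6)))
            evalues = 10.0 ** -rng.integers(6, 40, size=len(taxa))
            hits = [
                _hit(s=str(i), e=float(evalues[i]), taxid=int(taxa[i]))
                for i in range(len(taxa))
            ]
            got = lca_assign(hits, tree)
            # oracle: brute-force filter + lineage intersection
            min_e = min(evalues)
            retained = [int(t) for t, e in zip(taxa, evalues) if e <= 10 * min_e]
            lineages = [tree.lineage(t) for t in retained]
            common = None
            for depth in range(min(len(l) for l in lineages)):
                level = {l[depth] for l in lineages}
                if len(level) == 1:
                    common = level.pop()
                else:
                    break
            assert got == common


class TestAnnotateGenome:
    def test_majority_genus_label(self):
        tree = _ladder_tree()
        taxa = [11, 11, 11, 12, 12, 12, 21, 21, 21, 21]
        ann = annotate_genome(taxa, tree)  # 6/10 under genus G1
        assert ann.chosen_rank == "genus" and ann.chosen_taxon == 10

    def test_falls_back_to_broader_rank(self):
        tree = _ladder_tree()
        taxa = [11, 11, 21, 21, 12]  # top genus 0.6, top family 1.0
        assert annotate_genome(taxa, tree, majority=0.5).chosen_rank == "genus"
        # at 0.7 the genus vote fails but the family vote (1.0) passes
        assert annotate_genome(taxa, tree, majority=0.7).chosen_rank == "family"

    def test_single_classified_sequence_full_lineage(self):
        tree = _ladder_tree()
        ann = annotate_genome([11], tree)
        assert ann.chosen_rank == "species" and ann.chosen_taxon == 11
        for rank in ("superkingdom", "genus", "species"):
            assert ann.per_rank[rank][1] == pytest.approx(1.0)

    def test_all_unclassified(self):
        ann = annotate_genome([None, None], _ladder_tree())
        assert ann.chosen_rank is None and ann.chosen_taxon is None

    def test_raising_majority_never_more_specific(self):
        """Monotonicity: a stricter majority can only broaden the label."""
        tree = _ladder_tree()
        rng = np.random.default_rng(5)
        rank_depth = {r: i for i, r in enumerate(annotate.RANKS)}
        for _ in range(20):
            taxa = [int(t) for t in rng.choice([11, 12, 21], size=8)]
            prev_depth = None
            for majority in (0.3, 0.5, 0.7, 0.9):
                ann = annotate_genome(taxa, tree, majority)
                depth = -1 if ann.chosen_rank is None else rank_depth[ann.chosen_rank]
                if prev_depth is not None:
                    assert depth <= prev_depth
                prev_depth = depth


class TestMarkerCompleteness:
    def test_above_threshold_selected(self):
        markers = [f"m{i}" for i in range(100)]
        frac, selected = marker_completeness(markers[:76], markers)
        assert frac == pytest.approx(0.76) and selected

    def test_exactly_threshold_not_selected(self):
        markers = [f"m{i}" for i in range(100)]
        frac, selected = marker_completeness(markers[:75], markers)
        assert frac == pytest.approx(0.75) and not selected

    def test_none_present(self):
        frac, selected = marker_completeness([], ["a", "b"])
        assert frac == 0.0 and not selected

    def test_duplicates_count_once(self):
        frac, _ = marker_completeness(["a", "a", "a"], ["a", "b"])
        assert frac == pytest.approx(0.5)

    def test_empty_marker_set_raises(self):
        with pytest.raises(MgsConfigError):
            marker_completeness(["a"], [])


class TestTaxdumpRoundTrip:
    def test_written_dump_reloads_identically(self, truth, tmp_path):
        nodes_p, names_p = synthio.write_taxdump(truth.taxonomy, tmp_path)
        tree = TaxonomyTree.from_taxdump(nodes_p, names_p)
        assert tree.parent == truth.taxonomy.parent
        assert tree.rank == truth.taxonomy.rank
        assert tree.name == truth.taxonomy.name

    def test_two_roots_rejected(self):
        with pytest.raises(MgsDataError):
            TaxonomyTree({1: (1, "no rank", "r1"), 2: (2, "no rank", "r2")})


class TestOutfmt6:
    def test_round_trip_with_metadata(self, truth, tmp_path):
        paths = synthio.write_all(truth, tmp_path)
        meta = annotate.read_subject_metadata(paths["subjects.tsv"])
        hits = annotate.read_outfmt6(paths["hits.outfmt6.tsv"], meta)
        direct, meta2, _, _ = synthio.gen_hit_table(truth)
        assert set(hits) == set(direct)
        for q in hits:
            assert [h.subject_id for h in hits[q]] == [h.subject_id for h in direct[q]]
            assert [h.taxon_id for h in hits[q]] == [h.taxon_id for h in direct[q]]

    def test_malformed_line_reports_line_number(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("q\ts\tnot_a_number\t1\t0\t0\t1\t1\t1\t1\t1e-9\t50\n")
        with pytest.raises(MgsDataError, match="1"):
            annotate.read_outfmt6(bad)
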