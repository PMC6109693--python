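"""Scaftigs, windowed coverage, CD breakpoints, contig splitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mgspipe import covsplit, synthio
from mgspipe.covsplit import (
    Breakpoint,
    CoverageProfile,
    MODE_INSERT,
    MODE_READ,
    compute_cd,
    find_breakpoints,
    make_scaftigs,
    split_contigs,
    window_coverage,
)
from mgspipe.errors import MgsDataError
from mgspipe.io import SamAlignment, SequenceRecord


class TestMakeScaftigs:
    def test_split_at_n_both_pieces_survive(self):
        rec = SequenceRecord("sc", "A" * 600 + "NN" + "C" * 700)
        out = list(make_scaftigs([rec]))
        assert [len(s) for s in out] == [600, 700]
        assert out[0].id == "sc_scaftig1:1-600"
        assert out[1].id == "sc_scaftig2:603-1302"

    def test_no_n_emitted_unchanged(self):
        rec = SequenceRecord("sc", "A" * 900)
        assert list(make_scaftigs([rec])) == [rec]

    def test_short_piece_dropped(self):
        rec = SequenceRecord("sc", "A" * 400 + "N" + "C" * 900)
        out = list(make_scaftigs([rec]))
        assert [len(s) for s in out] == [900]

    def test_runs_of_multiple_ns_are_one_gap(self):
        rec = SequenceRecord("sc", "A" * 500 + "N" * 50 + "C" * 500)
        out = list(make_scaftigs([rec]))
        assert [len(s) for s in out] == [500, 500]


class TestWindowCoverage:
    def test_single_read_partial_window(self):
        contig = SequenceRecord("c", "A" * 1000)
        aln = [SamAlignment("r", 0, "c", 0, 60, "100M")]
        prof = window_coverage(aln, contig, window_size=1000)
        assert prof.window_means.tolist() == [0.1]

    def test_no_alignments_all_zero(self):
        contig = SequenceRecord("c", "A" * 2500)
        prof = window_coverage([], contig, window_size=1000)
        assert prof.window_means.tolist() == [0.0, 0.0, 0.0]
        assert len(prof.window_means) == math.ceil(2500 / 1000)

    def test_partial_final_window_uses_true_length(self):
        contig = SequenceRecord("c", "A" * 1500)
        aln = [SamAlignment("r", 0, "c", 1000, 60, "500M")]
        prof = window_coverage(aln, contig, window_size=1000)
        assert prof.window_means.tolist() == [0.0, 1.0]

    def test_alignment_beyond_contig_end_raises(self):
        contig = SequenceRecord("c", "A" * 100)
        with pytest.raises(MgsDataError):
            window_coverage([SamAlignment("r", 0, "c", 50, 60, "100M")], contig)

    def test_insert_mode_covers_fragment_span(self):
        contig = SequenceRecord("c", "A" * 1000)
        alns = [
            SamAlignment("p", 99, "c", 0, 60, "100M", "=", 300, 400),
            SamAlignment("p", 147, "c", 300, 60, "100M", "=", 0, -400),
        ]
        prof = window_coverage(alns, contig, window_size=1000, mode=MODE_INSERT)
        assert prof.window_means.tolist() == [0.4]  # 400 covered bases, counted once

    def test_unpaired_skipped_in_insert_mode(self):
        intervals, skipped = covsplit.coverage_intervals(
            [SamAlignment("r", 0, "c", 0, 60, "100M")], "c", MODE_INSERT
        )
        assert intervals == [] and skipped == 1

    def test_matches_per_base_pileup_oracle(self, truth, sim):
        """Window means equal a naive per-base pileup computed base by base."""
        contig = truth.contigs[0]
        for mode in (MODE_READ, MODE_INSERT):
            prof = window_coverage(sim.alignments, contig, 1000, mode)
            depth = [0] * len(contig)
            for a in sim.alignments:
                if a.rname != contig.id:
                    continue
                if mode == MODE_READ:
                    span = range(a.pos, a.pos + covsplit.cigar_reference_length(a.cigar))
                else:
                    if a.tlen <= 0:
                        continue
                    span = range(a.pos, a.pos + a.tlen)
                for i in span:
                    depth[i] += 1
            oracle = [
                sum(depth[s : s + 1000]) / len(depth[s : s + 1000])
                for s in range(0, len(contig), 1000)
            ]
            assert prof.window_means.tolist() == pytest.approx(oracle, abs=1e-12)

    def test_uniform_contig_windows_near_target_depth(self, truth, sim):
        """Interior window means on a uniform 20x contig sit within 10% of
        the target depth (contig-end windows carry the sampling ramp)."""
        contig = next(
            c for c in truth.contigs
            if c.id.startswith("uniform") and truth.contig_depths[c.id] >= 10
        )
        depth = truth.contig_depths[contig.id]
        prof = window_coverage(sim.alignments, contig, 1000, MODE_READ)
        interior = prof.window_means[1:-1]
        assert np.all(np.abs(interior - depth) / depth < 0.10)


class TestComputeCd:
    @pytest.mark.parametrize(
        "m1,m2,expected",
        [(10, 20, 1.0), (7, 7, 0.0), (100, 60, 2 / 3), (30, 60, 1.0)],
    )
    def test_direct_formula(self, m1, m2, expected):
        assert compute_cd(m1, m2) == pytest.approx(expected)

    def test_100_vs_60_not_over_threshold(self):
        assert compute_cd(100, 60) < 0.75

    def test_zero_handling(self):
        assert compute_cd(0, 0) == 0.0
        assert compute_cd(0, 30) == math.inf
        with pytest.raises(MgsDataError):
            compute_cd(-1, 5)

    @given(
        st.floats(min_value=0.01, max_value=1e6),
        st.floats(min_value=0.01, max_value=1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_and_matches_formula(self, a, b):
        assert compute_cd(a, b) == compute_cd(b, a)
        assert compute_cd(a, b) == pytest.approx(abs(a - b) / min(a, b))


def _profile(means, window=1000):
    means = np.asarray(means, dtype=float)
    return CoverageProfile("c", MODE_READ, window, means, len(means) * window)


class TestFindBreakpoints:
    def test_flat_profile_no_breakpoints(self):
        assert find_breakpoints(_profile([30, 30, 30, 30])) == []

    def test_single_step_detected_at_boundary(self):
        bps = find_breakpoints(_profile([30, 30, 60, 60]))
        assert len(bps) == 1
        assert bps[0].position == 2000
        assert bps[0].cd_value == pytest.approx(1.0)

    def test_one_sided_zero_with_sufficient_coverage_cuts(self):
        bps = find_breakpoints(_profile([0, 0, 30, 30]), min_cov=5)
        assert [b.position for b in bps] == [2000]
        assert bps[0].cd_value == math.inf

    def test_low_coverage_pairs_suppressed(self):
        assert find_breakpoints(_profile([1, 4, 1, 4]), min_cov=5) == []

    def test_cd_exactly_at_threshold_not_cut(self):
        # 35 vs 20 -> CD = 0.75 exactly: "over 0.75" is strict
        assert find_breakpoints(_profile([20, 35])) == []
        assert find_breakpoints(_profile([20, 35.1]))

    def test_single_window_profile_empty(self):
        assert find_breakpoints(_profile([30])) == []

    def test_matches_exhaustive_adjacent_pair_oracle(self):
        rng = np.random.default_rng(42)
        means = rng.uniform(0, 50, size=40)
        prof = _profile(means)
        got = {(b.position, b.cd_value) for b in find_breakpoints(prof, 0.75, 5)}
        expected = set()
        for i in range(39):
            m1, m2 = means[i], means[i + 1]
            if max(m1, m2) < 5:
                continue
            cd = compute_cd(m1, m2)
            if cd > 0.75:
                expected.add(((i + 1) * 1000, cd))
        assert got == expected


class TestSplitContigs:
    def test_no_breakpoints_identity(self):
        contigs = [SequenceRecord("c", "A" * 700)]
        frags, bed, dropped = split_contigs(contigs, [], [])
        assert frags == contigs and bed == [] and dropped == 0

    def test_single_cut_arithmetic(self):
        contig = SequenceRecord("c", "A" * 5000 + "C" * 3000)
        bp = [Breakpoint("c", 5000, 2.0, MODE_READ)]
        frags, bed, dropped = split_contigs([contig], bp, [])
        assert [len(f) for f in frags] == [5000, 3000]
        assert frags[0].id == "c:1-5000" and frags[1].id == "c:5001-8000"
        assert bed == [("c", 5000, 5001, "cut")]

    def test_short_fragment_dropped(self):
        contig = SequenceRecord("c", "A" * 4000)
        frags, _, dropped = split_contigs([contig], [Breakpoint("c", 300, 2.0, MODE_READ)], [])
        assert [len(f) for f in frags] == [3700]
        assert dropped == 1

    def test_union_of_read_and_insert_cuts(self):
        contig = SequenceRecord("c", "A" * 6000)
        r = [Breakpoint("c", 2000, 1.0, MODE_READ)]
        i = [Breakpoint("c", 4000, 1.0, MODE_INSERT), Breakpoint("c", 2000, 1.2, MODE_INSERT)]
        frags, bed, _ = split_contigs([contig], r, i)
        assert [len(f) for f in frags] == [2000, 2000, 2000]
        assert len(bed) == 2  # duplicate position collapses

    def test_unknown_contig_raises(self):
        with pytest.raises(MgsDataError):
            split_contigs([SequenceRecord("c", "A" * 1000)], [Breakpoint("x", 10, 1.0, MODE_READ)], [])

    def test_length_conservation(self):
        rng = np.random.default_rng(0)
        contig = SequenceRecord("c", "A" * 9000)
        cuts = [Breakpoint("c", int(p), 1.0, MODE_READ) for p in rng.choice(range(1, 9000), 5, replace=False)]
        frags, _, dropped = split_contigs([contig], cuts, [])
        emitted = sum(len(f) for f in frags)
        positions = sorted({b.position for b in cuts})
        bounds = [0] + positions + [9000]
        dropped_len = sum(
            e - s for s, e in zip(bounds[:-1], bounds[1:]) if e - s < 500
        )
        assert emitted + dropped_len == 9000


class TestChimeraRecovery:
    def test_planted_junctions_recovered_without_false_cuts(self, truth, sim):
        """Breakpoints land within one window of every planted junction
        (depth ratios >= 2, depths >= 10x) and uniform contigs are never cut."""
        profiles_r = covsplit.coverage_profiles(sim.alignments, truth.contigs, 1000, MODE_READ)
        profiles_i = covsplit.coverage_profiles(sim.alignments, truth.contigs, 1000, MODE_INSERT)
        found = {
            cid: [b.position for prof in (profiles_r[cid], profiles_i[cid])
                  for b in find_breakpoints(prof)]
            for cid in profiles_r
        }
        for cid, pos in truth.chimera_junctions:
            assert any(abs(p - pos) <= 1000 for p in found[cid]), cid
        for contig in truth.contigs:
            if contig.id.startswith("uniform"):
                assert found[contig.id] == []
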