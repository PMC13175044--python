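"""Record parsing, spacer lift-back, filtering, merging and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cobitools import svmerge
from cobitools.svmerge import (
    MergeParams,
    MergedEvent,
    SvRecord,
    concat_with_spacer,
    filter_min_length,
    generations_per_sv,
    liftback,
    merge_neighbours,
)


def _rec(rs, re_, qs, qe, t="TRANS", rc="chr1", qc="q1", id="-"):
    return SvRecord(rc, rs, re_, qc, qs, qe, t, id=id)


class TestReadWrite:
    def test_inverted_query_coordinates_normalised(self, tmp_path):
        p = tmp_path / "in.tsv"
        p.write_text("chr1\t100\t200\t-\t-\tchr1\t300\t200\tINV1\t-\tINV\t-\n")
        (rec,) = svmerge.read_syri_tsv(p)
        assert (rec.qry_start, rec.qry_end) == (200, 300)
        assert rec.orientation == "-"

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert svmerge.read_syri_tsv(p) == []

    def test_round_trip(self, tmp_path):
        recs = [
            _rec(100, 9_000, 200, 9_100, "TRANS", id="T1"),
            _rec(20_000, 30_000, 40_000, 50_000, "INV", id="I1"),
        ]
        p = tmp_path / "rt.tsv"
        svmerge.write_syri_tsv(recs, p)
        assert svmerge.read_syri_tsv(p) == recs

    def test_unknown_type_skipped_with_warning(self, tmp_path):
        p = tmp_path / "odd.tsv"
        p.write_text(
            "chr1\t1\t10\t-\t-\tq1\t1\t10\tX1\t-\tWEIRD\t-\n"
            "chr1\t1\t10\t-\t-\tq1\t1\t10\tX2\t-\tDUP\t-\n"
        )
        with pytest.warns(UserWarning, match="WEIRD"):
            recs = svmerge.read_syri_tsv(p)
        assert [r.id for r in recs] == ["X2"]

    def test_non_numeric_coordinate_names_line(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "chr1\t1\t10\t-\t-\tq1\t1\t10\tX1\t-\tDUP\t-\n"
            "chr1\tabc\t10\t-\t-\tq1\t1\t10\tX2\t-\tDUP\t-\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            svmerge.read_syri_tsv(p)

    def test_child_records_dropped_by_default(self, tmp_path):
        p = tmp_path / "kids.tsv"
        p.write_text(
            "chr1\t1\t9000\t-\t-\tq1\t1\t9000\tT1\t-\tTRANS\t-\n"
            "chr1\t1\t4000\t-\t-\tq1\t1\t4000\tT1.1\tT1\tTRANS\t-\n"
        )
        assert [r.id for r in svmerge.read_syri_tsv(p)] == ["T1"]
        assert len(svmerge.read_syri_tsv(p, keep_children=True)) == 2


class TestSpacerMap:
    def test_offsets_and_total(self):
        m = concat_with_spacer([("A", 100), ("B", 200)])
        assert [(n, off) for n, off, _ in m.components] == [("A", 0), ("B", 1_100)]
        assert m.total_length == 1_300

    def test_three_components_total(self):
        m = concat_with_spacer([("A", 10), ("B", 10), ("C", 10)])
        assert m.total_length == 2_030

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=2, max_size=8))
    def test_offsets_strictly_monotone(self, lengths):
        comps = [(f"c{i}", ln) for i, ln in enumerate(lengths)]
        m = concat_with_spacer(comps)
        offsets = [off for _, off, _ in m.components]
        assert offsets == sorted(offsets) and len(set(offsets)) == len(offsets)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError):
            concat_with_spacer([("A", 10), ("A", 10)])


class TestLiftback:
    MAP = concat_with_spacer([("A", 100), ("B", 200)], name="AB")

    def test_position_shifts_onto_second_component(self):
        rec = SvRecord("AB", 1_150, 1_160, "q1", 1, 11, "DUP")
        (out,) = liftback(rec, self.MAP)
        assert (out.ref_chrom, out.ref_start, out.ref_end) == ("B", 50, 60)

    def test_spacer_spanning_record_split(self):
        rec = SvRecord("AB", 50, 1_150, "q1", 1, 11, "DUP", id="D1")
        a, b = liftback(rec, self.MAP)
        assert (a.ref_chrom, a.ref_start, a.ref_end) == ("A", 50, 100)
        assert (b.ref_chrom, b.ref_start, b.ref_end) == ("B", 1, 50)

    def test_record_inside_spacer_dropped_with_warning(self):
        rec = SvRecord("AB", 500, 600, "q1", 1, 101, "DUP", id="S")
        with pytest.warns(UserWarning, match="spacer"):
            assert liftback(rec, self.MAP) == []

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            liftback(SvRecord("AB", 1, 5_000, "q1", 1, 5_000, "DUP"), self.MAP)

    def test_projection_round_trip(self):
        # records given in component coordinates, projected, lifted back
        rng = np.random.default_rng(7)
        for _ in range(20):
            comp = "A" if rng.random() < 0.5 else "B"
            length = 100 if comp == "A" else 200
            s = int(rng.integers(1, length))
            e = int(rng.integers(s, length + 1))
            offset = dict((n, o) for n, o, _ in self.MAP.components)[comp]
            proj = SvRecord("AB", s + offset, e + offset, "q1", 1, e - s + 1, "TRANS")
            (back,) = liftback(proj, self.MAP)
            assert (back.ref_chrom, back.ref_start, back.ref_end) == (comp, s, e)


class TestFilter:
    def test_strictly_greater_than_cutoff(self):
        recs = [
            _rec(1, 4_999, 1, 4_999),
            _rec(1, 5_000, 1, 5_000),
            _rec(1, 5_001, 1, 5_001),
        ]
        kept = filter_min_length(recs)
        assert [r.ref_span for r in kept] == [5_001]

    def test_zero_cutoff_keeps_all(self):
        recs = [_rec(1, 10, 1, 10), _rec(1, 2, 1, 2)]
        assert filter_min_length(recs, MergeParams(min_block_len=0)) == recs

    def test_count_matches_brute_force(self):
        rng = np.random.default_rng(11)
        recs = []
        for i in range(200):
            s = int(rng.integers(1, 100_000))
            e = s + int(rng.integers(0, 20_000))
            recs.append(_rec(s, e, s, e, id=str(i)))
        kept = filter_min_length(recs)
        assert len(kept) == sum(1 for r in recs if r.ref_end - r.ref_start + 1 > 5_000)


class TestMerge:
    def test_contiguous_inversion_blocks_merge(self):
        recs = [
            _rec(10_000, 20_000, 80_000, 90_000, "INV", id="a"),
            _rec(21_000, 30_000, 70_000, 79_000, "INV", id="b"),
            _rec(31_000, 45_000, 55_000, 69_000, "INV", id="c"),
        ]
        (ev,) = merge_neighbours(recs)
        assert (ev.ref_start, ev.ref_end, ev.n_members) == (10_000, 45_000, 3)
        assert ev.member_ids == ["a", "b", "c"]

    def test_intervening_different_type_blocks_merge(self):
        recs = [
            _rec(10_000, 20_000, 80_000, 90_000, "INV", id="a"),
            _rec(21_000, 30_000, 70_000, 79_000, "INV", id="b"),
            _rec(30_200, 30_900, 10_000, 10_700, "TRANS", id="t"),
            _rec(31_000, 45_000, 55_000, 69_000, "INV", id="c"),
        ]
        events = merge_neighbours(recs)
        inv_events = [e for e in events if e.sv_type == "INV"]
        assert len(inv_events) == 2
        assert sorted(len(e.member_ids) for e in inv_events) == [1, 2]

    def test_syn_records_do_not_block(self):
        recs = [
            _rec(10_000, 20_000, 10_000, 20_000, "DUP", id="a"),
            _rec(20_500, 20_900, 20_500, 20_900, "SYN", id="s"),
            _rec(21_000, 30_000, 21_000, 30_000, "DUP", id="b"),
        ]
        (ev,) = merge_neighbours(recs)
        assert ev.n_members == 2

    def test_nonmonotone_query_blocks_merge(self):
        recs = [
            _rec(10_000, 20_000, 50_000, 60_000, "TRANS", id="a"),
            _rec(21_000, 30_000, 10_000, 19_000, "TRANS", id="b"),
        ]
        assert len(merge_neighbours(recs)) == 2

    def test_single_block_identity(self):
        recs = [_rec(10_000, 20_000, 5_000, 15_000, "DUP", id="d")]
        (ev,) = merge_neighbours(recs)
        assert (ev.ref_start, ev.ref_end, ev.sv_type, ev.n_members) == (
            10_000, 20_000, "DUP", 1,
        )

    def test_max_gap_limits_merging(self):
        recs = [
            _rec(10_000, 20_000, 10_000, 20_000, "DUP", id="a"),
            _rec(40_000, 50_000, 40_000, 50_000, "DUP", id="b"),
        ]
        assert len(merge_neighbours(recs, MergeParams(max_gap=10_000))) == 2
        assert len(merge_neighbours(recs, MergeParams(max_gap=None))) == 1

    def test_merge_is_idempotent_and_partitions_members(self):
        rng = np.random.default_rng(13)
        recs = []
        pos = 1
        for i in range(60):
            span = int(rng.integers(5_100, 20_000))
            t = ("INV", "TRANS", "DUP")[int(rng.integers(0, 3))]
            q = int(rng.integers(1, 1_000_000))
            recs.append(_rec(pos, pos + span, q, q + span, t, id=f"r{i}"))
            pos += span + int(rng.integers(1, 5_000))
        merged = merge_neighbours(recs)
        all_members = [m for e in merged for m in e.member_ids]
        assert sorted(all_members) == sorted(r.id for r in recs)
        again = merge_neighbours([e.as_record() for e in merged])
        assert len(again) == len(merged)
        assert sorted((e.ref_start, e.ref_end) for e in again) == sorted(
            (e.ref_start, e.ref_end) for e in merged
        )


class TestSummaries:
    def test_large_event_counting(self):
        evs = [
            MergedEvent("INV", "-", "c", 1, 900_000, "q", 1, 900_000, ["a"]),
            MergedEvent("INV", "-", "c", 1, 1_100_000, "q", 1, 1_100_000, ["b"]),
        ]
        counts = svmerge.count_large_events(evs)
        assert counts["total"] == 1 and counts["INV"] == 1

    def test_zero_threshold_counts_everything(self):
        evs = [MergedEvent("DUP", "+", "c", 1, 10, "q", 1, 10, ["a"])]
        counts = svmerge.count_large_events(evs, MergeParams(large_event_threshold=0))
        assert counts["total"] == 1

    def test_type_length_table(self):
        recs = [_rec(1, 6_000, 1, 6_000, "INV")]
        tab = svmerge.summarize_by_type_length(recs, [5_000, 10_000, np.inf])
        assert tab.loc["INV"].tolist() == [1, 0]

    def test_empty_input_empty_table(self):
        assert svmerge.summarize_by_type_length([], [0, 10]).empty

    def test_marginals_equal_record_count(self):
        rng = np.random.default_rng(17)
        recs = [
            _rec(1, 1 + int(rng.integers(1, 50_000)), 1, 2, ("INV", "DUP")[i % 2], id=str(i))
            for i in range(100)
        ]
        tab = svmerge.summarize_by_type_length(recs, [0, 10_000, 25_000, np.inf])
        assert tab.to_numpy().sum() == 100


class TestAnnotationOverlap:
    GENES = pd.DataFrame(
        {
            "chrom": ["c1", "c1", "c1"],
            "start": [50, 200, 600],
            "end": [150, 300, 700],
            "attrs": ["g1", "g2", "g3"],
        }
    )

    def test_event_spans_two_genes(self):
        ev = MergedEvent("TRANS", "+", "c1", 100, 500, "q", 1, 400, ["a"])
        assert svmerge.genes_spanned(ev, self.GENES) == 2

    def test_no_genes_on_chromosome(self):
        ev = MergedEvent("TRANS", "+", "c9", 100, 500, "q", 1, 400, ["a"])
        assert svmerge.genes_spanned(ev, self.GENES) == 0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(19)
        genes = pd.DataFrame(
            {
                "chrom": "c1",
                "start": (s := rng.integers(1, 10_000, 100)),
                "end": s + rng.integers(1, 500, 100),
                "attrs": "g",
            }
        )
        for _ in range(20):
            a = int(rng.integers(1, 10_000))
            b = a + int(rng.integers(1, 2_000))
            ev = MergedEvent("INV", "-", "c1", a, b, "q", 1, 2, ["x"])
            oracle = sum(
                1 for g in genes.itertuples() if g.start <= b and g.end >= a
            )
            assert svmerge.genes_spanned(ev, genes) == oracle

    def test_indel_repeat_fraction_half(self):
        indels = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100]})
        repeats = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [50]})
        assert svmerge.indel_repeat_fraction(indels, repeats) == 0.5

    def test_disjoint_sets_zero(self):
        indels = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100]})
        repeats = pd.DataFrame({"chrom": ["c1"], "start": [500], "end": [600]})
        assert svmerge.indel_repeat_fraction(indels, repeats) == 0.0

    def test_zero_indel_bases_rejected(self):
        empty = pd.DataFrame({"chrom": [], "start": [], "end": []})
        with pytest.raises(ValueError):
            svmerge.indel_repeat_fraction(empty, empty)

    def test_matches_bitmap_oracle(self):
        rng = np.random.default_rng(23)
        L = 50_000
        indels = pd.DataFrame(
            {"chrom": "c1", "start": (s := np.sort(rng.integers(0, L - 500, 40))), "end": s + rng.integers(1, 500, 40)}
        )
        repeats = pd.DataFrame(
            {"chrom": "c1", "start": (t := rng.integers(0, L - 800, 60)), "end": t + rng.integers(1, 800, 60)}
        )
        ind_mask = np.zeros(L, dtype=bool)
        rep_mask = np.zeros(L, dtype=bool)
        # indel bases counted with multiplicity when intervals overlap
        total = 0
        covered = 0
        for a, b in zip(repeats["start"], repeats["end"]):
            rep_mask[a:b] = True
        for a, b in zip(indels["start"], indels["end"]):
            total += b - a
            covered += int(rep_mask[a:b].sum())
        assert svmerge.indel_repeat_fraction(indels, repeats) == pytest.approx(
            covered / total
        )


class TestSvRate:
    def test_recent_divergence_quotient(self):
        assert generations_per_sv(35_633, 1e6) == pytest.approx(28.064, abs=1e-3)

    def test_generation_time_scales_linearly(self):
        assert generations_per_sv(100, 1e6, generation_time_years=2.0) == pytest.approx(
            generations_per_sv(100, 1e6) / 2
        )

    def test_zero_svs_rejected(self):
        with pytest.raises(ValueError):
            generations_per_sv(0, 1e6)
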