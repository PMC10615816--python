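from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melonmeta.projection import (
    FlankPair,
    PafAlignment,
    ProjectionStatus,
    chrom_number,
    overlap_components,
    parse_paf,
    pair_flanks,
    project_all,
    project_interval,
    quarter_filter,
    rename_qtls,
    select_best_hit,
    status_counts,
)
from melonmeta.qtl_io import ChromTableError
from melonmeta.synthetic import SimConfig, emit_synthetic_paf, simulate_studies, simulate_truth

from conftest import make_proj, make_qtl


def aln(
    qname="q__L",
    tname="chrT",
    ts=1000,
    te=2000,
    strand="+",
    mapq=60,
    primary=True,
    alen=1000,
    nm=980,
    tlen=40_000_000,
):
    return PafAlignment(
        query_name=qname,
        query_len=1000,
        query_start=0,
        query_end=1000,
        strand=strand,
        target_name=tname,
        target_len=tlen,
        target_start=ts,
        target_end=te,
        n_matches=nm,
        aln_len=alen,
        mapq=mapq,
        is_primary=primary,
    )


class TestParsePaf:
    LINE = "q__L\t1000\t0\t1000\t+\tchrT\t40000000\t5000\t6000\t980\t1000\t60\ttp:A:P"

    def test_single_primary_line(self):
        result = parse_paf([self.LINE])
        assert len(result) == 1
        a = result.alignments[0]
        assert a.is_primary and a.mapq == 60
        assert (a.target_start, a.target_end) == (5000, 6000)

    def test_secondary_tag(self):
        result = parse_paf([self.LINE.replace("tp:A:P", "tp:A:S")])
        assert not result.alignments[0].is_primary

    def test_no_tag_defaults_primary(self):
        result = parse_paf(["\t".join(self.LINE.split("\t")[:12])])
        assert result.alignments[0].is_primary

    def test_short_line_rejected_with_line_number(self):
        result = parse_paf([self.LINE, "\t".join(["a"] * 10)])
        assert len(result.alignments) == 1
        assert result.errors == [(2, "expected >=12 columns, got 10")]

    def test_inverted_coordinates_rejected(self):
        bad = self.LINE.replace("5000\t6000", "6000\t5000")
        result = parse_paf([bad])
        assert result.alignments == []
        assert result.errors[0][0] == 1

    def test_synthetic_fixture_counts(self):
        # fixture built by the synthetic generator: 2 QTLs -> 4 lines, all
        # primary; downgrade two by tag editing to get 2 primaries
        config = SimConfig(n_studies=1, trait_specs=(SimConfig().trait_specs[0],))
        truth = simulate_truth(config, 11)
        records = simulate_studies(truth, 11)
        lines, _ = emit_synthetic_paf(truth, records)
        assert len(lines) == 4
        lines = [
            line.replace("tp:A:P", "tp:A:S") if i % 2 else line
            for i, line in enumerate(lines)
        ]
        result = parse_paf(lines)
        assert len(result) == 4
        assert sum(a.is_primary for a in result) == 2


class TestSelectBestHit:
    def test_empty_is_none(self):
        assert select_best_hit([]) is None

    def test_single_hit_identity(self):
        h = aln()
        assert select_best_hit([h]) is h

    def test_mapq_wins_among_primaries(self):
        lo, hi = aln(mapq=30), aln(mapq=60)
        assert select_best_hit([lo, hi]) is hi

    def test_primary_beats_secondary_mapq(self):
        sec = aln(mapq=60, primary=False)
        prim = aln(mapq=10, primary=True)
        assert select_best_hit([sec, prim]) is prim

    def test_tie_break_exhaustive_orderings(self):
        # two primaries tied on mapq and aln_len -> lowest target_start wins,
        # regardless of input order (checked over all permutations)
        a = aln(ts=100, te=1100)
        b = aln(ts=900, te=1900)
        c = aln(ts=500, te=1500, primary=False)
        for perm in itertools.permutations([a, b, c]):
            assert select_best_hit(list(perm)) is a

    def test_aln_len_breaks_mapq_tie(self):
        short = aln(alen=500, nm=400)
        long = aln(alen=1000)
        assert select_best_hit([short, long]) is long


class BruteForceToyGenome:
    """Oracle: place two flank strings on a coordinate line and read off the
    interval between them (end of left flank .. start of right flank)."""

    @staticmethod
    def project(left_span, right_span):
        (ls, le), (rs, re) = left_span, right_span
        spans = sorted([(ls, le), (rs, re)])
        inner_start = spans[0][1]
        inner_end = spans[1][0]
        if inner_start >= inner_end:
            return None
        return inner_start, inner_end


class TestProjectInterval:
    def test_plus_plus_projection_vs_oracle(self, chroms):
        pair = FlankPair(
            qtl_id="q",
            left_hits=[aln("q__L", ts=1000, te=2000)],
            right_hits=[aln("q__R", ts=501_000, te=502_000)],
        )
        rec = project_interval(pair, chroms)
        assert rec.status is ProjectionStatus.PROJECTED
        assert (rec.start_bp, rec.end_bp) == (2000, 501_000)
        assert (rec.start_bp, rec.end_bp) == BruteForceToyGenome.project(
            (1000, 2000), (501_000, 502_000)
        )

    def test_cross_chrom(self, chroms):
        pair = FlankPair(
            qtl_id="q",
            left_hits=[aln("q__L", tname="chrT")],
            right_hits=[aln("q__R", tname="chrU", tlen=30_000_000)],
        )
        assert project_interval(pair, chroms).status is ProjectionStatus.FAILED_CROSS_CHROM

    def test_missing_right_flank(self, chroms):
        pair = FlankPair(qtl_id="q", left_hits=[aln("q__L")])
        assert project_interval(pair, chroms).status is ProjectionStatus.FAILED_FLANK_MISSING

    def test_discordant_strands(self, chroms):
        pair = FlankPair(
            qtl_id="q",
            left_hits=[aln("q__L", strand="+")],
            right_hits=[aln("q__R", ts=501_000, te=502_000, strand="-")],
        )
        assert project_interval(pair, chroms).status is ProjectionStatus.FAILED_ORIENTATION

    def test_minus_minus_projection(self, chroms):
        # the locus aligned reverse-complemented: inner edges swap sides
        pair = FlankPair(
            qtl_id="q",
            left_hits=[aln("q__L", ts=501_000, te=502_000, strand="-")],
            right_hits=[aln("q__R", ts=1000, te=2000, strand="-")],
        )
        rec = project_interval(pair, chroms)
        assert rec.status is ProjectionStatus.PROJECTED
        assert (rec.start_bp, rec.end_bp) == (2000, 501_000)

    def test_empty_interval_fails_orientation(self, chroms):
        pair = FlankPair(
            qtl_id="q",
            left_hits=[aln("q__L", ts=1000, te=2000)],
            right_hits=[aln("q__R", ts=1000, te=2000)],
        )
        assert project_interval(pair, chroms).status is ProjectionStatus.FAILED_ORIENTATION

    def test_unknown_chromosome_raises(self, chroms):
        pair = FlankPair(
            qtl_id="q",
            left_hits=[aln("q__L", tname="chrX")],
            right_hits=[aln("q__R", tname="chrX", ts=5000, te=6000)],
        )
        with pytest.raises(ChromTableError):
            project_interval(pair, chroms)


class TestProjectAll:
    def test_projection_is_total(self, chroms):
        qtls = [make_qtl(f"q{i}") for i in range(4)]
        alns = [
            aln("q0__L", ts=1000, te=2000),
            aln("q0__R", ts=10_000, te=11_000),
            aln("q1__L"),  # right flank missing
            aln("q2__L", tname="chrT"),
            aln("q2__R", tname="chrU", ts=100, te=1100, tlen=30_000_000),
        ]  # q3 has no hits at all
        out = project_all(qtls, alns, chroms)
        assert len(out) == 4
        counts = status_counts(out)
        assert sum(counts.values()) == 4
        assert counts["projected"] == 1
        assert counts["failed_flank_missing"] == 2
        assert counts["failed_cross_chrom"] == 1

    def test_pair_flanks_partition(self):
        alns = [aln("a__L"), aln("a__R"), aln("b__L"), aln("ignored")]
        pairs = pair_flanks(alns)
        assert set(pairs) == {"a", "b"}
        assert len(pairs["a"].left_hits) == 1 and len(pairs["a"].right_hits) == 1
        assert pairs["b"].right_hits == []


class TestQuarterFilter:
    def test_strictly_larger_excluded(self, chroms):
        rec = make_proj("q1", "chrT", 0, 10_000_001)
        out = quarter_filter([rec], chroms)
        assert out[0].status is ProjectionStatus.EXCLUDED_QUARTER_FILTER

    def test_boundary_retained(self, chroms):
        rec = make_proj("q1", "chrT", 0, 10_000_000)
        out = quarter_filter([rec], chroms)
        assert out[0].status is ProjectionStatus.PROJECTED

    def test_coordinates_unchanged_and_idempotent(self, chroms):
        recs = [
            make_proj("q1", "chrT", 5, 10_000_006),
            make_proj("q2", "chrT", 0, 500),
        ]
        once = quarter_filter(recs, chroms)
        twice = quarter_filter(once, chroms)
        assert once == twice
        assert [(r.start_bp, r.end_bp) for r in once] == [(5, 10_000_006), (0, 500)]

    def test_failed_records_untouched(self, chroms):
        rec = make_proj("q1", status=ProjectionStatus.FAILED_FLANK_MISSING)
        rec.chrom = None
        rec.start_bp = rec.end_bp = None
        assert quarter_filter([rec], chroms)[0].status is ProjectionStatus.FAILED_FLANK_MISSING


class TestRename:
    def test_first_locus_name(self):
        recs = [make_proj("q1", "chr08", 100, 200, trait="FSI")]
        assert rename_qtls(recs)[0].renamed_id == "FSI8.1"

    def test_second_locus_rank(self):
        recs = [
            make_proj("q1", "chr08", 100, 200, trait="FSI"),
            make_proj("q2", "chr08", 5000, 6000, trait="FSI"),
        ]
        out = rename_qtls(recs)
        assert [r.renamed_id for r in out] == ["FSI8.1", "FSI8.2"]

    def test_overlap_group_shares_name(self):
        # seven mutually overlapping same-trait intervals -> one shared name
        recs = [
            make_proj(f"q{i}", "chr08", 1000 + i * 10, 9000 + i * 10, trait="FSI")
            for i in range(7)
        ]
        out = rename_qtls(recs)
        assert {r.renamed_id for r in out} == {"FSI8.1"}

    def test_traits_numbered_independently(self):
        recs = [
            make_proj("q1", "chr03", 100, 200, trait="FW"),
            make_proj("q2", "chr03", 100, 200, trait="FSI"),
        ]
        out = rename_qtls(recs)
        assert {r.renamed_id for r in out} == {"FW3.1", "FSI3.1"}

    @settings(max_examples=30, deadline=None)
    @given(perm=st.permutations(list(range(6))))
    def test_permutation_invariant(self, perm):
        recs = [
            make_proj("a", "chr02", 0, 100),
            make_proj("b", "chr02", 50, 150),
            make_proj("c", "chr02", 400, 500),
            make_proj("d", "chr02", 1000, 1100, trait="FW"),
            make_proj("e", "chr05", 0, 100),
            make_proj("f", "chr02", 90, 120),
        ]
        baseline = {r.qtl_id: r.renamed_id for r in rename_qtls(recs)}
        shuffled = [recs[i] for i in perm]
        assert {r.qtl_id: r.renamed_id for r in rename_qtls(shuffled)} == baseline

    def test_renamed_only_when_projected(self):
        rec = make_proj("q1", status=ProjectionStatus.EXCLUDED_QUARTER_FILTER)
        assert rename_qtls([rec])[0].renamed_id == ""


class TestHelpers:
    @pytest.mark.parametrize(
        "name,expected", [("chr08", "8"), ("chr12", "12"), ("chrT", "chrT"), ("LG3", "3")]
    )
    def test_chrom_number(self, name, expected):
        assert chrom_number(name) == expected

    def test_overlap_components_chain(self):
        # A-B and B-C intersect, A-C do not: single linkage joins all three
        comps = overlap_components([("A", 0, 10), ("B", 8, 20), ("C", 18, 30)])
        assert comps == [["A", "B", "C"]]

    def test_overlap_components_touching_split(self):
        comps = overlap_components([("A", 0, 10), ("B", 10, 20)])
        assert comps == [["A"], ["B"]]


class TestNoiseFreeOracleEquivalence:
    def test_exact_recovery_on_clean_synthetic(self):
        # flanks placed without noise: projected intervals == simulated truth
        config = SimConfig(n_studies=3)
        truth = simulate_truth(config, 23)
        records = simulate_studies(truth, 23)
        lines, skipped = emit_synthetic_paf(truth, records)
        assert skipped == []
        chroms = truth.chrom_table()
        out = project_all(records, parse_paf(lines).alignments, chroms)
        assert all(r.status is ProjectionStatus.PROJECTED for r in out)
        for rec, qtl in zip(out, records):
            start = round(qtl.ci_start_cM * config.bp_per_cm)
            end = round(qtl.ci_end_cM * config.bp_per_cm)
            assert (rec.start_bp, rec.end_bp) == (start, end)

    def test_corruption_counts(self):
        config = SimConfig(n_studies=2)
        truth = simulate_truth(config, 5)
        records = simulate_studies(truth, 5)
        ids = [r.qtl_id for r in records]
        drop = {ids[0]}
        cross = {ids[1], ids[2]}
        lines, _ = emit_synthetic_paf(truth, records, drop_right_flank=drop, cross_chrom=cross)
        out = project_all(records, parse_paf(lines).alignments, truth.chrom_table())
        counts = status_counts(out)
        assert counts["failed_flank_missing"] == 1
        assert counts["failed_cross_chrom"] == 2
        assert counts["projected"] == len(records) - 3
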