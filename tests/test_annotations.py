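"""Annotation parsing, intergenic filtering, and subfamily summaries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ervscan.annotations import (
    AnnotationParseError,
    ErvCopy,
    GeneFeature,
    filter_intergenic,
    merge_intervals,
    merged_length,
    parse_gtf_features,
    parse_repeatmasker_out,
    read_bed,
    select_erv_copies,
    summarize_subfamilies,
    write_bed,
)

RMSK_HEADER = (
    "   SW   perc perc perc  query      position in query           matching repeat\n"
    "score   div. del. ins.  sequence    begin     end    (left)    repeat  class/family begin end (left) ID\n"
    "\n"
)


def rmsk_line(chrom="chr1", qbegin=10001, qend=10468, strand="+", repeat="LTR7Y",
              family="LTR/ERV1", div=1.3):
    return (
        f" 1000 {div:5.1f}  0.0  0.0  {chrom}  {qbegin}  {qend}  (0)  {strand}  "
        f"{repeat}  {family}  1  468  (0)  1\n"
    )


def make_copy(chrom="chr1", start=0, end=100, strand="+", subfamily="LTR7Y",
              family="LTR/ERV1", div=1.0, copy_id="c1"):
    return ErvCopy(chrom, start, end, strand, subfamily, family, div, copy_id)


def make_gene(chrom="chr1", start=0, end=100, gene_id="G1", feature_type="gene"):
    return GeneFeature(chrom, start, end, "+", gene_id, feature_type)


class TestParseRepeatmasker:
    def test_coordinates_become_zero_based_half_open(self):
        (rec,) = parse_repeatmasker_out(RMSK_HEADER + rmsk_line())
        assert (rec.start, rec.end) == (10000, 10468)
        assert rec.strand == "+"
        assert rec.subfamily == "LTR7Y"
        assert rec.class_family == "LTR/ERV1"
        assert rec.divergence_pct == pytest.approx(1.3)

    def test_complement_strand_maps_to_minus(self):
        (rec,) = parse_repeatmasker_out(RMSK_HEADER + rmsk_line(strand="C"))
        assert rec.strand == "-"

    def test_header_only_file_yields_empty_list(self):
        assert parse_repeatmasker_out(RMSK_HEADER) == []

    @pytest.mark.parametrize(
        "bad_line",
        [
            " 1000 1.3 0.0 chr1 10001\n",  # wrong column count
            rmsk_line(qbegin="ten"),  # non-numeric coordinate
        ],
    )
    def test_malformed_line_names_line_number(self, bad_line):
        with pytest.raises(AnnotationParseError, match="line 4"):
            parse_repeatmasker_out(RMSK_HEADER + bad_line)

    def test_trailing_star_is_tolerated(self):
        line = rmsk_line().rstrip("\n") + " *\n"
        (rec,) = parse_repeatmasker_out(RMSK_HEADER + line)
        assert rec.subfamily == "LTR7Y"


class TestParseGtf:
    GTF = (
        'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "G1";\n'
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G1";\n'
        'chr1\tsrc\tCDS\t120\t180\t.\t+\t.\tgene_id "G1";\n'
        'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "G1";\n'
    )

    def test_one_based_to_zero_based(self):
        feats = parse_gtf_features(self.GTF)
        exon = [f for f in feats if f.feature_type == "exon"][0]
        assert (exon.start, exon.end) == (100, 200)

    def test_cds_rows_are_ignored(self):
        feats = parse_gtf_features(self.GTF)
        assert {f.feature_type for f in feats} == {"gene", "exon"}
        assert len(feats) == 3

    def test_shared_gene_id_kept_per_feature(self):
        exons = [f for f in parse_gtf_features(self.GTF) if f.feature_type == "exon"]
        assert len(exons) == 2 and all(f.gene_id == "G1" for f in exons)

    def test_missing_gene_id_is_error(self):
        bad = "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tfoo bar;\n"
        with pytest.raises(AnnotationParseError, match="gene_id"):
            parse_gtf_features(bad)


class TestSelectErv:
    @pytest.mark.parametrize(
        "family,kept",
        [
            ("LTR/ERV1", True),
            ("LTR/ERVK", True),
            ("LTR/ERVL-MaLR", True),
            ("SINE/Alu", False),
            ("LINE/L1", False),
            ("DNA/hAT", False),
        ],
    )
    def test_default_class_patterns(self, family, kept):
        rec = make_copy(family=family)
        assert (select_erv_copies([rec]) == [rec]) is kept

    def test_order_preserved(self):
        recs = [make_copy(copy_id=f"c{i}", start=i * 10, end=i * 10 + 5) for i in range(5)]
        assert select_erv_copies(recs) == recs


class TestFilterIntergenic:
    def test_one_bp_overlap_removes(self):
        copy = make_copy(start=100, end=200)
        gene = make_gene(start=150, end=300)
        assert filter_intergenic([copy], [gene]) == []

    def test_bookended_halfopen_intervals_do_not_overlap(self):
        copy = make_copy(start=100, end=200)
        gene = make_gene(start=200, end=300)
        assert filter_intergenic([copy], [gene]) == [copy]

    def test_chromosome_absent_from_genes_is_retained(self):
        copy = make_copy(chrom="chrX")
        gene = make_gene(chrom="chr1", start=0, end=10_000)
        assert filter_intergenic([copy], [gene]) == [copy]

    def test_exon_rows_do_not_mask(self):
        copy = make_copy(start=100, end=200)
        exon = make_gene(start=100, end=200, feature_type="exon")
        assert filter_intergenic([copy], [exon]) == [copy]

    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)), max_size=20),
           st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)), max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, copy_spec, gene_spec):
        copies = [make_copy(start=s, end=s + l, copy_id=f"c{i}")
                  for i, (s, l) in enumerate(copy_spec)]
        genes = [make_gene(start=s, end=s + l, gene_id=f"G{i}")
                 for i, (s, l) in enumerate(gene_spec)]
        once = filter_intergenic(copies, genes)
        assert filter_intergenic(once, genes) == once


class TestSummaries:
    def test_unweighted_mean_divergence(self):
        copies = [make_copy(div=2.0, copy_id="a"), make_copy(start=300, end=400, div=4.0, copy_id="b")]
        (s,) = summarize_subfamilies(copies, copies)
        assert s.mean_divergence_pct == pytest.approx(3.0)

    def test_weighted_mean_divergence(self):
        # 100 bp at 2% and 300 bp at 6% -> (200 + 1800) / 400 = 5.0
        copies = [
            make_copy(start=0, end=100, div=2.0, copy_id="a"),
            make_copy(start=200, end=500, div=6.0, copy_id="b"),
        ]
        (s,) = summarize_subfamilies(copies, copies, weighted_divergence=True)
        assert s.mean_divergence_pct == pytest.approx(5.0)

    def test_overlapping_copies_merge_before_length_sum(self):
        copies = [make_copy(start=0, end=100, copy_id="a"), make_copy(start=50, end=150, copy_id="b")]
        (s,) = summarize_subfamilies(copies, copies)
        assert s.merged_length_bp == 150

    def test_zero_intergenic_copies_flagged_unusable(self):
        copy = make_copy()
        (s,) = summarize_subfamilies([], [copy])
        assert not s.usable_for_expression
        assert math.isnan(s.mean_divergence_pct)
        assert s.n_copies_total == 1 and s.n_copies_intergenic == 0

    def test_intergenic_counts_sum_to_filtered_list(self, small_annotation):
        from ervscan.annotations import filter_intergenic as fi
        inter = fi(small_annotation.copies, small_annotation.genes)
        summaries = summarize_subfamilies(inter, small_annotation.copies)
        assert sum(s.n_copies_intergenic for s in summaries) == len(inter)

    @given(st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 200)),
                    min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_merged_length_matches_per_base_occupancy(self, spec):
        """Interval-merge length equals a brute-force base-by-base union count."""
        copies = [make_copy(start=s, end=s + l, copy_id=f"c{i}") for i, (s, l) in enumerate(spec)]
        occupied = np.zeros(2300, dtype=bool)
        for c in copies:
            occupied[c.start:c.end] = True
        assert merged_length(copies) == int(occupied.sum())

    def test_merge_intervals_handles_bookends(self):
        assert merge_intervals([(0, 10), (10, 20), (30, 40)]) == [(0, 20), (30, 40)]


class TestBedRoundTrip:
    def test_intervals_survive_round_trip(self, small_annotation):
        import io
        inter = filter_intergenic(small_annotation.copies, small_annotation.genes)
        buf = io.StringIO()
        write_bed(inter, buf)
        back = read_bed(buf.getvalue())
        assert [(c.chrom, c.start, c.end, c.strand, c.subfamily) for c in back] == [
            (c.chrom, c.start, c.end, c.strand, c.subfamily) for c in inter
        ]
        assert [c.divergence_pct for c in back] == pytest.approx(
            [c.divergence_pct for c in inter]
        )


class TestExonUnionFeatures:
    GTF = (
        'chr1\tsrc\tgene\t101\t1000\t.\t+\t.\tgene_id "IFI1";\n'
        'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "IFI1";\n'
        'chr1\tsrc\texon\t151\t300\t.\t+\t.\tgene_id "IFI1";\n'
        'chr1\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "IFI1";\n'
        'chr2\tsrc\tgene\t1\t500\t.\t-\t.\tgene_id "OAS9";\n'
    )

    def test_overlapping_exons_merge_into_parts(self):
        from ervscan.annotations import exon_union_features
        feats = exon_union_features(parse_gtf_features(self.GTF))
        parts = [(c.start, c.end) for c in feats["IFI1"]]
        assert parts == [(100, 300), (500, 600)]
        assert all(c.strand == "+" for c in feats["IFI1"])

    def test_gene_without_exons_falls_back_to_body(self):
        from ervscan.annotations import exon_union_features
        feats = exon_union_features(parse_gtf_features(self.GTF))
        assert [(c.start, c.end) for c in feats["OAS9"]] == [(0, 500)]

    def test_panel_restriction_and_missing_id_error(self):
        from ervscan.annotations import exon_union_features, read_gene_id_list
        panel = read_gene_id_list("# innate immune panel\nIFI1\nIFI1\n")
        assert panel == ["IFI1"]
        feats = exon_union_features(parse_gtf_features(self.GTF), panel)
        assert set(feats) == {"IFI1"}
        with pytest.raises(ValueError, match="absent"):
            exon_union_features(parse_gtf_features(self.GTF), ["NOPE"])

    def test_gene_features_countable_by_fragment_machinery(self):
        from ervscan.annotations import exon_union_features
        from ervscan.quantification import AlignedFragment, CountingParams, count_fragments
        feats = exon_union_features(parse_gtf_features(self.GTF))
        frag = AlignedFragment("q1", "chr1", 120, 250, "-", 60)
        res = count_fragments([frag], feats, CountingParams(strandedness="reverse"))
        assert res.counts["IFI1"] == 1


class TestInvariants:
    def test_end_must_exceed_start(self):
        with pytest.raises(ValueError):
            make_copy(start=100, end=100)

    def test_divergence_bounds(self):
        with pytest.raises(ValueError):
            make_copy(div=101.0)

    def test_strand_vocabulary(self):
        with pytest.raises(ValueError):
            make_copy(strand="*")
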