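"""Parsing, annotation loading, per-gene counting, and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from satay.insertion_io import (
    count_per_gene,
    load_annotation,
    parse_bed,
    parse_wig,
    read_count_matrix,
    write_count_matrix,
)
from satay.models import GeneModel, InsertionSite, LibraryMeta
from satay.reference import brute_force_counts

from conftest import make_sites


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

class TestParseBed:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrII\t1000\t1001\t.\t17\t+\n")
        (site,) = parse_bed(p, "L1")
        assert site == InsertionSite("chrII", 1000, "+", 17, "L1")

    def test_duplicates_merged_by_summing_reads(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrI\t10\t11\t.\t5\t+\nchrI\t10\t11\t.\t3\t+\n")
        (site,) = parse_bed(p, "L1")
        assert site.reads == 8

    def test_missing_score_defaults_to_one_read(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chrI\t10\t11\n")
        (site,) = parse_bed(p, "L1")
        assert site.reads == 1 and site.strand == "."

    def test_empty_file_returns_empty_list(self, tmp_path, caplog):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert parse_bed(p, "L1") == []
        assert "no insertion records" in caplog.text

    @pytest.mark.parametrize(
        "line, msg",
        [
            ("chrI\t10\n", "expected >=3"),
            ("chrI\tx\t11\n", "non-integer"),
            ("chrI\t10\t11\t.\t-5\t+\n", "negative score"),
        ],
    )
    def test_malformed_lines_name_line_number(self, tmp_path, line, msg):
        p = tmp_path / "bad.bed"
        p.write_text("chrI\t1\t2\n" + line)
        with pytest.raises(ValueError, match=f"2: .*{msg}|{msg}"):
            parse_bed(p, "L1")

    def test_merge_invariance_vs_prededuplicated_input(self, tmp_path):
        dup = tmp_path / "dup.bed"
        dup.write_text(
            "chrI\t5\t6\t.\t2\t+\nchrI\t5\t6\t.\t7\t+\nchrI\t9\t10\t.\t1\t-\n"
        )
        dedup = tmp_path / "dedup.bed"
        dedup.write_text("chrI\t5\t6\t.\t9\t+\nchrI\t9\t10\t.\t1\t-\n")
        assert parse_bed(dup, "L1") == parse_bed(dedup, "L1")


# ---------------------------------------------------------------------------
# WIG
# ---------------------------------------------------------------------------

class TestParseWig:
    def test_one_based_conversion_and_unknown_strand(self, tmp_path):
        p = tmp_path / "a.wig"
        p.write_text("variableStep chrom=chrI\n501 12\n")
        (site,) = parse_wig(p, "L1")
        assert (site.chrom, site.pos, site.strand, site.reads) == ("chrI", 500, ".", 12)

    def test_zero_value_positions_are_omitted(self, tmp_path):
        p = tmp_path / "a.wig"
        p.write_text("variableStep chrom=chrI\n5 0\n6 3\n")
        sites = parse_wig(p, "L1")
        assert [s.pos for s in sites] == [5]

    def test_duplicate_position_declaration_is_error(self, tmp_path):
        p = tmp_path / "a.wig"
        p.write_text("variableStep chrom=chrI\n5 1\n5 2\n")
        with pytest.raises(ValueError, match="declared twice"):
            parse_wig(p, "L1")

    def test_data_before_header_is_error(self, tmp_path):
        p = tmp_path / "a.wig"
        p.write_text("5 1\n")
        with pytest.raises(ValueError, match="header"):
            parse_wig(p, "L1")

    def test_fixed_step(self, tmp_path):
        p = tmp_path / "a.wig"
        p.write_text("fixedStep chrom=chrII start=10 step=5\n3\n0\n7\n")
        sites = parse_wig(p, "L1")
        assert [(s.pos, s.reads) for s in sites] == [(9, 3), (19, 7)]


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

GFF_HEADER = "##gff-version 3\n"


class TestLoadAnnotation:
    def test_coordinate_conversion_to_half_open(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            GFF_HEADER + "chrI\tsrc\tgene\t101\t200\t.\t+\t.\tID=YAL001C;Name=TFC3\n"
        )
        (g,) = load_annotation(p)
        assert (g.start, g.end, g.length) == (100, 200, 100)
        assert g.gene_id == "YAL001C" and g.common_name == "TFC3"

    def test_feature_type_filter(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            GFF_HEADER
            + "chrI\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            + "chrI\tsrc\tCDS\t10\t90\t.\t+\t.\tID=c1\n"
        )
        assert [g.gene_id for g in load_annotation(p, feature_type="CDS")] == ["c1"]

    def test_missing_id_names_line(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_HEADER + "chrI\tsrc\tgene\t1\t100\t.\t+\t.\tName=foo\n")
        with pytest.raises(ValueError, match="2"):
            load_annotation(p)

    def test_duplicate_id_is_error(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            GFF_HEADER
            + "chrI\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            + "chrI\tsrc\tgene\t200\t300\t.\t+\t.\tID=g1\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_annotation(p)

    def test_end_before_start_is_error(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_HEADER + "chrI\tsrc\tgene\t100\t50\t.\t+\t.\tID=g1\n")
        with pytest.raises(ValueError, match="end < start"):
            load_annotation(p)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

class TestCountPerGene:
    def test_half_open_boundary(self, toy_genes):
        sites = make_sites([("chrI", 199, "+", 1), ("chrI", 200, "+", 1)])
        m = count_per_gene(sites, toy_genes)
        assert m.tn.at["geneA", "L1"] == 1  # pos 199 inside [100, 200)
        assert m.tn.at["geneB", "L1"] == 2  # both inside [150, 400)

    def test_additivity_of_reads(self, toy_genes):
        sites = make_sites(
            [("chrI", 110, "+", 2), ("chrI", 120, "-", 5), ("chrI", 130, "+", 1)]
        )
        m = count_per_gene(sites, toy_genes)
        assert m.tn.at["geneA", "L1"] == 3
        assert m.reads.at["geneA", "L1"] == 8

    def test_totals_include_intergenic(self, toy_genes):
        genic = [("chrI", 100 + i, "+", 1) for i in range(10)]
        intergenic = [("chrI", 5000 + i, "+", 1) for i in range(4)]
        m = count_per_gene(make_sites(genic + intergenic), toy_genes)
        assert m.totals_tn["L1"] == 14

    def test_overlapping_genes_both_counted(self, toy_genes):
        m = count_per_gene(make_sites([("chrI", 160, "+", 3)]), toy_genes)
        assert m.tn.at["geneA", "L1"] == 1 and m.tn.at["geneB", "L1"] == 1

    def test_unannotated_chromosome_counts_toward_totals_only(self, toy_genes, caplog):
        m = count_per_gene(make_sites([("chrX", 5, "+", 2)]), toy_genes)
        assert m.totals_tn["L1"] == 1 and m.tn["L1"].sum() == 0
        assert "chrX" in caplog.text

    def test_terminus_truncation_excludes_gene_ends(self, toy_genes):
        # geneA [100, 200): at 10% truncation the counted window is [110, 190)
        sites = make_sites(
            [("chrI", 105, "+", 1), ("chrI", 150, "+", 1), ("chrI", 195, "+", 1)]
        )
        full = count_per_gene(sites, toy_genes)
        trunc = count_per_gene(sites, toy_genes, truncate_fraction=0.1)
        assert full.tn.at["geneA", "L1"] == 3
        assert trunc.tn.at["geneA", "L1"] == 1
        assert trunc.totals_tn["L1"] == full.totals_tn["L1"]

    def test_duplicate_records_merged(self, toy_genes):
        sites = make_sites([("chrI", 110, "+", 2), ("chrI", 110, "+", 5)])
        m = count_per_gene(sites, toy_genes)
        assert m.tn.at["geneA", "L1"] == 1
        assert m.reads.at["geneA", "L1"] == 7
        assert m.totals_tn["L1"] == 1


@st.composite
def counting_instance(draw):
    n_genes = draw(st.integers(1, 12))
    genes = []
    for i in range(n_genes):
        start = draw(st.integers(0, 300))
        genes.append(
            GeneModel(
                gene_id=f"g{i}",
                chrom=draw(st.sampled_from(["c1", "c2"])),
                start=start,
                end=start + draw(st.integers(1, 120)),
            )
        )
    sites = draw(
        st.lists(
            st.builds(
                InsertionSite,
                chrom=st.sampled_from(["c1", "c2", "c3"]),
                pos=st.integers(0, 450),
                strand=st.sampled_from(["+", "-"]),
                reads=st.integers(0, 30),
                library=st.just("L1"),
            ),
            max_size=60,
        )
    )
    return sites, genes


@given(counting_instance())
@settings(max_examples=40, deadline=None, derandomize=True)
def test_counting_matches_brute_force_scan(instance):
    """Vectorized interval counting agrees exactly with a per-site
    membership scan on random (possibly overlapping) gene sets."""
    sites, genes = instance
    merged: dict[tuple, int] = {}
    for s in sites:
        key = (s.chrom, s.pos, s.strand)
        merged[key] = merged.get(key, 0) + s.reads
    merged_sites = [
        InsertionSite(chrom=c, pos=p, strand=s, reads=r, library="L1")
        for (c, p, s), r in merged.items()
    ]
    m = count_per_gene(sites, genes, libraries=[LibraryMeta(library="L1")])
    expect = brute_force_counts(merged_sites, genes)
    for g in genes:
        assert m.tn.at[g.gene_id, "L1"] == expect[g.gene_id][0]
        assert m.reads.at[g.gene_id, "L1"] == expect[g.gene_id][1]
    assert m.totals_tn["L1"] == len(merged_sites)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

class TestCountMatrixRoundTrip:
    def test_round_trip_identity_and_gene_order(self, small_screen, tmp_path):
        path = tmp_path / "counts.tsv"
        write_count_matrix(small_screen.counts, path)
        back = read_count_matrix(path)
        assert back.genes == small_screen.counts.genes
        assert back.tn.equals(small_screen.counts.tn)
        assert back.reads.equals(small_screen.counts.reads)
        assert back.totals_tn.equals(small_screen.counts.totals_tn)
        assert [m.to_dict() for m in back.libraries] == [
            m.to_dict() for m in small_screen.counts.libraries
        ]

    def test_metadata_header_mismatch_is_error(self, small_screen, tmp_path):
        import yaml

        path = tmp_path / "counts.tsv"
        write_count_matrix(small_screen.counts, path)
        meta_path = tmp_path / "counts.tsv.meta.yaml"
        meta = yaml.safe_load(meta_path.read_text())
        meta["libraries"].append({"library": "ghost"})
        meta["totals_tn"]["ghost"] = 1
        meta["totals_reads"]["ghost"] = 1
        meta_path.write_text(yaml.safe_dump(meta))
        with pytest.raises(ValueError, match="mismatch"):
            read_count_matrix(path)
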