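import io

import pytest

from virin.annotation import (
    IntervalLookup,
    annotate_all,
    annotate_dnase,
    annotate_repeat,
    classify_region,
    summary_tables,
)
from virin.breakpoint_calling import Breakpoint, BreakpointCluster
from virin.config import AnnotationConfig
from virin.io_formats import GenomicInterval, read_gene_model

GTF = (
    'chr1\tx\tgene\t10001\t14000\t.\t+\t.\tgene_name "PC"; gene_type "protein_coding";\n'
    'chr1\tx\texon\t10001\t11000\t.\t+\t.\tgene_name "PC"; gene_type "protein_coding";\n'
    'chr1\tx\texon\t13001\t14000\t.\t+\t.\tgene_name "PC"; gene_type "protein_coding";\n'
    'chr1\tx\tCDS\t10501\t11000\t.\t+\t.\tgene_name "PC"; gene_type "protein_coding";\n'
    'chr1\tx\tCDS\t13001\t13500\t.\t+\t.\tgene_name "PC"; gene_type "protein_coding";\n'
    'chr1\tx\tgene\t30001\t32000\t.\t-\t.\tgene_name "LNC"; gene_type "lncRNA";\n'
    'chr1\tx\texon\t30001\t32000\t.\t-\t.\tgene_name "LNC"; gene_type "lncRNA";\n'
)


@pytest.fixture(scope="module")
def model():
    return read_gene_model(io.StringIO(GTF))


class TestRegionClassification:
    def test_cds_point_is_exon(self, model):
        region, gene, gtype = classify_region("chr1", 10700, model)
        assert (region, gene, gtype) == ("exon", "PC", "protein_coding")

    def test_utr_from_cds_geometry(self, model):
        assert classify_region("chr1", 10300, model)[0] == "five_prime_utr"
        assert classify_region("chr1", 13800, model)[0] == "three_prime_utr"

    def test_intron_between_exons(self, model):
        assert classify_region("chr1", 12000, model)[0] == "intron"

    def test_promoter_upstream_of_plus_strand_tss(self, model):
        # 1,500 bases upstream of the + strand TSS at 10001
        region, gene, _ = classify_region("chr1", 8501, model)
        assert (region, gene) == ("promoter", "PC")

    def test_promoter_is_orientation_aware(self, model):
        # LNC is - strand: TSS at 32000, promoter extends to higher coordinates
        assert classify_region("chr1", 33500, model)[0] == "promoter"
        assert classify_region("chr1", 29000, model)[0] == "intergenic"

    def test_intergenic_far_from_genes(self, model):
        region, gene, gtype = classify_region("chr1", 500000, model)
        assert (region, gene, gtype) == ("intergenic", None, "none")

    def test_promoter_window_configurable(self, model):
        narrow = AnnotationConfig(promoter_up=100, promoter_down=0)
        assert classify_region("chr1", 8501, model, narrow)[0] == "intergenic"


class TestDnase:
    LOOKUP = IntervalLookup([GenomicInterval("chr1", 100, 200)])

    @pytest.mark.parametrize(
        "pos,expected",
        [(150, True), (200, True), (201, False), (100, False), (101, True)],
    )
    def test_half_open_boundary_arithmetic(self, pos, expected):
        assert annotate_dnase("chr1", pos, self.LOOKUP) is expected

    def test_chrom_prefix_unified(self):
        assert annotate_dnase("1", 150, self.LOOKUP)


class TestRepeats:
    def test_single_overlap(self):
        lookup = IntervalLookup(
            [GenomicInterval("chr1", 100, 300, name="LTR", attrs={"repeat_class": "LTR"})]
        )
        assert annotate_repeat("chr1", 200, lookup) == "LTR"

    def test_equal_score_resolved_by_priority(self):
        lookup = IntervalLookup(
            [
                GenomicInterval("chr1", 100, 300, name="SINE", score=10,
                                attrs={"repeat_class": "SINE"}),
                GenomicInterval("chr1", 150, 350, name="LINE", score=10,
                                attrs={"repeat_class": "LINE"}),
            ]
        )
        assert annotate_repeat("chr1", 200, lookup) == "LINE"

    def test_higher_score_wins_over_priority(self):
        lookup = IntervalLookup(
            [
                GenomicInterval("chr1", 100, 300, score=10, attrs={"repeat_class": "LTR"}),
                GenomicInterval("chr1", 150, 350, score=99, attrs={"repeat_class": "Simple_repeat"}),
            ]
        )
        assert annotate_repeat("chr1", 200, lookup) == "Simple_repeat"

    def test_no_overlap_and_unknown_class(self):
        lookup = IntervalLookup(
            [GenomicInterval("chr1", 100, 300, attrs={"repeat_class": "weird"})]
        )
        assert annotate_repeat("chr1", 200, lookup) == "none"
        assert annotate_repeat("chr1", 5000, lookup) == "none"


def make_cluster(pos, sample="s1"):
    return BreakpointCluster(members=[Breakpoint(sample, "1", pos, "v", "softclip")])


class TestSummaries:
    def test_region_percentages_partition(self, model):
        clusters = [make_cluster(p) for p in (10700, 12000, 500000, 600000)]
        annotated = annotate_all(clusters, model, [], [])
        tables = summary_tables(annotated)
        region = tables["region_distribution"]
        assert region["n"].sum() == 4
        assert region["pct"].sum() == pytest.approx(100.0, abs=0.02)

    def test_gene_list_accounting(self, model):
        clusters = [make_cluster(p) for p in (10700, 10750, 12000, 500000)]
        annotated = annotate_all(clusters, model, [], [])
        genes = summary_tables(annotated)["gene_list"]
        assert genes["n_breakpoints"].sum() == 3  # the three in-gene points
        assert genes.iloc[0]["gene_name"] == "PC"

    def test_unknown_chromosome_is_intergenic_with_no_labels(self, model):
        clusters = [BreakpointCluster(members=[Breakpoint("s1", "99", 100, "v", "softclip")])]
        (ab,) = annotate_all(clusters, model, [], [])
        assert ab.region_class == "intergenic"
        assert ab.repeat_class == "none" and not ab.dnase

    def test_track_order_independence(self, model):
        ivs = [
            GenomicInterval("chr1", 10690, 10800, attrs={"repeat_class": "LTR"}),
            GenomicInterval("chr1", 100, 200, attrs={"repeat_class": "LINE"}),
        ]
        a = annotate_all([make_cluster(10700)], model, [], ivs)
        b = annotate_all([make_cluster(10700)], model, [], ivs[::-1])
        assert a[0].repeat_class == b[0].repeat_class == "LTR"
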