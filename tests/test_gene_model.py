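"""Gene model construction, flank extension and region classification."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from cvload.gene_model import (
    GeneRegion,
    GtfParseError,
    NoGenesError,
    classify_region,
    count_gene_overlaps,
    extend_regions,
    parse_gene_model,
    read_gene_list,
    regions_to_bed,
)


def make_gene(start=1000, end=5000, strand="+", cats=("common",), **kw):
    defaults = dict(
        gene_id="G1", symbol="GENEA", chrom="chr1", start=start, end=end,
        strand=strand, categories=frozenset(cats),
    )
    defaults.update(kw)
    return GeneRegion(**defaults)


class TestParseGeneModel:
    def test_single_gene_identity(self, toy_gtf):
        model = parse_gene_model(toy_gtf, {"common": {"GENEA"}})
        assert len(model.genes) == 1
        g = model.genes[0]
        assert (g.symbol, g.chrom, g.start, g.end, g.strand) == ("GENEA", "chr1", 1000, 5000, "+")
        assert g.categories == {"common"}
        # CDS intervals become the exonic set; UTRs oriented by strand
        assert g.exons == [(1200, 2000), (4000, 4500)]
        assert g.utr5 == [(1000, 1199)]
        assert g.utr3 == [(4501, 5000)]

    def test_multi_list_gene_counted_once_with_union(self, toy_gtf):
        model = parse_gene_model(
            toy_gtf, {"common": {"GENEA", "GENEB"}, "mendelian": {"GENEA"}}
        )
        by_symbol = {g.symbol: g for g in model.genes}
        assert len(model.genes) == 2
        assert by_symbol["GENEA"].categories == {"common", "mendelian"}

    def test_missing_symbols_reported_not_fabricated(self, toy_gtf):
        model = parse_gene_model(toy_gtf, {"common": {"GENEA", "NOSUCH"}})
        assert [g.symbol for g in model.genes] == ["GENEA"]
        assert model.missing["common"] == ["NOSUCH"]

    def test_no_genes_error(self, toy_gtf):
        with pytest.raises(NoGenesError):
            parse_gene_model(toy_gtf, {"common": {"NOSUCH"}})

    def test_malformed_line_names_line_number(self):
        bad = 'chr1\tX\tgene\t10\t20\t.\t+\t.\tgene_id "A";\nnot-a-gtf-line\n'
        with pytest.raises(GtfParseError, match="line 2"):
            parse_gene_model(bad, {"common": {"A"}})

    def test_alias_table(self, toy_gtf):
        model = parse_gene_model(toy_gtf, {"common": {"GENEA_NEW"}}, aliases={"GENEA": "GENEA_NEW"})
        assert model.genes[0].symbol == "GENEA_NEW"

    def test_venn_counts_match_brute_force(self, toy_gtf):
        # 5-gene toy model, lists sized 3/2/1 sharing one symbol
        lists = {
            "common": {"GENEA", "GENEB", "GENEC"},
            "mendelian": {"GENEC", "GENED"},
            "congenital": {"GENEE"},
        }
        model = parse_gene_model(toy_gtf, lists)
        venn = count_gene_overlaps(model.genes)
        # independent set-algebra enumeration
        key_of = {
            ("common",): "common_only",
            ("mendelian",): "mendelian_only",
            ("congenital",): "congenital_only",
            ("common", "mendelian"): "common_mendelian",
            ("common", "congenital"): "common_congenital",
            ("congenital", "mendelian"): "mendelian_congenital",
            ("common", "congenital", "mendelian"): "common_mendelian_congenital",
        }
        expected = dict.fromkeys(key_of.values(), 0)
        for sym in set().union(*lists.values()):
            member = tuple(sorted(c for c, s in lists.items() if sym in s))
            expected[key_of[member]] += 1
        assert venn == expected
        assert sum(venn.values()) == len(model.genes)


class TestCountGeneOverlaps:
    def test_single_category_genes_have_zero_overlap_regions(self):
        genes = [make_gene(cats=(c,), symbol=f"G{i}") for i, c in enumerate(["common", "mendelian"])]
        venn = count_gene_overlaps(genes)
        assert venn["common_only"] == 1 and venn["mendelian_only"] == 1
        assert sum(v for k, v in venn.items() if not k.endswith("_only")) == 0

    def test_triple_membership(self):
        venn = count_gene_overlaps([make_gene(cats=("common", "mendelian", "congenital"))])
        assert venn["common_mendelian_congenital"] == 1
        assert sum(venn.values()) == 1


class TestExtendRegions:
    def test_clipped_at_chromosome_start(self):
        (r,) = extend_regions([make_gene(start=1000, end=5000)], flank=2000)
        assert (r.start_ext, r.end_ext) == (1, 7000)

    def test_standard_flank_arithmetic(self):
        (r,) = extend_regions([make_gene(start=10000, end=20000, chrom="chr2")], flank=2000)
        assert (r.start_ext, r.end_ext) == (8000, 22000)

    def test_zero_flank_is_identity(self):
        (r,) = extend_regions([make_gene(start=1000, end=5000)], flank=0)
        assert (r.start_ext, r.end_ext) == (1000, 5000)

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            extend_regions([make_gene()], flank=-1)

    def test_overlapping_regions_not_merged(self):
        genes = [make_gene(symbol="A"), make_gene(symbol="B", start=4000, end=9000)]
        regions = extend_regions(genes, 2000)
        assert len(regions) == 2

    @given(flank_a=st.integers(0, 5000), flank_b=st.integers(0, 5000))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_flank(self, flank_a, flank_b):
        lo, hi = sorted((flank_a, flank_b))
        (ra,) = extend_regions([make_gene()], lo)
        (rb,) = extend_regions([make_gene()], hi)
        assert rb.start_ext <= ra.start_ext and rb.end_ext >= ra.end_ext


def brute_force_label(pos, gene, flank):
    """Independent oracle: plain interval-membership scan with the stated precedence."""
    if pos < max(1, gene.start - flank) or pos > gene.end + flank:
        return "intergenic"
    for label, ivs in (("exonic", gene.exons), ("UTR5", gene.utr5), ("UTR3", gene.utr3)):
        if any(lo <= pos <= hi for lo, hi in ivs):
            return label
    low = gene.start - flank <= pos < gene.start
    high = gene.end < pos <= gene.end + flank
    if low:
        return "upstream" if gene.strand == "+" else "downstream"
    if high:
        return "downstream" if gene.strand == "+" else "upstream"
    return "intronic"


class TestClassifyRegion:
    GENE = make_gene(
        start=1000, end=9000,
        exons=[(1200, 2000), (4000, 5000)],
        utr5=[(1000, 1199)], utr3=[(5001, 5400)],
    )

    def test_cds_position_is_exonic(self):
        assert classify_region(1500, self.GENE, 2000) == "exonic"

    def test_flank_before_plus_strand_gene_is_upstream(self):
        assert classify_region(999, self.GENE, 2000) == "upstream"
        assert classify_region(1000 - 2000, self.GENE, 2000) == "intergenic"

    def test_matches_brute_force_on_random_positions(self):
        import random

        rnd = random.Random(0)
        for _ in range(200):
            pos = rnd.randint(1, 12000)
            assert classify_region(pos, self.GENE, 2000) == brute_force_label(pos, self.GENE, 2000)

    def test_strand_symmetry(self):
        """Flipping strand in place swaps upstream/downstream; mirroring the
        coordinates together with the strand flip restores every label."""
        plus = make_gene(start=5000, end=6000, strand="+")
        minus_in_place = make_gene(start=5000, end=6000, strand="-")
        m = 20000  # mirror pivot: pos -> m - pos maps [5000,6000] to [14000,15000]
        mirrored = make_gene(start=m - 6000, end=m - 5000, strand="-")
        swap = {"upstream": "downstream", "downstream": "upstream"}
        for pos in range(2500, 8600, 37):
            a = classify_region(pos, plus, 2000)
            assert classify_region(pos, minus_in_place, 2000) == swap.get(a, a)
            assert classify_region(m - pos, mirrored, 2000) == a


class TestIO:
    def test_gene_list_header_and_symbols(self):
        cat, symbols = read_gene_list("# category: common\nGENEA\nGENEB\n")
        assert cat == "common" and symbols == {"GENEA", "GENEB"}

    def test_gene_list_requires_header(self):
        with pytest.raises(ValueError):
            read_gene_list("GENEA\n")

    def test_bed_export_is_zero_based_half_open(self, tmp_path):
        import io

        (r,) = extend_regions([make_gene(start=1000, end=5000)], 0)
        buf = io.StringIO()
        regions_to_bed([r], buf)
        assert buf.getvalue() == "chr1\t999\t5000\tGENEA\n"


def test_gene_region_rejects_interval_outside_body():
    with pytest.raises(ValueError):
        make_gene(start=1000, end=2000, exons=[(500, 900)])
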