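"""Gene-model parsing and the nine-category region index."""

import numpy as np
import pytest

from seqqc.annotation import (
    Gene,
    GeneModel,
    GtfParseError,
    RegionCategory,
    build_region_index,
    category_of,
    parse_gtf,
    tss_list,
)

GTF_PLUS = """chr1\tsrc\tgene\t101\t400\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";
chr1\tsrc\ttranscript\t101\t400\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t1";
"""


def brute_force_category(model, hw, dl, chrom, pos):
    """Independent oracle: explicit interval membership + the fixed priority."""
    def hit(cat_intervals):
        return any(s <= pos < e for s, e in cat_intervals)

    for cat in (
        RegionCategory.PROMOTER,
        RegionCategory.UTR5,
        RegionCategory.UTR3,
        RegionCategory.FIRST_EXON,
        RegionCategory.OTHER_EXON,
        RegionCategory.FIRST_INTRON,
        RegionCategory.OTHER_INTRON,
        RegionCategory.DOWNSTREAM,
    ):
        for g in model.genes:
            if g.chrom != chrom:
                continue
            if cat == RegionCategory.PROMOTER:
                ivs = [(max(g.tss - hw, 0), g.tss + hw + 1)]
            elif cat == RegionCategory.UTR5:
                ivs = g.utr5
            elif cat == RegionCategory.UTR3:
                ivs = g.utr3
            elif cat == RegionCategory.FIRST_EXON:
                ivs = g.exons[:1]
            elif cat == RegionCategory.OTHER_EXON:
                ivs = g.exons[1:]
            elif cat == RegionCategory.FIRST_INTRON:
                ivs = g.introns[:1]
            elif cat == RegionCategory.OTHER_INTRON:
                ivs = g.introns[1:]
            else:
                ivs = (
                    [(max(g.start - dl, 0), g.start)]
                    if g.strand == "-"
                    else [(g.end, g.end + dl)]
                )
            if hit(ivs):
                return cat
    return RegionCategory.DISTAL_INTERGENIC


class TestParseGtf:
    def test_plus_strand_structure(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_PLUS)
        model = parse_gtf(p)
        (g,) = model.genes
        assert g.tss == 100  # 0-based of GTF coordinate 101
        assert g.exons == ((100, 200), (300, 400))
        assert g.introns == ((200, 300),)

    def test_minus_strand_reverses_transcription_order(self, tmp_path):
        p = tmp_path / "b.gtf"
        p.write_text(GTF_PLUS.replace("\t+\t", "\t-\t"))
        (g,) = parse_gtf(p).genes
        assert g.tss == 399
        assert g.exons[0] == (300, 400)  # first exon in transcription order
        assert g.introns == ((200, 300),)

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "c.gtf"
        p.write_text('chr1\ts\texon\t400\t101\t.\t+\t.\tgene_id "g"; transcript_id "t";\n')
        with pytest.raises(GtfParseError, match="end"):
            parse_gtf(p)

    def test_exon_without_transcript_rejected(self, tmp_path):
        p = tmp_path / "d.gtf"
        p.write_text('chr1\ts\texon\t101\t200\t.\t+\t.\tgene_id "g";\n')
        with pytest.raises(GtfParseError, match="transcript_id"):
            parse_gtf(p)

    def test_longest_transcript_is_representative(self, tmp_path):
        extra = (
            'chr1\tsrc\texon\t101\t150\t.\t+\t.\tgene_id "g1"; transcript_id "g1.t2";\n'
        )
        p = tmp_path / "e.gtf"
        p.write_text(GTF_PLUS + extra)
        (g,) = parse_gtf(p).genes
        assert g.exons == ((100, 200), (300, 400))


def _two_gene_model():
    g1 = Gene("a", "chr1", "+", 10_000, 12_000, 10_000,
              exons=((10_000, 10_500), (11_500, 12_000)), introns=((10_500, 11_500),))
    # g2's promoter window overlaps g1's exons
    g2 = Gene("b", "chr1", "+", 13_000, 14_000, 13_000,
              exons=((13_000, 14_000),), introns=())
    return GeneModel((g1, g2))


class TestRegionIndex:
    def test_position_inside_promoter_window(self):
        idx = build_region_index(_two_gene_model())
        assert category_of(idx, "chr1", 10_000 - 1000) == RegionCategory.PROMOTER

    def test_promoter_outranks_exon(self):
        # 11_600 is inside g1's second exon and within g2's promoter window
        idx = build_region_index(_two_gene_model())
        assert category_of(idx, "chr1", 11_600) == RegionCategory.PROMOTER

    def test_far_position_is_distal_intergenic(self):
        idx = build_region_index(_two_gene_model())
        assert category_of(idx, "chr1", 100_000) == RegionCategory.DISTAL_INTERGENIC

    def test_unknown_chromosome_is_distal(self):
        idx = build_region_index(_two_gene_model())
        assert category_of(idx, "chrUn", 5) == RegionCategory.DISTAL_INTERGENIC

    def test_negative_position_rejected(self):
        idx = build_region_index(_two_gene_model())
        with pytest.raises(ValueError):
            category_of(idx, "chr1", -1)

    def test_empty_model_everything_distal(self):
        idx = build_region_index(GeneModel(()))
        assert category_of(idx, "chr1", 123) == RegionCategory.DISTAL_INTERGENIC

    def test_matches_bruteforce_scan(self, gene_model):
        """Interval-index lookup ≡ exhaustive per-gene interval scan."""
        idx = build_region_index(gene_model)
        rng = np.random.default_rng(42)
        positions = rng.integers(0, 200_000, size=1000)
        for pos in positions:
            assert category_of(idx, "chr1", int(pos)) == brute_force_category(
                gene_model, 3000, 3000, "chr1", int(pos)
            )

    def test_every_position_gets_exactly_one_category(self, gene_model):
        idx = build_region_index(gene_model)
        for pos in range(9_000, 12_000, 7):  # dense scan across a gene boundary
            cat = category_of(idx, "chr1", pos)
            assert isinstance(cat, RegionCategory)

    def test_strand_symmetry(self):
        """Mirroring the layout maps promoter↔promoter and downstream↔downstream."""
        L = 50_000
        g = Gene("a", "chr1", "+", 20_000, 24_000, 20_000,
                 exons=((20_000, 21_000), (23_000, 24_000)), introns=((21_000, 23_000),))
        mirrored = Gene("a", "chr1", "-", L - 24_000, L - 20_000, L - 20_000 - 1,
                        exons=((L - 24_000, L - 23_000), (L - 21_000, L - 20_000))[::-1],
                        introns=((L - 23_000, L - 21_000),))
        idx = build_region_index(GeneModel((g,)))
        idx_m = build_region_index(GeneModel((mirrored,)))
        for pos in range(15_000, 29_000, 97):
            cat = category_of(idx, "chr1", pos)
            cat_m = category_of(idx_m, "chr1", L - 1 - pos)
            assert cat == cat_m


class TestTssList:
    def test_one_entry_per_gene_sorted(self, gene_model):
        entries = tss_list(gene_model)
        assert len(entries) == len(gene_model)
        assert entries == sorted(entries, key=lambda t: (t[0], t[1]))

    def test_minus_strand_tss_at_three_prime_span_end(self):
        g = Gene("a", "chr2", "-", 100, 500, 499, exons=((100, 500),), introns=())
        assert tss_list(GeneModel((g,))) == [("chr2", 499, "-")]

    def test_empty_model(self):
        assert tss_list(GeneModel(())) == []
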