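"""Gene-part classification and its per-base oracle."""

import numpy as np
import pytest

from peakatlas.annotate import (
    CATEGORIES,
    AnnotationConfig,
    classify_peaks,
    compare_genes,
    expected_fractions,
    find_closest_genes,
    find_distal_peaks,
    geneparts_matrix,
    nongenic_annotate,
    promoter_region,
)
from peakatlas.formats import GeneModel
from peakatlas.intervals import GenomicInterval, PeakSet

from test_intervals import random_peakset

# one + strand gene on a toy chromosome: [10000, 20000), exons
# [10000,12000) and [18000,20000), so one intron [12000,18000)
GENE = GeneModel(
    name="tx1", symbol="GENE1", chrom="chr1", strand="+",
    tx_start=10_000, tx_end=20_000,
    exon_starts=[10_000, 18_000], exon_ends=[12_000, 20_000],
)
SIZES = {"chr1": 100_000}


def classify_one(peak, genes=(GENE,), cfg=None):
    res = classify_peaks(PeakSet([peak]), list(genes), cfg)
    return res.primary[0][1]


class TestClassification:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (9_000, 9_100, "promoter"),  # 1 kb upstream of TSS, in 4 kb window
            (11_000, 11_100, "promoter"),  # first exon, still inside TSS window
            (13_000, 13_100, "first_intron"),
            (30_000, 30_100, "distal"),  # 10 kb past TES
            (18_500, 18_600, "exon"),  # second exon, outside the TSS window
            (20_500, 20_600, "downstream"),  # within 2 kb after TES
            (21_500, 21_600, "downstream"),  # still inside the 2 kb window
            (17_900, 18_100, "exon"),  # exon beats intron on overlap
        ],
    )
    def test_primary_category(self, start, end, expected):
        assert classify_one(GenomicInterval("chr1", start, end)) == expected

    def test_other_category_between_parts_and_distal(self):
        """With a narrow downstream window, near-gene peaks in no part
        fall into the residual category rather than distal."""
        cfg = AnnotationConfig(downstream_window=1000)
        cat = classify_one(GenomicInterval("chr1", 21_500, 21_600), cfg=cfg)
        assert cat == "other"

    def test_promoter_clipped_at_downstream_extremity(self):
        short = GeneModel("t", "S", "chr1", "+", 10_000, 10_500,
                          [10_000], [10_500])
        ps, pe = promoter_region(short, 4000)
        assert pe == 10_500  # never past the transcript 3' end

    def test_chromosome_without_genes_is_distal(self):
        cat = classify_one(GenomicInterval("chr9", 0, 100))
        assert cat == "distal"

    def test_partition_and_fraction_normalization(self, fixture, genes):
        rng = np.random.default_rng(21)
        peaks = random_peakset(rng, 200, span=150_000)
        res = classify_peaks(peaks, genes)
        assert sum(len(ps) for ps in res.by_category.values()) == len(peaks)
        assert sum(res.observed_fractions.values()) == pytest.approx(1.0, abs=0)

    def test_strand_mirror_symmetry(self):
        """Mirroring gene and peaks to the minus strand mirrors the
        strand-dependent labels."""
        G = 100_000
        mirrored_gene = GeneModel(
            "tx1m", "GENE1", "chr1", "-",
            G - GENE.tx_end, G - GENE.tx_start,
            [G - e for e in reversed(GENE.exon_ends)],
            [G - s for s in reversed(GENE.exon_starts)],
        )
        rng = np.random.default_rng(33)
        for _ in range(100):
            s = int(rng.integers(0, G - 300))
            length = int(rng.integers(50, 300))
            fwd = classify_one(GenomicInterval("chr1", s, s + length))
            mir = classify_one(
                GenomicInterval("chr1", G - s - length, G - s),
                genes=(mirrored_gene,),
            )
            assert fwd == mir

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            classify_peaks(PeakSet([GenomicInterval("chr1", 0, 10)]), [])


class TestExpectedFractions:
    def test_no_genes_all_distal(self):
        fr = expected_fractions([], SIZES)
        assert fr["distal"] == 1.0

    def test_sums_to_one(self, genes, chrom_sizes):
        fr = expected_fractions(genes, chrom_sizes)
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_matches_per_peak_classification_oracle(self):
        """Per-base fractions agree with classifying every 1 bp window."""
        sizes = {"chr1": 40_000}
        fr = expected_fractions([GENE], sizes)
        counts = {c: 0 for c in CATEGORIES}
        step = 40  # every 40th base; fixture geometry is 40 bp-aligned
        for pos in range(0, 40_000, step):
            counts[classify_one(GenomicInterval("chr1", pos, pos + 1))] += 1
        n = sum(counts.values())
        for c in CATEGORIES:
            assert counts[c] / n == pytest.approx(fr[c], abs=0.01)


class TestGenePartsMatrix:
    def test_single_promoter_peak(self):
        res = classify_peaks(
            PeakSet([GenomicInterval("chr1", 9_000, 9_100)]), [GENE]
        )
        m = geneparts_matrix(res)
        assert m.loc["GENE1", "promoter"] == 1
        assert m.loc["GENE1"].sum() == 1

    def test_empty(self):
        res = classify_peaks(PeakSet(), [GENE])
        assert geneparts_matrix(res).empty

    def test_hand_counted_fixture(self):
        peaks = PeakSet([
            GenomicInterval("chr1", 9_000, 9_100),    # promoter
            GenomicInterval("chr1", 9_200, 9_300),    # promoter
            GenomicInterval("chr1", 13_000, 13_100),  # first_intron
        ])
        m = geneparts_matrix(classify_peaks(peaks, [GENE]))
        assert m.loc["GENE1", "promoter"] == 2
        assert m.loc["GENE1", "first_intron"] == 1


class TestClosestAndDistal:
    def test_overlapping_gene_distance_zero(self):
        out = find_closest_genes(
            PeakSet([GenomicInterval("chr1", 15_000, 15_100)]), [GENE]
        )
        (iv, hits), = out
        assert hits == [(GENE, 0)]

    def test_equidistant_tie_kept(self):
        g2 = GeneModel("tx2", "GENE2", "chr1", "+", 30_000, 40_000,
                       [30_000], [40_000])
        # peak midway: gap 500 to GENE1 end (20000) and to GENE2 start
        out = find_closest_genes(
            PeakSet([GenomicInterval("chr1", 20_500, 29_500)]), [GENE, g2]
        )
        (_, hits), = out
        assert {g.symbol for g, _ in hits} == {"GENE1", "GENE2"}

    def test_brute_force_agreement(self, genes):
        rng = np.random.default_rng(5)
        peaks = random_peakset(rng, 200, span=150_000, chroms=("chr1",))
        result = find_closest_genes(peaks, genes)
        chr1_genes = [g for g in genes if g.chrom == "chr1"]
        for iv, hits in result:
            dists = [
                iv.distance_to(GenomicInterval(g.chrom, g.tx_start, g.tx_end))
                for g in chr1_genes
            ]
            assert {g.name for g, _ in hits} == {
                g.name for g, d in zip(chr1_genes, dists) if d == min(dists)
            }

    def test_distal_zero_distance_keeps_nonoverlapping(self):
        peaks = PeakSet([
            GenomicInterval("chr1", 15_000, 15_100),  # inside gene
            GenomicInterval("chr1", 50_000, 50_100),
        ])
        out = find_distal_peaks(peaks, [GENE], 0)
        assert out.coords() == [("chr1", 50_000, 50_100)]

    def test_no_genes_keeps_all(self):
        rng = np.random.default_rng(6)
        peaks = random_peakset(rng, 20)
        assert find_distal_peaks(peaks, [], 2000) == peaks

    def test_classify_distal_equals_find_distal(self, genes):
        """classify's distal category coincides with find_distal_peaks at
        the same threshold."""
        rng = np.random.default_rng(77)
        peaks = random_peakset(rng, 300, span=150_000)
        res = classify_peaks(peaks, genes)
        via_classify = sorted(res.by_category["distal"].coords())
        via_distal = sorted(find_distal_peaks(peaks, genes, 2000).coords())
        assert via_classify == via_distal


class TestCompareGenes:
    def test_identical(self):
        common, oa, ob = compare_genes(["A", "B"], ["B", "A"])
        assert common == ["A", "B"] and oa == [] and ob == []

    def test_disjoint_and_random(self):
        rng = np.random.default_rng(8)
        pool = [f"G{i}" for i in range(50)]
        a = list(rng.choice(pool, 20, replace=False))
        b = list(rng.choice(pool, 20, replace=False))
        common, oa, ob = compare_genes(a, b)
        assert set(common) == set(a) & set(b)
        assert set(oa) == set(a) - set(b)
        assert set(ob) == set(b) - set(a)
        assert sorted(common + oa) == sorted(set(a))


class TestNongenicAnnotate:
    def test_self_track_full_overlap(self, fixture, genes, chrom_sizes):
        truth = fixture.truth_peaks
        out = nongenic_annotate(
            truth, {"self": truth}, genes, chrom_sizes, n_rand=19, seed=1
        )
        hit, stats = out["self"]
        assert len(hit) == len(truth)
        assert stats.p_value == pytest.approx(1 / 20)

    def test_disjoint_track(self, fixture, genes, chrom_sizes):
        far = PeakSet([GenomicInterval("chr2", 99_000, 99_050)])
        out = nongenic_annotate(
            fixture.truth_peaks, {"far": far}, genes, chrom_sizes,
            n_rand=19, seed=1,
        )
        hit, stats = out["far"]
        assert len(hit) == 0
        assert stats.p_value == 1.0

    def test_empty_track_skipped(self, fixture, genes, chrom_sizes):
        out = nongenic_annotate(
            fixture.truth_peaks, {"empty": PeakSet()}, genes, chrom_sizes
        )
        hit, stats = out["empty"]
        assert len(hit) == 0 and stats is None
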