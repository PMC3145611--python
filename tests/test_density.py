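"""Density matrices, read-count matrices, and clustering."""

import numpy as np
import pandas as pd
import pytest

from peakatlas.density import (
    density_matrix,
    hierarchical_cluster,
    kmeans_cluster,
    read_count_matrix,
    som_cluster,
    summarize_density_in_geneparts,
)
from peakatlas.formats import GeneModel, ReadSet
from peakatlas.intervals import GenomicInterval, PeakSet


def simple_gene(strand="+", chrom="chr1", start=10_000, end=14_000, name="g1"):
    return GeneModel(name, name.upper(), chrom, strand, start, end,
                     [start], [end])


class TestDensityMatrix:
    def test_default_400_columns(self, genes, chip_reads, chrom_sizes):
        dm = density_matrix("tss", genes, chip_reads, chrom_sizes)
        assert dm.values.shape[1] == 400

    def test_no_reads_all_zero(self, genes, chrom_sizes):
        dm = density_matrix("tss", genes, ReadSet(), chrom_sizes)
        assert (dm.values.values == 0).all()

    def test_single_read_covers_five_bins(self):
        g = simple_gene()
        rs = ReadSet(fragment_length=50)
        rs.add("chr1", 10_000, 10_036, "+")
        dm = density_matrix("tss", [g], rs, {"chr1": 30_000}, window=4000, bin=10)
        row = dm.values.iloc[0].values
        # TSS at 10_000 = window centre = bin 200; fragment [TSS, TSS+50)
        assert np.allclose(row[200:205], 1.0)
        assert row.sum() == pytest.approx(5.0)

    def test_strand_flip_is_involution(self, chrom_sizes):
        plus = simple_gene("+")
        minus = GeneModel("g1m", "G1M", "chr1", "-", 10_000, 14_000,
                          [10_000], [14_000])
        rs = ReadSet(fragment_length=50)
        rs.add("chr1", 10_050, 10_086, "+")
        dm_p = density_matrix("tss", [plus], rs, {"chr1": 30_000})
        dm_m = density_matrix("tes", [minus], rs, {"chr1": 30_000})
        # same anchor base (10_000 vs TES of minus = 10_000): minus row is
        # the mirror of the plus row
        assert np.allclose(dm_m.values.iloc[0].values,
                           dm_p.values.iloc[0].values[::-1])

    def test_coverage_conservation(self, chrom_sizes):
        """Sum over bins x bin_bp equals the extended-read overlap with
        the window."""
        rng = np.random.default_rng(8)
        g = simple_gene()
        rs = ReadSet(fragment_length=200)
        for s in rng.integers(7_000, 13_000, size=300):
            rs.add("chr1", int(s), int(s) + 36, "+")
        dm = density_matrix("tss", [g], rs, {"chr1": 30_000}, window=4000, bin=10)
        from peakatlas.detect import coverage

        cov = coverage(rs, {"chr1": 30_000})["chr1"]
        window_overlap = cov[8_000:12_000].sum()
        assert dm.values.iloc[0].sum() * 10 == pytest.approx(window_overlap)

    def test_rpkm_invariant_under_duplication(self, chrom_sizes):
        g = simple_gene()
        rs1 = ReadSet(fragment_length=200)
        rs2 = ReadSet(fragment_length=200)
        rng = np.random.default_rng(2)
        for s in rng.integers(8_000, 12_000, size=100):
            rs1.add("chr1", int(s), int(s) + 36, "+")
            rs2.add("chr1", int(s), int(s) + 36, "+")
            rs2.add("chr1", int(s), int(s) + 36, "+")
        kw = dict(window=4000, bin=10, normalize="rpkm")
        dm1 = density_matrix("tss", [g], rs1, {"chr1": 30_000}, **kw)
        dm2 = density_matrix("tss", [g], rs2, {"chr1": 30_000}, **kw)
        assert np.allclose(dm1.values.values, dm2.values.values)

    def test_linearity_under_concatenation(self):
        g = simple_gene()
        rs1 = ReadSet(fragment_length=200)
        rs1.add("chr1", 9_500, 9_536, "+")
        rs2 = ReadSet(fragment_length=200)
        rs2.add("chr1", 9_500, 9_536, "+")
        rs2.add("chr1", 9_500, 9_536, "+")
        dm1 = density_matrix("tss", [g], rs1, {"chr1": 30_000})
        dm2 = density_matrix("tss", [g], rs2, {"chr1": 30_000})
        assert np.allclose(dm2.values.values, 2 * dm1.values.values)

    def test_truncated_window_flagged(self):
        g = simple_gene(start=500, end=3_000)
        dm = density_matrix("tss", [g], ReadSet(), {"chr1": 30_000})
        assert dm.truncated == ["g1"]

    def test_indivisible_window_rejected(self, genes, chrom_sizes):
        with pytest.raises(ValueError):
            density_matrix("tss", genes, ReadSet(), chrom_sizes, window=4000, bin=3)


class TestReadCountMatrix:
    def test_zero_read_dataset_zero_column(self, fixture, chip_reads, chrom_sizes):
        with pytest.warns(UserWarning, match="no reads"):
            df = read_count_matrix(
                fixture.truth_peaks, {"a": chip_reads, "empty": ReadSet()},
                chrom_sizes,
            )
        assert (df["empty"] == 0).all()
        assert (df["a"] > 0).any()

    def test_max_dominates_avg(self, fixture, chip_reads, chrom_sizes):
        mx = read_count_matrix(fixture.truth_peaks, {"a": chip_reads},
                               chrom_sizes, stat="max")
        av = read_count_matrix(fixture.truth_peaks, {"a": chip_reads},
                               chrom_sizes, stat="avg")
        assert (mx.values >= av.values - 1e-12).all()

    def test_rpkm_duplication_invariance(self, fixture, chrom_sizes):
        rs1 = ReadSet()
        rs2 = ReadSet()
        rng = np.random.default_rng(4)
        for s in rng.integers(0, 150_000, size=500):
            rs1.add("chr1", int(s), int(s) + 36, "+")
            rs2.add("chr1", int(s), int(s) + 36, "+")
            rs2.add("chr1", int(s), int(s) + 36, "+")
        a = read_count_matrix(fixture.truth_peaks, {"x": rs1}, chrom_sizes,
                              stat="avg", normalize="rpkm")
        b = read_count_matrix(fixture.truth_peaks, {"x": rs2}, chrom_sizes,
                              stat="avg", normalize="rpkm")
        assert np.allclose(a.values, b.values)

    def test_cells_match_coverage_oracle(self, fixture, chip_reads, chrom_sizes):
        from peakatlas.detect import coverage

        df = read_count_matrix(fixture.truth_peaks, {"a": chip_reads},
                               chrom_sizes, stat="avg")
        cov = coverage(chip_reads, chrom_sizes)
        for iv in fixture.truth_peaks:
            rid = iv.id
            assert df.loc[rid, "a"] == pytest.approx(
                cov[iv.chrom][iv.start : iv.end].mean()
            )


class TestClustering:
    @staticmethod
    def planted_matrix(k=3, per=20, dim=40, sep=10.0, seed=0):
        rng = np.random.default_rng(seed)
        rows, labels = [], []
        for c in range(k):
            center = np.zeros(dim)
            center[c * (dim // k)] = sep
            for _ in range(per):
                rows.append(center + rng.normal(0, 0.3, dim))
                labels.append(c)
        idx = [f"r{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=idx), np.array(labels)

    def test_som_identical_groups_map_to_single_nodes(self):
        X = pd.DataFrame(
            [[1.0, 0.0]] * 10 + [[0.0, 1.0]] * 10,
            index=[f"r{i}" for i in range(20)],
        )
        ca = som_cluster(X, grid=(2, 2), epochs=30, seed=1)
        first = set(ca.labels[:10])
        second = set(ca.labels[10:])
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_som_1x1_single_cluster(self):
        X, _ = self.planted_matrix()
        ca = som_cluster(X, grid=(1, 1), epochs=5, seed=0)
        assert set(ca.labels.tolist()) == {0}

    def test_som_seed_determinism(self):
        X, _ = self.planted_matrix(seed=5)
        a = som_cluster(X, grid=(3, 3), epochs=20, seed=9)
        b = som_cluster(X, grid=(3, 3), epochs=20, seed=9)
        assert (a.labels == b.labels).all()

    def test_kmeans_recovers_planted_partition(self):
        """Two well-separated planted clusters recovered >= 95% of rows
        (up to relabeling) across seeds."""
        for seed in range(10):
            X, truth = self.planted_matrix(k=2, seed=seed)
            ca = kmeans_cluster(X, 2, seed=seed)
            agree = max(
                (ca.labels == truth).mean(), (ca.labels != truth).mean()
            )
            assert agree >= 0.95

    def test_kmeans_k_equals_rows_singletons(self):
        X, _ = self.planted_matrix(k=2, per=3)
        ca = kmeans_cluster(X, len(X), seed=0)
        assert len(set(ca.labels.tolist())) == len(X)

    def test_duplicated_rows_same_cluster(self):
        X, _ = self.planted_matrix(k=2)
        X2 = pd.concat([X, X.iloc[[0]].rename(index={"r0": "dup"})])
        for ca in (kmeans_cluster(X2, 2, seed=1), hierarchical_cluster(X2, 2)):
            assert ca.labels[ca.row_ids.index("dup")] == ca.labels[0]

    def test_invalid_k_rejected(self):
        X, _ = self.planted_matrix()
        with pytest.raises(ValueError):
            kmeans_cluster(X, 0)
        with pytest.raises(ValueError):
            kmeans_cluster(X, len(X) + 1)


class TestGenepartsSummary:
    def test_promoter_spiked_fixture_greatest(self, fixture, genes, chip_reads,
                                              chrom_sizes):
        """Truth peaks sit at promoters and distal territory, so those
        categories out-cover exon/intron."""
        df = summarize_density_in_geneparts(chip_reads, genes, chrom_sizes)
        by_cat = dict(zip(df["category"], df["mean_coverage"]))
        assert by_cat["promoter"] > by_cat["intron"]

    def test_no_reads_zeros(self, genes, chrom_sizes):
        df = summarize_density_in_geneparts(ReadSet(), genes, chrom_sizes)
        assert (df["mean_coverage"].fillna(0) == 0).all()
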