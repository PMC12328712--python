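import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from cellmkl import (
    CellByFeatureMatrix,
    FeatureGrouping,
    GenomicInterval,
    gene_activity_score,
    gene_sets_to_peak_groups,
    map_peaks_to_genes,
    normalize_chrom_names,
    tf_peak_groups,
)
from oracles import brute_force_peak_gene_overlap


def genes_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


class TestMapPeaksToGenes:
    def test_peak_within_window_assigned(self):
        peaks = [GenomicInterval("chr1", 1000, 1500, name="p1")]
        genes = genes_df([("gA", "chr1", 2000, 5000, "+")])
        assert map_peaks_to_genes(peaks, genes, 5000) == {"gA": {"p1"}}

    def test_peak_beyond_window_not_assigned(self):
        peaks = [GenomicInterval("chr1", 0, 100, name="p1")]
        genes = genes_df([("gA", "chr1", 10000, 12000, "+")])
        assert map_peaks_to_genes(peaks, genes, 5000) == {"gA": set()}

    def test_halfopen_boundary_peak_abutting_window_end_excluded(self):
        # peak starts exactly at gene_end + window -> zero-length intersection
        genes = genes_df([("gA", "chr1", 2000, 5000, "+")])
        at_boundary = [GenomicInterval("chr1", 10000, 10100, name="p")]
        just_inside = [GenomicInterval("chr1", 9999, 10100, name="p")]
        assert map_peaks_to_genes(at_boundary, genes, 5000)["gA"] == set()
        assert map_peaks_to_genes(just_inside, genes, 5000)["gA"] == {"p"}

    def test_matches_brute_force_on_random_layout(self, rng):
        peaks = []
        for i in range(150):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 200_000))
            peaks.append(GenomicInterval(chrom, start, start + int(rng.integers(100, 800)),
                                         name=f"p{i}"))
        rows = []
        for j in range(30):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 200_000))
            rows.append((f"g{j}", chrom, start, start + int(rng.integers(1000, 9000)), "+"))
        genes = genes_df(rows)
        for window in (0, 2000, 5000):
            assert map_peaks_to_genes(peaks, genes, window) == \
                brute_force_peak_gene_overlap(peaks, genes, window)

    def test_peak_may_map_to_multiple_genes(self):
        peaks = [GenomicInterval("chr1", 4900, 5200, name="p")]
        genes = genes_df([("gA", "chr1", 1000, 5000, "+"), ("gB", "chr1", 5100, 9000, "+")])
        out = map_peaks_to_genes(peaks, genes, 0)
        assert out == {"gA": {"p"}, "gB": {"p"}}

    def test_invalid_inputs(self):
        genes = genes_df([("gA", "chr1", 0, 10, "+")])
        with pytest.raises(ValueError, match="window_bp"):
            map_peaks_to_genes([], genes, -1)
        with pytest.raises(ValueError, match="empty gene"):
            map_peaks_to_genes([], genes_df([]), 5000)


class TestGeneSetsToPeakGroups:
    def test_union_without_multiplicity(self):
        rna = FeatureGrouping("RNA", {"S": {"A", "B"}})
        g2p = {"A": {"p1", "p2"}, "B": {"p2", "p3"}}
        out = gene_sets_to_peak_groups(rna, g2p)
        assert out.modality == "ATAC"
        assert out.groups == {"S": {"p1", "p2", "p3"}}

    def test_gene_without_peaks_contributes_nothing(self):
        rna = FeatureGrouping("RNA", {"S": {"A", "B"}})
        out = gene_sets_to_peak_groups(rna, {"A": {"p1"}, "B": set()})
        assert out.groups == {"S": {"p1"}}

    def test_monotone_adding_gene_never_shrinks_group(self, rng):
        g2p = {f"g{i}": {f"p{rng.integers(0, 40)}" for _ in range(rng.integers(0, 5))}
               for i in range(20)}
        base = {"S": {f"g{i}" for i in range(5)}}
        bigger = {"S": base["S"] | {"g7"}}
        small = gene_sets_to_peak_groups(FeatureGrouping("RNA", base), g2p).groups.get("S", set())
        large = gene_sets_to_peak_groups(FeatureGrouping("RNA", bigger), g2p).groups.get("S", set())
        assert small <= large

    def test_all_empty_is_error(self):
        rna = FeatureGrouping("RNA", {"S": {"A"}})
        with pytest.raises(ValueError, match="zero peaks"):
            gene_sets_to_peak_groups(rna, {"A": set()})

    def test_group_sizes_reproducible_by_rescan(self, rng):
        # many sets over a toy annotation; sizes re-derived by brute force
        from cellmkl import make_toy_genome

        genome = make_toy_genome(n_chroms=2, n_genes=40, seed=5, peaks_per_gene=2,
                                 n_intergenic_peaks=10)
        mapping = map_peaks_to_genes(genome.peaks, genome.genes, 5000)
        gene_ids = list(genome.genes["gene_id"])
        sets = {f"SET{k}": set(rng.choice(gene_ids, size=6, replace=False))
                for k in range(15)}
        out = gene_sets_to_peak_groups(FeatureGrouping("RNA", sets), mapping)
        brute = brute_force_peak_gene_overlap(genome.peaks, genome.genes, 5000)
        for name, members in sets.items():
            expect = set().union(*(brute[g] for g in members))
            assert out.groups.get(name, set()) == expect


class TestTFPeakGroups:
    def _dataset_peaks(self):
        return [
            GenomicInterval("chr1", 100, 300, name="pk1"),
            GenomicInterval("chr1", 1000, 1200, name="pk2"),
            GenomicInterval("chr2", 50, 250, name="pk3"),
        ]

    def test_largest_study_retained(self):
        small = [GenomicInterval("chr1", i * 10, i * 10 + 5) for i in range(4)]
        big = [GenomicInterval("chr1", 150, 260)] + \
              [GenomicInterval("chr2", 10_000 + i * 10, 10_000 + i * 10 + 5) for i in range(5)]
        out = tf_peak_groups(self._dataset_peaks(), {"TF1": {"studyA": small, "studyB": big}},
                             min_peaks=0)
        # studyB (6 regions) wins over studyA (4); only its overlaps count
        assert out.groups["TF1"] == {"pk1"}

    def test_min_peaks_filter_applied_before_overlap(self):
        regions = [GenomicInterval("chr1", 100, 2000)]  # overlaps everything on chr1
        with pytest.raises(ValueError, match="no TF group"):
            tf_peak_groups(self._dataset_peaks(), {"TF1": regions}, min_peaks=500)

    def test_peak_shared_across_tf_groups(self):
        tfs = {
            "TF1": [GenomicInterval("chr1", 200, 1100)],
            "TF2": [GenomicInterval("chr1", 250, 280)],
        }
        out = tf_peak_groups(self._dataset_peaks(), tfs, min_peaks=0)
        assert "pk1" in out.groups["TF1"] and "pk1" in out.groups["TF2"]

    def test_min_peaks_zero_single_study_equals_plain_overlap(self, rng):
        peaks = [GenomicInterval("chr1", int(s), int(s) + 200, name=f"p{i}")
                 for i, s in enumerate(rng.integers(0, 50_000, size=60))]
        regions = [GenomicInterval("chr1", int(s), int(s) + 300)
                   for s in rng.integers(0, 50_000, size=20)]
        out = tf_peak_groups(peaks, {"TF": regions}, min_peaks=0)
        expect = {p.label for p in peaks if any(p.overlaps(r) for r in regions)}
        assert out.groups["TF"] == expect

    def test_empty_tf_sets_rejected(self):
        with pytest.raises(ValueError, match="empty TF"):
            tf_peak_groups(self._dataset_peaks(), {})


class TestGeneActivityScore:
    def _atac(self, values, peak_ids):
        n = values.shape[0] if hasattr(values, "shape") else len(values)
        return CellByFeatureMatrix(values, [f"c{i}" for i in range(n)],
                                   peak_ids, "ATAC")

    def test_counts_summed_over_body_and_promoter(self):
        atac = self._atac([[3.0, 4.0, 7.0]], ["chr1:1000-1500", "chr1:2000-2500", "chr1:9000-9100"])
        genes = genes_df([("gA", "chr1", 1200, 2200, "+")])
        gas = gene_activity_score(atac, genes, promoter_bp=2000)
        assert gas.modality == "GAS"
        assert gas.feature_ids == ["gA"]
        assert gas.dense()[0, 0] == 7.0  # 3 + 4; far peak excluded

    def test_promoter_is_strand_aware(self):
        # peak upstream of a - strand gene (past its end)
        atac = self._atac([[5.0]], ["chr1:10500-10600"])
        plus = genes_df([("gA", "chr1", 9000, 10000, "+")])
        minus = genes_df([("gA", "chr1", 9000, 10000, "-")])
        assert gene_activity_score(atac, plus, 2000).dense()[0, 0] == 0.0
        assert gene_activity_score(atac, minus, 2000).dense()[0, 0] == 5.0

    def test_gene_with_no_peaks_scores_zero(self):
        atac = self._atac([[1.0], [2.0]], ["chr1:0-100"])
        genes = genes_df([("gB", "chr2", 0, 1000, "+")])
        np.testing.assert_array_equal(gene_activity_score(atac, genes).dense(), [[0.0], [0.0]])

    def test_missing_strand_rejected_when_promoter_requested(self):
        atac = self._atac([[1.0]], ["chr1:0-100"])
        genes = genes_df([("gA", "chr1", 0, 1000, ".")])
        with pytest.raises(ValueError, match="strand"):
            gene_activity_score(atac, genes, promoter_bp=2000)
        gene_activity_score(atac, genes, promoter_bp=0)  # fine without promoter

    def test_matches_brute_force_recount(self, rng):
        from cellmkl import make_toy_genome

        genome = make_toy_genome(n_chroms=1, n_genes=5, seed=8, peaks_per_gene=3,
                                 n_intergenic_peaks=4)
        n_cells, peak_ids = 7, genome.peak_ids
        counts = rng.integers(0, 5, size=(n_cells, len(peak_ids))).astype(float)
        atac = self._atac(sp.csr_matrix(counts), peak_ids)
        promoter_bp = 1500
        gas = gene_activity_score(atac, genome.genes, promoter_bp).dense()
        from cellmkl.grouping import _parse_peak_id

        for j, row in enumerate(genome.genes.itertuples(index=False)):
            lo = row.start - (promoter_bp if row.strand == "+" else 0)
            hi = row.end + (promoter_bp if row.strand == "-" else 0)
            for c in range(n_cells):
                expect = sum(
                    counts[c, i]
                    for i, pid in enumerate(peak_ids)
                    if (iv := _parse_peak_id(pid)).chrom == row.chrom
                    and iv.start < hi and iv.end > lo
                )
                assert gas[c, j] == pytest.approx(expect)


class TestChromNameNormalization:
    def test_explicit_styles(self):
        ivs = [GenomicInterval("1", 0, 10), GenomicInterval("chr2", 0, 10)]
        chr_style = normalize_chrom_names(ivs, "chr")
        assert [iv.chrom for iv in chr_style] == ["chr1", "chr2"]
        plain = normalize_chrom_names(ivs, "plain")
        assert [iv.chrom for iv in plain] == ["1", "2"]
        with pytest.raises(ValueError):
            normalize_chrom_names(ivs, "ucsc")
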