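import itertools

import numpy as np
import pandas as pd
import pytest

from chipnorm.diff_norm import CHE, DHE_LIB1, DHE_LIB2, NONE, BinLabels
from chipnorm.evaluation import (
    bivalent_classes,
    classify_gene_types,
    gene_density_profile,
    labels_from_regions,
    promoter_sensitivity,
    replicate_fpr,
    roc_points,
    select_differential_genes,
)
from chipnorm.io_binning import GeneSet, GenomeLayout, RegionSet


def layout_of(n_bins: int, bin_size: int = 1000) -> GenomeLayout:
    return GenomeLayout((("chr1", n_bins * bin_size),), bin_size)


def labels_of(codes) -> BinLabels:
    codes = np.asarray(codes, dtype=np.int8)
    return BinLabels(
        labels=codes,
        norm1=np.zeros(len(codes)),
        norm2=np.zeros(len(codes)),
        stage2=codes != NONE,
    )


def genes_at(tss_list, chrom="chr1") -> GeneSet:
    rows = [(f"g{i}", chrom, t, "+") for i, t in enumerate(tss_list)]
    return GeneSet(pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"]))


def expr_table(rows) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=["gene_id", "expr_cond1", "expr_cond2"])
    return df.set_index("gene_id")


class TestGeneDensityProfile:
    def test_uniform_everything_is_flat(self):
        layout = layout_of(1000)  # 1 Mbp windows of 100 bins each
        values = np.ones(1000)
        genes = genes_at(list(range(50_000, 1_000_000 * 10, 100_000)))
        prof = gene_density_profile(values, genes, layout, window=100_000, classes=5)
        assert np.allclose(prof, prof[0])

    def test_gene_dense_half_gives_monotone_profile(self):
        from scipy.stats import spearmanr

        layout = layout_of(1000)
        # enriched bins and genes both concentrated toward the end
        values = np.zeros(1000)
        tss = []
        for w in range(10):  # 10 windows of 100 bins
            density = w  # 0..9 genes per window, matching labels
            values[w * 100 : w * 100 + density * 5] = 1
            tss.extend(w * 100_000 + 1000 * g for g in range(density))
        prof = gene_density_profile(values, genes_at(tss), layout, window=100_000, classes=5)
        rho = spearmanr(np.arange(5), prof).statistic
        assert rho == pytest.approx(1.0)
        assert (np.diff(prof) > 0).all()

    def test_empty_labels_give_zero_profile(self):
        layout = layout_of(1000)
        genes = genes_at(list(range(0, 10_000_000, 500_000)))
        prof = gene_density_profile(np.zeros(1000), genes, layout, window=100_000, classes=5)
        assert (prof == 0).all()

    def test_class_occupancy_balanced(self):
        layout = layout_of(1000)
        genes = genes_at(list(range(0, 10_000_000, 130_000)))
        # 10 windows into 4 classes: occupancy differs by at most one window
        from chipnorm.evaluation import _gene_counts_per_window, window_values

        merged = window_values(np.zeros(1000), layout, 100_000).merge(
            _gene_counts_per_window(genes, layout, 100_000), on=["chrom", "start"]
        )
        order = np.argsort(merged["genes"].to_numpy(), kind="stable")
        sizes = [len(g) for g in np.array_split(order, 4)]
        assert max(sizes) - min(sizes) <= 1

    def test_fewer_windows_than_classes_is_an_error(self):
        layout = layout_of(100)
        with pytest.raises(ValueError, match="windows"):
            gene_density_profile(
                np.zeros(100), genes_at([0]), layout, window=100_000, classes=10
            )


class TestPromoterSensitivity:
    def test_forced_hit_and_miss(self):
        layout = layout_of(20)
        codes = np.zeros(20, dtype=np.int8)
        codes[5] = DHE_LIB1  # promoter bin of the gene at 5500
        labels = labels_of(codes)
        genes = genes_at([5500, 15_500])
        expr = expr_table([("g0", 10.0, 100.0), ("g1", 10.0, 10.0)])
        out = promoter_sensitivity(labels, genes, expr, layout, fold=4.0)
        assert out["cond2_over"]["n_genes"] == 1
        assert out["cond2_over"]["sensitivity_pct"] == 100.0
        assert out["cond2_over"]["error_pct"] == 0.0

    def test_all_none_labels(self):
        layout = layout_of(20)
        labels = labels_of(np.zeros(20, dtype=np.int8))
        genes = genes_at([5500])
        expr = expr_table([("g0", 10.0, 100.0)])
        out = promoter_sensitivity(labels, genes, expr, layout, fold=4.0)
        assert out["cond2_over"]["sensitivity_pct"] == 0.0
        assert out["cond2_over"]["error_pct"] == 0.0

    def test_no_gene_passes_filter_is_an_error(self):
        layout = layout_of(20)
        labels = labels_of(np.zeros(20, dtype=np.int8))
        genes = genes_at([5500])
        expr = expr_table([("g0", 10.0, 11.0)])
        with pytest.raises(ValueError, match="fold"):
            promoter_sensitivity(labels, genes, expr, layout, fold=4.0)

    def test_multi_tss_gene_counts_once(self):
        layout = layout_of(20)
        codes = np.zeros(20, dtype=np.int8)
        codes[5] = DHE_LIB1
        labels = labels_of(codes)
        genes = GeneSet(
            pd.DataFrame(
                [("g0", "chr1", 5500, "+"), ("g0", "chr1", 15_500, "+")],
                columns=["gene_id", "chrom", "tss", "strand"],
            )
        )
        expr = expr_table([("g0", 10.0, 100.0)])
        out = promoter_sensitivity(labels, genes, expr, layout, fold=4.0)
        assert out["cond2_over"]["n_genes"] == 1
        assert out["cond2_over"]["sensitivity_pct"] == 100.0

    def test_pseudocount_guards_zero_expression(self):
        expr = expr_table([("g0", 0.0, 100.0), ("g1", 0.0, 0.0)])
        cond2, cond1 = select_differential_genes(expr, fold=4.0)
        assert cond2 == ["g0"] and cond1 == []


class TestRoc:
    def _fixture(self):
        layout = layout_of(40)
        genes = genes_at([i * 1000 + 500 for i in range(0, 40, 2)])  # 20 genes
        rows = []
        for i, g in enumerate(genes.gene_ids):
            if i < 5:
                rows.append((g, 10.0, 100.0))  # class 1 (cond2-over)
            elif i < 10:
                rows.append((g, 100.0, 10.0))
            else:
                rows.append((g, 50.0, 50.0))
        return layout, genes, expr_table(rows)

    def test_perfect_labels_reach_corner(self):
        layout, genes, expr = self._fixture()
        codes = np.zeros(40, dtype=np.int8)
        for i in range(0, 10, 2):  # promoter bins of the 5 cond2-over genes
            codes[i] = DHE_LIB1
        curves = roc_points([(3.0, labels_of(codes))], genes, expr, layout)
        assert curves["cond2_over"][0] == (0.0, 1.0)

    def test_single_threshold_single_point(self):
        layout, genes, expr = self._fixture()
        curves = roc_points(
            [(3.0, labels_of(np.zeros(40, dtype=np.int8)))], genes, expr, layout
        )
        assert len(curves["cond2_over"]) == 1

    def test_random_labels_near_diagonal(self):
        from chipnorm.io_binning import GeneSet

        layout = layout_of(4000)
        rng = np.random.default_rng(0)
        genes = genes_at([i * 1000 + 500 for i in range(0, 4000, 2)])
        rows = []
        for i, g in enumerate(genes.gene_ids):
            r = i % 4
            if r == 0:
                rows.append((g, 10.0, 100.0))
            elif r == 1:
                rows.append((g, 100.0, 10.0))
            else:
                rows.append((g, 10.0, 10.0))
        expr = expr_table(rows)
        codes = np.where(rng.random(4000) < 0.3, DHE_LIB1, NONE).astype(np.int8)
        curves = roc_points([(3.0, labels_of(codes))], genes, expr, layout)
        fpr, tpr = curves["cond2_over"][0]
        assert abs(tpr - fpr) < 0.07


class TestReplicateFpr:
    def test_all_none_is_zero(self):
        labels = BinLabels(
            labels=np.zeros(10, dtype=np.int8),
            norm1=np.zeros(10),
            norm2=np.zeros(10),
            stage2=np.ones(10, dtype=bool),
        )
        assert replicate_fpr(labels) == 0.0

    def test_percentage_arithmetic(self):
        codes = np.zeros(10_000, dtype=np.int8)
        codes[0] = DHE_LIB1
        labels = BinLabels(
            labels=codes,
            norm1=np.zeros(10_000),
            norm2=np.zeros(10_000),
            stage2=np.ones(10_000, dtype=bool),
        )
        assert replicate_fpr(labels) == pytest.approx(0.01)


PROMOTER_STATES = [
    (frozenset(), 1),
    (frozenset({DHE_LIB1}), 2),
    (frozenset({DHE_LIB2}), 4),
    (frozenset({CHE}), 3),
    (frozenset({DHE_LIB1, DHE_LIB2}), 3),
    (frozenset({DHE_LIB1, CHE}), 3),
    (frozenset({DHE_LIB2, CHE}), 3),
    (frozenset({DHE_LIB1, DHE_LIB2, CHE}), 3),
]


class TestGeneClassifiers:
    @pytest.mark.parametrize("codes,expected", PROMOTER_STATES)
    def test_type_classification_truth_table(self, codes, expected):
        """Exhaustive promoter-state combinations against the 4-type rules."""
        layout = layout_of(10)
        vec = np.zeros(10, dtype=np.int8)
        for j, code in enumerate(sorted(codes)):
            vec[4 + j] = code  # all inside TSS +/- 1 kb of tss=5500
        genes = genes_at([5500])
        out = classify_gene_types(labels_of(vec), genes, layout)
        assert out["g0"] == expected

    def test_gene_without_promoter_overlap_is_type_1(self):
        layout = layout_of(10)
        vec = np.full(10, CHE, dtype=np.int8)
        genes = GeneSet(
            pd.DataFrame(
                [("far", "chr2", 5000, "+")],
                columns=["gene_id", "chrom", "tss", "strand"],
            )
        )
        out = classify_gene_types(labels_of(vec), genes, layout)
        assert out["far"] == 1


def _presence_codes(present1: bool, present2: bool):
    """Promoter codes giving a mark presence pattern per cell type."""
    if present1 and present2:
        return [CHE]
    if present1:
        return [DHE_LIB1]
    if present2:
        return [DHE_LIB2]
    return []


class TestBivalentClasses:
    def test_named_example(self):
        # cell 1 carries K4+K27 (bivalent), cell 2 keeps only K27
        layout = layout_of(10)
        k27 = np.zeros(10, dtype=np.int8)
        k27[5] = CHE  # K27 present in both cells
        k4 = np.zeros(10, dtype=np.int8)
        k4[5] = DHE_LIB1  # K4 present in cell 1 only
        genes = genes_at([5500])
        out = bivalent_classes(labels_of(k27), layout, labels_of(k4), layout, genes)
        assert out["g0"] == "K4+K27-K27"

    def test_no_marks_anywhere(self):
        layout = layout_of(10)
        zeros = labels_of(np.zeros(10, dtype=np.int8))
        out = bivalent_classes(zeros, layout, zeros, layout, genes_at([5500]))
        assert out["g0"] == "none-none"

    def test_all_16_classes_enumerate(self):
        """Every (cell1, cell2) x (K4, K27) presence combination maps to a
        distinct label and all 16 appear."""
        layout = layout_of(10)
        genes = genes_at([5500])
        seen = set()
        for k4_1, k4_2, k27_1, k27_2 in itertools.product([False, True], repeat=4):
            k4 = np.zeros(10, dtype=np.int8)
            k27 = np.zeros(10, dtype=np.int8)
            for j, c in enumerate(_presence_codes(k4_1, k4_2)):
                k4[5 + j] = c
            for j, c in enumerate(_presence_codes(k27_1, k27_2)):
                k27[5 + j] = c
            out = bivalent_classes(labels_of(k27), layout, labels_of(k4), layout, genes)
            seen.add(out["g0"])
        assert len(seen) == 16
        states = {"none", "K4", "K27", "K4+K27"}
        assert seen == {f"{a}-{b}" for a in states for b in states}


class TestLabelsFromRegions:
    def test_round_trip_with_merge(self):
        from chipnorm.diff_norm import merge_regions

        layout = layout_of(12)
        codes = np.array(
            [NONE, DHE_LIB1, DHE_LIB1, NONE, CHE, NONE, DHE_LIB2, DHE_LIB2, NONE, NONE, CHE, NONE],
            dtype=np.int8,
        )
        regions = merge_regions(codes, layout)
        back = labels_from_regions(regions, layout)
        assert np.array_equal(back.labels, codes)
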