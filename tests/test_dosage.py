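import numpy as np
import pandas as pd
import pytest

import germline_reset as gr
from germline_reset import dosage
from germline_reset.expression import detect_expressed_genes
from germline_reset.stats import compare_groups, dunn_test, kruskal_dunn


def _matrix(tpm_rows, chroms, cells=None, tss=None):
    genes = [f"g{i}" for i in range(len(tpm_rows))]
    ann = pd.DataFrame(
        {
            "chrom": chroms,
            "start": tss if tss is not None else [0] * len(genes),
            "end": [(t or 0) + 100 for t in (tss or [0] * len(genes))],
            "strand": ["+"] * len(genes),
            "single_copy_y": [False] * len(genes),
        },
        index=genes,
    )
    if tss is not None:
        ann["tss"] = tss
    tpm = pd.DataFrame(tpm_rows, index=genes,
                       columns=cells or [f"c{i}" for i in range(len(tpm_rows[0]))])
    return gr.ExpressionMatrix(tpm, ann)


class TestGeometricMean:
    def test_closed_forms(self, thr):
        m = _matrix([[0.0], [3.0]], ["X", "X"])
        out = dosage.chrom_geometric_mean(m, "X", thr)
        assert out.iloc[0] == pytest.approx(2.0)  # geomean of (1, 4)

    def test_all_zero_gives_pseudocount_identity(self, thr):
        m = _matrix([[0.0], [0.0]], ["X", "X"])
        assert dosage.chrom_geometric_mean(m, "X", thr).iloc[0] == pytest.approx(1.0)

    def test_single_gene(self, thr):
        m = _matrix([[7.0]], ["X"])
        assert dosage.chrom_geometric_mean(m, "X", thr).iloc[0] == pytest.approx(8.0)

    def test_no_genes_errors(self, thr):
        m = _matrix([[1.0]], ["auto1"])
        with pytest.raises(ValueError, match="no genes"):
            dosage.chrom_geometric_mean(m, "X", thr)


class TestFmRatio:
    def test_identical_sexes_give_unit_ratio(self, thr):
        m = _matrix([[5.0, 5.0], [9.0, 9.0]], ["X", "auto1"], cells=["f", "m"])
        sex = pd.Series({"f": "F", "m": "M"})
        out = dosage.fm_ratio(m, sex, thr, chroms=("X", "auto1"))
        assert out["X"] == pytest.approx(1.0)
        assert out["auto1"] == pytest.approx(1.0)

    def test_missing_sex_errors(self, thr):
        m = _matrix([[5.0, 5.0]], ["X"], cells=["a", "b"])
        sex = pd.Series({"a": "F", "b": "F"})
        with pytest.raises(ValueError, match="lacks both sexes"):
            dosage.fm_ratio(m, sex, thr, chroms=("X",))

    def test_zero_shared_genes_errors(self, thr):
        m = _matrix([[5.0, 0.0]], ["X"], cells=["f", "m"])
        sex = pd.Series({"f": "F", "m": "M"})
        with pytest.raises(ValueError, match="shared expressed"):
            dosage.fm_ratio(m, sex, thr, chroms=("X",))

    def test_planted_twofold_recovered(self, genome, expr_bundle, thr):
        matrix, meta, truth = expr_bundle
        pgc = meta.index[meta["stage"] == "pgc"]
        sub = matrix.subset_cells(list(pgc))
        sex = truth.cells["true_sex"].reindex(sub.cells)
        out = dosage.fm_ratio(sub, sex, thr)
        assert 1.8 <= out["X"] <= 2.2
        assert out[["auto1", "auto2", "auto3"]].between(0.9, 1.1).all()


class TestFmRatioWindows:
    def test_boundary_and_empty_windows(self, thr):
        thr_small = thr.replace(fm_window=1000, fm_window_min_genes=1)
        # TSS exactly at the boundary goes to the right-open bin containing it
        m = _matrix(
            [[4.0, 2.0], [6.0, 2.0], [8.0, 2.0]], ["X", "X", "X"],
            cells=["f", "m"], tss=[999, 1000, 1001],
        )
        sex = pd.Series({"f": "F", "m": "M"})
        out = dosage.fm_ratio_windows(m, sex, thr_small, chrom_size=4000)
        assert out.loc[0, "n_genes"] == 1
        assert out.loc[1, "n_genes"] == 2
        assert out.loc[2, "n_genes"] == 0
        assert np.isnan(out.loc[2, "median_fm_ratio"])  # missing, not zero
        assert len(out) == 4

    def test_gene_order_permutation_invariance(self, expr_bundle, thr, genome):
        matrix, meta, truth = expr_bundle
        pgc = meta.index[meta["stage"] == "pgc"]
        sub = matrix.subset_cells(list(pgc))
        sex = truth.cells["true_sex"].reindex(sub.cells)
        a = dosage.fm_ratio_windows(sub, sex, thr, chrom_size=genome.chrom_sizes["X"])
        perm = np.random.default_rng(0).permutation(len(sub.tpm))
        shuffled = gr.ExpressionMatrix(sub.tpm.iloc[perm], sub.genes.iloc[perm])
        b = dosage.fm_ratio_windows(shuffled, sex, thr,
                                    chrom_size=genome.chrom_sizes["X"])
        pd.testing.assert_frame_equal(a, b)

    def test_uniform_twofold_in_populated_windows(self, expr_bundle, thr, genome):
        matrix, meta, truth = expr_bundle
        pgc = meta.index[meta["stage"] == "pgc"]
        sub = matrix.subset_cells(list(pgc))
        sex = truth.cells["true_sex"].reindex(sub.cells)
        out = dosage.fm_ratio_windows(sub, sex, thr,
                                      chrom_size=genome.chrom_sizes["X"])
        populated = out.dropna(subset=["median_fm_ratio"])
        assert len(populated) >= 1
        assert ((populated["median_fm_ratio"] > 1.5)
                & (populated["median_fm_ratio"] < 2.6)).all()


class TestXToAllA:
    def test_degenerate_identity(self, thr):
        # all genes drawn, X total equals autosomal total -> exactly 1
        m = _matrix([[3.0], [7.0], [6.0], [4.0]],
                    ["X", "X", "auto1", "auto2"])
        r = dosage.x_to_alla_bootstrap(m, "c0", thr, seed=0, n_genes=2, n_reps=10)
        assert r == pytest.approx(1.0)

    def test_determinism_and_insufficient_genes(self, thr):
        m = _matrix([[3.0], [7.0], [6.0], [4.0]], ["X", "X", "auto1", "auto2"])
        a = dosage.x_to_alla_bootstrap(m, "c0", thr, seed=5, n_genes=1, n_reps=50)
        b = dosage.x_to_alla_bootstrap(m, "c0", thr, seed=5, n_genes=1, n_reps=50)
        assert a == b
        with pytest.raises(ValueError, match="smaller n_genes"):
            dosage.x_to_alla_bootstrap(m, "c0", thr, seed=0, n_genes=3, n_reps=10)

    def test_stable_over_n_genes_range(self, expr_bundle, thr):
        """Bootstrap estimator varies little over a 2x n_genes range."""
        matrix, meta, truth = expr_bundle
        cell = truth.cells.index[truth.cells["xc_state"] == "XCR"][0]
        stage_cells = meta.index[meta["stage"] == "pgc"]
        expressed = detect_expressed_genes(matrix.subset_cells(list(stage_cells)), thr)
        r1 = dosage.x_to_alla_bootstrap(matrix, cell, thr, seed=3,
                                        expressed=expressed, n_genes=12, n_reps=500)
        r2 = dosage.x_to_alla_bootstrap(matrix, cell, thr, seed=4,
                                        expressed=expressed, n_genes=24, n_reps=500)
        assert abs(np.log(r1 / r2)) < np.log(1.35)


class TestGroupComparisons:
    def test_identical_groups_null(self):
        out = compare_groups({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]},
                             "mann-whitney")
        assert out["p_raw"].iloc[0] > 0.9

    def test_exact_rank_enumeration(self):
        # all 3-subsets of 6 ranks: P(U <= 0) one-sided = 1/20 -> two-sided 0.1
        out = compare_groups({"a": [1, 2, 3], "b": [11, 12, 13]}, "mann-whitney")
        assert out["p_raw"].iloc[0] == pytest.approx(0.1)

    def test_pairwise_wilcoxon_holm(self):
        groups = {"a": [1, 2, 3, 4], "b": [1.1, 2.1, 3.1, 4.1],
                  "c": [10, 11, 12, 13]}
        out = compare_groups(groups, "pairwise-wilcoxon")
        assert len(out) == 3
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()

    def test_kruskal_dunn_detects_planted_shift(self):
        rng = np.random.default_rng(0)
        g1 = rng.normal(0, 1, 40)
        g2 = rng.normal(0, 1, 40)
        g3 = rng.normal(2.0, 1, 40)
        p_omni, table = kruskal_dunn({"g1": g1, "g2": g2, "g3": g3})
        assert p_omni < 1e-6
        shifted = table[(table["group1"] == "g1") & (table["group2"] == "g3")]
        assert shifted["p_adj"].iloc[0] < 1e-4
        null_pair = table[(table["group1"] == "g1") & (table["group2"] == "g2")]
        assert null_pair["p_adj"].iloc[0] > 0.05

    def test_dunn_ties_handled(self):
        out = dunn_test({"a": [1, 1, 2, 2], "b": [1, 2, 2, 3]})
        assert np.isfinite(out["z"]).all()

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="fewer than"):
            compare_groups({"a": [1.0, 2.0], "b": []}, "mann-whitney")
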