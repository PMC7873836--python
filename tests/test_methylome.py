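import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact, hypergeom

import germline_reset.methylome as me
from germline_reset.methylome import (
    classify_promoters,
    classify_te_content,
    detect_escapees,
    gene_metaprofile,
    interval_overlap_fraction,
    region_methylation,
    repeat_expression_rpm,
    te_enrichment,
    tile_methylation,
    window_composition,
)


def _cpgs(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "total"])
    df["level"] = df["meth"] / df["total"]
    return df


class TestRegionMethylation:
    def test_weighted_arithmetic(self):
        cpgs = _cpgs([("c", 10, 5, 10), ("c", 20, 0, 10)])
        iv = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [100]})
        out = region_methylation(cpgs, iv)
        assert out.loc[0, "level"] == pytest.approx(0.25)
        assert out.loc[0, "n_cpg"] == 2

    def test_empty_interval_is_missing_not_zero(self):
        cpgs = _cpgs([("c", 10, 5, 10)])
        iv = pd.DataFrame({"chrom": ["c"], "start": [50], "end": [60]})
        out = region_methylation(cpgs, iv)
        assert np.isnan(out.loc[0, "level"])

    def test_unknown_chrom_errors(self):
        cpgs = _cpgs([("c", 10, 5, 10)])
        iv = pd.DataFrame({"chrom": ["nope"], "start": [0], "end": [10]})
        with pytest.raises(ValueError, match="unknown chromosome"):
            region_methylation(cpgs, iv)

    def test_matches_naive_oracle_on_random_intervals(self, methylomes, genome):
        """Exact agreement with per-CpG brute-force aggregation."""
        tables, _ = methylomes
        cpgs = tables["PGC_F"]
        rng = np.random.default_rng(77)
        chroms = list(genome.cpg_sites)
        n = 1000
        iv = pd.DataFrame(
            {
                "chrom": rng.choice(chroms[:-1], size=n),
                "start": rng.integers(0, 990_000, size=n),
            }
        )
        iv["end"] = iv["start"] + rng.integers(100, 10_000, size=n)
        fast = region_methylation(cpgs, iv, chrom_sizes=genome.chrom_sizes)
        arrays = {
            c: sub.sort_values("pos")[["pos", "meth", "total"]].to_numpy()
            for c, sub in cpgs.groupby("chrom")
        }
        for i, row in iv.iterrows():
            arr = arrays[row.chrom]
            mask = (arr[:, 0] >= row.start) & (arr[:, 0] < row.end)
            m, t = arr[mask, 1].sum(), arr[mask, 2].sum()
            assert fast.loc[i, "meth_reads"] == m
            assert fast.loc[i, "total_reads"] == t
            if t == 0:
                assert np.isnan(fast.loc[i, "level"])
            else:
                assert fast.loc[i, "level"] == pytest.approx(m / t, abs=0)


class TestTiling:
    def test_partial_last_tile(self):
        cpgs = _cpgs([("c", 10, 1, 2)])
        out = tile_methylation(cpgs, {"c": 2500}, 1000)
        assert len(out) == 3
        assert out.loc[2, "end"] - out.loc[2, "start"] == 500

    def test_recovers_simulated_rates(self, methylomes, sizes_no_y):
        tables, _ = methylomes
        pgc = tile_methylation(tables["PGC_F"], sizes_no_y, 1000)
        soma = tile_methylation(tables["soma_F"], sizes_no_y, 1000)
        assert pgc["level"].median() < 0.05
        assert soma["level"].median() > 0.70


class TestPromoterClasses:
    def test_degenerate_compositions(self, thr):
        out = classify_promoters({"at": "AT" * 400, "cg": "CG" * 400}, thr)
        assert out.loc["at", "class"] == "LCP"
        assert out.loc["cg", "class"] == "HCP"

    def test_constructed_icp_matches_formula_oracle(self, thr):
        # periodic 20-mer: 3 C, 3 G, 1 CpG -> per-window (500 bp) counts are
        # exact multiples; CpG ratio = n_cpg * L / (nC * nG)
        unit = "CCCCCCAGGGGGGTCGACGA"
        assert unit.count("C") == 8 and unit.count("G") == 8
        seq = unit * 75  # 1500 bp
        win = window_composition(seq, thr.promoter_win, thr.promoter_step)
        # oracle at offset 0: direct counts over the first 500 bases
        w = seq[:500]
        ncpg = sum(1 for i in range(499) if w[i] == "C" and w[i + 1] == "G")
        expected = ncpg * 500 / (w.count("C") * w.count("G"))
        assert win.loc[0, "cpg_ratio"] == pytest.approx(expected, rel=1e-12)
        cls = classify_promoters({"p": seq}, thr)
        assert 0.48 < expected <= 0.75
        assert cls.loc["p", "class"] == "ICP"

    def test_short_sequence_uncallable(self, thr):
        with pytest.warns(UserWarning, match="uncallable"):
            out = classify_promoters({"p": "ACGT" * 10}, thr)
        assert out.loc["p", "class"] == "uncallable"

    def test_partition_is_total_and_recovers_planted_classes(self, genome, thr):
        out = classify_promoters(genome.promoter_seqs, thr)
        assert set(out["class"]) <= {"HCP", "ICP", "LCP"}
        agreement = (
            out["class"].reindex(genome.promoter_class_truth.index)
            == genome.promoter_class_truth
        ).mean()
        assert agreement > 0.9


class TestMetaprofile:
    def test_uniform_methylome_is_flat(self):
        pos = np.arange(100, 30_000, 37)
        cpgs = _cpgs([("c", int(p), 1, 100) for p in pos])
        genes = pd.DataFrame(
            {"chrom": ["c"], "start": [10_000], "end": [20_000], "strand": ["+"]})
        prof = gene_metaprofile(cpgs, genes, flank=5000, bins=(10, 20, 10))
        assert np.nanmax(np.abs(prof["mean_level"] - 0.01)) < 1e-12

    def test_minus_strand_mirrors_plus_strand(self):
        rng = np.random.default_rng(3)
        L = 40_000
        pos = np.sort(rng.choice(L, size=600, replace=False))
        meth = rng.integers(0, 5, size=600)
        cpgs = _cpgs([("c", int(p), int(m), 10) for p, m in zip(pos, meth)])
        mirror = _cpgs(
            [("c", int(L - 1 - p), int(m), 10) for p, m in zip(pos, meth)])
        g_plus = pd.DataFrame(
            {"chrom": ["c"], "start": [15_000], "end": [25_000], "strand": ["+"]})
        g_minus = pd.DataFrame(
            {"chrom": ["c"], "start": [L - 25_000], "end": [L - 15_000],
             "strand": ["-"]})
        p1 = gene_metaprofile(cpgs, g_plus, flank=5000, bins=(10, 20, 10))
        p2 = gene_metaprofile(mirror, g_minus, flank=5000, bins=(10, 20, 10))
        np.testing.assert_allclose(p1["mean_level"], p2["mean_level"])

    def test_promoter_dip_recovered_in_soma(self, methylomes, genome):
        """CGI promoters are unmethylated in soma: the profile dips at the TSS."""
        tables, _ = methylomes
        cgi_genes = [g[4:] for g in genome.cgis["name"]]
        genes = genome.genes.loc[
            [g for g in cgi_genes if genome.genes.loc[g, "chrom"] != "Y"]
        ].reset_index()
        prof = gene_metaprofile(tables["soma_F"], genes, flank=5000)
        tss_bin = prof.loc[45:55, "mean_level"].min()
        flank_level = prof.loc[:20, "mean_level"].mean()
        assert tss_bin < 0.35
        assert flank_level > 0.6

    def test_short_genes_skipped(self, caplog):
        cpgs = _cpgs([("c", 10, 1, 10)])
        genes = pd.DataFrame(
            {"chrom": ["c"], "start": [0], "end": [50], "strand": ["+"]})
        with caplog.at_level("INFO", logger="germline_reset"):
            prof = gene_metaprofile(cpgs, genes, flank=100, bins=(5, 100, 5))
        assert "skipped" in caplog.text
        assert prof["n_sites"].sum() == 0


class TestEscapeeTiles:
    def test_fraction_rule_and_strict_boundary(self, thr):
        # ten covered CpGs, three at level >= 0.15 -> frac 0.30 -> meth+
        rows = [("c", 10 + i, (3 if i < 3 else 0), 10) for i in range(10)]
        out = detect_escapees(_cpgs(rows), {"c": 800}, thr)
        assert out.loc[0, "class"] == "meth+"
        assert out.loc[0, "frac"] == pytest.approx(0.3)
        # exactly 20% is meth- (strict inequality)
        rows = [("c", 10 + i, (3 if i < 2 else 0), 10) for i in range(10)]
        out = detect_escapees(_cpgs(rows), {"c": 800}, thr)
        assert out.loc[0, "class"] == "meth-"

    def test_low_coverage_cpgs_do_not_count(self, thr):
        rows = [("c", 10 + i, 4, 4) for i in range(10)]  # below 5x
        out = detect_escapees(_cpgs(rows), {"c": 800}, thr)
        assert out.loc[0, "class"] == "uncallable"
        assert out.loc[0, "n_cpg_5x"] == 0

    def test_monotone_in_meth_level_threshold(self, methylomes, sizes_no_y, thr):
        tables, _ = methylomes
        lo = detect_escapees(tables["PGC_F"], sizes_no_y, thr)
        hi = detect_escapees(
            tables["PGC_F"], sizes_no_y, thr.replace(escapee_meth_level=0.30))
        flipped_up = (lo["class"] == "meth-") & (hi["class"] == "meth+")
        assert not flipped_up.any()
        assert (hi["n_cpg_meth"] <= lo["n_cpg_meth"]).all()

    def test_high_coverage_limit_is_deterministic(self, genome, thr):
        """At coverage ~200 the calls equal the deterministic classification
        of the generating rates: exactly the planted tiles are meth+."""
        import germline_reset as gr

        tables, truth = gr.simulate_methylome(
            genome, [("p", "PGC", "F")], 55, coverage_mean=200.0)
        sizes = {c: s for c, s in genome.chrom_sizes.items() if c != "Y"}
        out = detect_escapees(tables["p"], sizes, thr)
        called = set(map(tuple, out.loc[out["class"] == "meth+",
                                        ["chrom", "start"]].values))
        planted = set(map(tuple, truth.escapee_tiles[["chrom", "start"]].values))
        assert called == planted


class TestTeContent:
    def test_boundary_arithmetic(self, thr):
        tiles = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [800]})
        reps = pd.DataFrame(
            {"chrom": ["c"], "start": [0], "end": [79], "family": ["f"]})
        out = classify_te_content(tiles, reps, thr)
        assert out.loc[0, "te_overlap_frac"] == pytest.approx(79 / 800)
        assert out.loc[0, "te_class"] == "TE-poor"
        reps80 = reps.assign(end=[80])
        out = classify_te_content(tiles, reps80, thr)
        assert out.loc[0, "te_class"] == "TE-rich"

    def test_full_overlap_and_union_semantics(self, thr):
        tiles = pd.DataFrame({"chrom": ["c"], "start": [100], "end": [900]})
        inside = pd.DataFrame(
            {"chrom": ["c"], "start": [0], "end": [2000], "family": ["f"]})
        assert classify_te_content(tiles, inside, thr).loc[0, "te_overlap_frac"] == 1.0
        double = pd.DataFrame(
            {"chrom": ["c", "c"], "start": [100, 100], "end": [300, 300],
             "family": ["f", "f"]})
        out = classify_te_content(tiles, double, thr)
        assert out.loc[0, "te_overlap_frac"] == pytest.approx(200 / 800)


class TestTeEnrichment:
    def test_null_identity(self, thr):
        tiles = pd.DataFrame(
            {"chrom": "c", "start": np.arange(0, 80_000, 800)})
        tiles["end"] = tiles["start"] + 800
        reps = pd.DataFrame(
            {"chrom": "c", "start": tiles["start"][::10] + 10,
             "end": tiles["start"][::10] + 110, "family": "f"})
        fg = tiles.iloc[:50]
        out = te_enrichment(fg, tiles, reps, thr)
        # identical overlap structure in fg and bg -> ES ~ 1
        assert 0.5 <= out.loc["f", "es"] <= 2.0
        assert not out.loc["f", "enriched"]

    def test_es_and_fisher_against_exact_tail(self, thr):
        """Constructed table (8/20 escapee vs 10/200 background) -> ES 8 and
        a p-value equal to the independently summed hypergeometric tails."""
        tiles = pd.DataFrame({"chrom": "c", "start": np.arange(0, 800 * 220, 800)})
        tiles["end"] = tiles["start"] + 800
        fg = tiles.iloc[:20]
        bg = tiles.iloc[20:]
        overlap_rows = pd.concat([fg.iloc[:8], bg.iloc[:10]])
        reps = pd.DataFrame(
            {"chrom": "c", "start": overlap_rows["start"] + 5,
             "end": overlap_rows["start"] + 105, "family": "young"})
        out = te_enrichment(fg, bg, reps, thr)
        assert out.loc["young", "es"] == pytest.approx((8 / 20) / (10 / 200))
        # independent oracle: two-sided Fisher as sum of hypergeometric
        # probabilities no larger than the observed table's
        M, K, N, a = 220, 18, 20, 8
        probs = [hypergeom.pmf(k, M, K, N) for k in range(0, K + 1)]
        p_exact = sum(p for p in probs if p <= probs[a] * (1 + 1e-9))
        assert out.loc["young", "p"] == pytest.approx(p_exact, rel=1e-8)
        assert out.loc["young", "enriched"]

    def test_empty_tile_sets_rejected(self, thr):
        tiles = pd.DataFrame({"chrom": ["c"], "start": [0], "end": [800]})
        reps = pd.DataFrame(
            {"chrom": ["c"], "start": [0], "end": [10], "family": ["f"]})
        with pytest.raises(ValueError, match="non-empty"):
            te_enrichment(tiles.iloc[:0], tiles, reps, thr)


class TestRepeatRpm:
    def test_arithmetic_and_scale_invariance(self):
        counts = pd.Series({"r1": 100, "r2": 50})
        out = repeat_expression_rpm(counts, 1_000_000)
        assert out["r1"] == pytest.approx(100.0)
        doubled = repeat_expression_rpm(counts * 2, 2_000_000)
        pd.testing.assert_series_equal(out, doubled)

    def test_family_additivity_and_rpkm_variant(self):
        counts = pd.Series({"r1": 100, "r2": 50, "r3": 10})
        fams = pd.Series({"r1": "A", "r2": "A", "r3": "B"})
        rpm = repeat_expression_rpm(counts, 1e6)
        sums = me.family_sums(rpm, fams)
        assert sums["A"] == pytest.approx(rpm["r1"] + rpm["r2"])
        lengths = pd.Series({"r1": 500, "r2": 1000, "r3": 2000})
        rpkm = repeat_expression_rpm(counts, 1e6, lengths=lengths, rpkm=True)
        assert rpkm["r1"] == pytest.approx(200.0)

    def test_zero_library_errors(self):
        with pytest.raises(ValueError, match="positive"):
            repeat_expression_rpm(pd.Series({"r": 1}), 0)
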