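"""Normalization, dispersion estimation and the NB Wald contrast test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import triadhet as th
from triadhet.diffexpr import DISPERSION_FLOOR, deg_set, detection_filter


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, matrix_factory):
        m = matrix_factory(
            {"g1": [10, 10, 10, 10], "g2": [5, 5, 5, 5]},
            ["parent1", "parent1", "parent2", "parent2"],
        )
        assert np.allclose(th.size_factors(m), 1.0)

    def test_doubled_column_gets_double_factor(self, matrix_factory):
        m = matrix_factory(
            {"g1": [10, 10, 10, 20], "g2": [6, 6, 6, 12], "g3": [40, 40, 40, 80]},
            ["parent1", "parent1", "parent2", "parent2"],
        )
        f = th.size_factors(m)
        assert f.iloc[3] / f.iloc[0] == pytest.approx(2.0)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_genes_with_zeros_excluded_from_reference(self, matrix_factory):
        # g2 has a zero; factors must come from g1/g3 only (identical columns)
        m = matrix_factory(
            {"g1": [10, 10, 10, 10], "g2": [0, 100, 100, 100], "g3": [7, 7, 7, 7]},
            ["parent1", "parent1", "parent2", "parent2"],
        )
        assert np.allclose(th.size_factors(m), 1.0)

    def test_no_allpositive_gene_falls_back_with_warning(self, matrix_factory):
        m = matrix_factory(
            {"g1": [0, 10, 10, 10], "g2": [10, 0, 10, 10]},
            ["parent1", "parent1", "parent2", "parent2"],
        )
        with pytest.warns(RuntimeWarning, match="total-count"):
            f = th.size_factors(m)
        assert (f > 0).all()


class TestEstimateDispersion:
    def test_equal_replicates_hit_floor(self, matrix_factory):
        m = matrix_factory(
            {"g1": [10, 10, 10, 10]}, ["parent1", "parent1", "parent2", "parent2"]
        )
        assert th.estimate_dispersion(m).iloc[0] == DISPERSION_FLOOR

    def test_recovers_designed_dispersion(self):
        cfg = th.TriadSimConfig(
            n_genes=2000, n_reps=50,
            pattern_proportions={"UNCLASSIFIED": 1.0}, seed=3,
        )
        disp = th.estimate_dispersion(th.simulate_triad(cfg).counts)
        assert 0.04 <= np.median(disp) <= 0.06

    def test_poisson_counts_estimated_near_zero(self):
        cfg = th.TriadSimConfig(
            n_genes=2000, n_reps=50, dispersion=1e-6,
            pattern_proportions={"UNCLASSIFIED": 1.0}, seed=4,
        )
        disp = th.estimate_dispersion(th.simulate_triad(cfg).counts)
        assert np.median(disp) <= 0.01


class TestContrast:
    def test_all_zero_gene_contract(self, matrix_factory):
        m = matrix_factory(
            {"g1": [0, 0, 0, 0], "g2": [10, 12, 30, 28]},
            ["parent1", "parent1", "hybrid", "hybrid"],
        )
        res = th.test_contrast(m, "parent1", "hybrid")
        assert res.loc["g1", "p"] == 1.0
        assert res.loc["g1", "log2FC"] == 0.0
        assert not res.loc["g1", "significant"]

    def test_swapping_groups_negates_log2fc(self, small_triad):
        a = th.test_contrast(small_triad.counts, "parent1", "hybrid")
        b = th.test_contrast(small_triad.counts, "hybrid", "parent1")
        assert np.allclose(a["log2FC"], -b["log2FC"])
        assert np.allclose(a["p"], b["p"])

    def test_global_scaling_leaves_statistics_unchanged(self, small_triad):
        # doubling depth everywhere only perturbs the Poisson (1/mu) part of
        # the NB variance, so p-values agree closely and calls agree
        m = small_triad.counts
        scaled = th.ExpressionMatrix(m.counts * 2, m.design.copy())
        a = th.test_contrast(m, "parent1", "hybrid")
        b = th.test_contrast(scaled, "parent1", "hybrid")
        # floor-boundary genes (variance ~ mean) and the pseudocount in the
        # displayed fold change leave a small depth dependence at low counts
        assert ((a["p"] - b["p"]).abs() < 0.02).mean() >= 0.99
        expressed = (a["baseMeanA"] >= 10) & (a["baseMeanB"] >= 10)
        assert np.allclose(
            a.loc[expressed, "log2FC"], b.loc[expressed, "log2FC"], atol=0.1
        )
        assert (a["significant"] == b["significant"]).mean() > 0.99

    def test_padj_at_least_p_and_monotone(self, small_de):
        for res in small_de.values():
            assert (res["padj"] >= res["p"] - 1e-12).all()
            srt = res.sort_values("p")
            assert (np.diff(srt["padj"]) >= -1e-12).all()

    def test_significance_flag_definition(self, small_de):
        for res in small_de.values():
            expect = (res["p"] < 0.05) & (res["log2FC"].abs() >= 2.0)
            assert (res["significant"] == expect).all()


class TestTriadDE:
    def test_hybrid_identical_to_parent1_gives_no_degs(self, matrix_factory):
        rng = np.random.default_rng(0)
        base = rng.poisson(100, size=(50, 3))
        rows = {
            f"g{i}": list(base[i]) * 2 + list(rng.poisson(100, 3))
            for i in range(50)
        }
        m = matrix_factory(rows, ["parent1"] * 3 + ["hybrid"] * 3 + ["parent2"] * 3)
        res = th.triad_de(m)
        assert res["F1vsP1"]["significant"].sum() == 0

    def test_detection_filter_drops_undetected_genes(self, matrix_factory):
        m = matrix_factory(
            {"g1": [0, 0, 5, 5, 5, 5], "g2": [9, 9, 9, 9, 9, 9]},
            ["parent1", "parent1", "parent2", "parent2", "hybrid", "hybrid"],
        )
        assert list(detection_filter(m).genes) == ["g2"]

    def test_overdominant_truth_recovered_as_double_deg(self):
        """F1-vs-both-parents DEGs overlap the designed overdominant set."""
        props = th.default_pattern_proportions(deg_fraction=0.2)
        cfg = th.TriadSimConfig(n_genes=2000, pattern_proportions=props, seed=6)
        triad = th.simulate_triad(cfg)
        res = th.triad_de(triad.counts)
        both = deg_set(res["F1vsP1"]) & deg_set(res["F1vsP2"])
        cat = triad.truth.map(th.patterns.CATEGORY_OF)
        designed = set(triad.truth.index[cat.str.startswith("overdominant")])
        designed &= set(res["F1vsP1"].index)
        jaccard = len(both & designed) / len(both | designed)
        assert jaccard >= 0.8

    def test_up_down_counts_self_consistent(self, small_de):
        for res in small_de.values():
            up = int((res["significant"] & (res["log2FC"] > 0)).sum())
            down = int((res["significant"] & (res["log2FC"] < 0)).sum())
            assert up + down == int(res["significant"].sum())

    def test_agrees_with_deseq2_reference(self, small_triad):
        """Independent cross-check: DESeq2 calls on the same simulated triad."""
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        cfg = th.TriadSimConfig(n_genes=400, seed=21)
        triad = th.simulate_triad(cfg)
        ours = deg_set(th.triad_de(triad.counts)["F1vsP1"])
        meta = triad.counts.design.rename(columns={"genotype": "condition"})
        dds = DeseqDataSet(
            counts=triad.counts.counts.T, metadata=meta,
            design="~condition", quiet=True,
        )
        dds.deseq2()
        stat = DeseqStats(dds, contrast=["condition", "hybrid", "parent1"], quiet=True)
        stat.summary()
        r = stat.results_df
        theirs = set(r.index[(r["pvalue"] < 0.05) & (r["log2FoldChange"].abs() >= 2)])
        jaccard = len(ours & theirs) / len(ours | theirs)
        assert jaccard >= 0.8


class TestVennCounts:
    def test_toy_enumeration(self):
        v = th.venn_counts({"a", "b"}, {"b", "c"}, {"b"})
        assert v == {
            "A_only": 1, "B_only": 1, "C_only": 0,
            "AB": 0, "AC": 0, "BC": 0, "ABC": 1,
        }

    def test_identical_sets_all_triple_shared(self):
        v = th.venn_counts({"x", "y"}, {"x", "y"}, {"x", "y"})
        assert v["ABC"] == 2 and sum(v.values()) == 2

    @given(st.integers(0, 2**31 - 1))
    def test_region_sums_equal_union(self, seed):
        rng = np.random.default_rng(seed)
        universe = np.arange(500)
        sets = [set(rng.choice(universe, 100, replace=False)) for _ in range(3)]
        v = th.venn_counts(*sets)
        assert sum(v.values()) == len(sets[0] | sets[1] | sets[2])
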