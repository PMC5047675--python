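"""FPKM, size factors, NB differential expression, PCA and qPCR."""


import numpy as np
import pandas as pd
import pytest

import regulomics as rg
from regulomics.expression import CountMatrix, CtMatrix, ExpressionError


def toy_counts(counts: np.ndarray, lengths=None, conditions=None) -> CountMatrix:
    n_g, n_s = counts.shape
    genes = [f"g{i}" for i in range(n_g)]
    samples = [f"s{j}" for j in range(n_s)]
    conditions = conditions or ["A"] * (n_s // 2) + ["B"] * (n_s - n_s // 2)
    design = pd.DataFrame({"condition": conditions}, index=samples)
    gl = pd.Series(lengths if lengths is not None else [1000] * n_g, index=genes)
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), design, gl)


class TestFpkm:
    def test_closed_form(self):
        cm = toy_counts(np.array([[1000], [9_999_000]]), lengths=[1000, 1000], conditions=["A"])
        # depth = 10M, 1 kb gene, 1000 counts -> FPKM 100
        assert rg.fpkm(cm).iloc[0, 0] == pytest.approx(100.0)

    def test_zero_counts_zero_fpkm(self):
        cm = toy_counts(np.array([[0, 5], [10, 5]]))
        assert rg.fpkm(cm).iloc[0, 0] == 0.0

    def test_depth_scale_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.integers(1, 500, size=(50, 2))
        cm1 = toy_counts(base)
        cm2 = toy_counts(base * np.array([2, 1]))
        f1, f2 = rg.fpkm(cm1), rg.fpkm(cm2)
        np.testing.assert_allclose(f1.iloc[:, 0], f2.iloc[:, 0], rtol=1e-10)


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        cm = toy_counts(np.tile(np.arange(1, 51)[:, None], (1, 4)))
        np.testing.assert_allclose(rg.size_factors(cm), 1.0)

    def test_threefold_sample_detected(self):
        rng = np.random.default_rng(1)
        base = rng.integers(10, 500, size=(200, 3))
        counts = base.copy()
        counts[:, 2] = base[:, 2] * 0 + base[:, 0] * 3  # sample 2 = 3x sample 0
        counts[:, 1] = base[:, 0]
        counts[:, 0] = base[:, 0]
        sf = rg.size_factors(toy_counts(counts))
        assert sf.iloc[2] / sf.iloc[0] == pytest.approx(3.0, rel=1e-10)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(2)
        counts = rng.negative_binomial(10, 0.1, size=(300, 5)) + 1
        sf = rg.size_factors(toy_counts(counts))
        logs = np.log(counts.astype(float))
        ref = logs.mean(axis=1)
        want = np.exp(np.median(logs - ref[:, None], axis=0))
        want = want / np.median(want)
        np.testing.assert_allclose(sf.to_numpy(), want, rtol=1e-10)


class TestDeTest:
    def test_constant_gene_is_null(self):
        rng = np.random.default_rng(3)
        counts = rng.negative_binomial(20, 0.2, size=(100, 6))
        counts[0] = 77  # identical in every sample
        res = rg.de_test(toy_counts(counts), ("A", "B"))
        # size-factor normalisation leaves a sub-0.1 residual on the
        # identical-count gene; the test must still be firmly null
        assert abs(res.table.iloc[0]["log2fc"]) < 0.1
        assert res.table.iloc[0]["pvalue"] >= 0.5

    def test_single_replicate_rejected(self):
        counts = np.ones((10, 3), dtype=int)
        cm = toy_counts(counts, conditions=["A", "B", "B"])
        with pytest.raises(ExpressionError):
            rg.de_test(cm, ("A", "B"))

    def test_bh_fdr_rankwise_monotone(self, genome):
        cfg = rg.SimConfig(seed=30, planted_lfc={"KO": {f"gene{i:04d}": 1.5 for i in range(20)}})
        design = rg.default_design(cfg, ["2iLIF_WT", "KO"])
        cm, _ = rg.simulate_counts(genome, design, cfg)
        res = rg.de_test(cm, ("KO", "2iLIF_WT"))
        t = res.table.sort_values("pvalue")
        assert (np.diff(t["fdr"].to_numpy()) >= -1e-12).all()

    def test_log2fc_sign_matches_mean_ratio(self, genome):
        cfg = rg.SimConfig(
            seed=31,
            planted_lfc={"KO": {"gene0000": 2.0, "gene0001": -2.0}},
            base_mean_log=5.5,
        )
        design = rg.default_design(cfg, ["2iLIF_WT", "KO"])
        cm, _ = rg.simulate_counts(genome, design, cfg)
        res = rg.de_test(cm, ("KO", "2iLIF_WT"))
        assert res.table.loc["gene0000", "log2fc"] > 0
        assert res.table.loc["gene0001", "log2fc"] < 0


class TestBhAdjust:
    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.random(200) ** 2
        _, want, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(rg.bh_adjust(p), want, rtol=1e-12)


class TestPca:
    def test_two_planted_clusters_separate(self, genome):
        cfg = rg.SimConfig(
            seed=32,
            planted_lfc={"N2B27": {f"gene{i:04d}": 3.0 for i in range(60)}},
        )
        design = rg.default_design(cfg, ["2iLIF_WT", "N2B27"], n_rep=4)
        cm, _ = rg.simulate_counts(genome, design, cfg)
        coords, explained = rg.pca_embed(cm, n_top_variable=200)
        xy = coords[["PC1", "PC2"]].to_numpy()
        cond = cm.design["condition"].to_numpy()
        within, between = [], []
        for i in range(len(xy)):
            for j in range(i + 1, len(xy)):
                d = np.linalg.norm(xy[i] - xy[j])
                (within if cond[i] == cond[j] else between).append(d)
        pairs_ok = sum(w < b for w in within for b in between)
        assert pairs_ok / (len(within) * len(between)) >= 0.9

    def test_duplicated_sample_identical_coordinates(self, genome):
        cfg = rg.SimConfig(seed=33, planted_lfc={"KO": {}})
        design = rg.default_design(cfg, ["2iLIF_WT", "KO"])
        cm, _ = rg.simulate_counts(genome, design, cfg)
        dup = cm.counts.copy()
        dup["copy_of_s0"] = dup.iloc[:, 0]
        design2 = pd.concat(
            [cm.design, cm.design.iloc[[0]].rename(index={cm.design.index[0]: "copy_of_s0"})]
        )
        cm2 = CountMatrix(dup, design2, cm.gene_lengths)
        coords, _ = rg.pca_embed(cm2, 100)
        np.testing.assert_allclose(
            coords.iloc[0].to_numpy(), coords.loc["copy_of_s0"].to_numpy(), atol=1e-8
        )

    def test_variance_explained_is_valid_spectrum(self, genome):
        cfg = rg.SimConfig(seed=34, planted_lfc={"KO": {}})
        design = rg.default_design(cfg, ["2iLIF_WT", "KO"])
        cm, _ = rg.simulate_counts(genome, design, cfg)
        _, explained = rg.pca_embed(cm, 100)
        assert explained.sum() <= 1.0 + 1e-9
        assert (np.diff(explained) <= 1e-12).all()


class TestDeltaCt:
    def test_gene_at_housekeeping_mean_is_zero(self):
        ct = pd.DataFrame(
            {"cell1": [18.0, 18.0, 18.0, 18.0]},
            index=["Atp5a1", "Ppia", "Gapdh", "Nanog"],
        )
        norm = rg.delta_ct_normalize(CtMatrix(ct=ct))
        assert norm.loc["Nanog", "cell1"] == pytest.approx(0.0)

    def test_three_cycles_earlier_is_plus_three(self):
        ct = pd.DataFrame(
            {"cell1": [18.0, 18.0, 18.0, 15.0]},
            index=["Atp5a1", "Ppia", "Gapdh", "Nanog"],
        )
        norm = rg.delta_ct_normalize(CtMatrix(ct=ct))
        assert norm.loc["Nanog", "cell1"] == pytest.approx(3.0)

    def test_missing_ct_stays_missing(self):
        ct = pd.DataFrame(
            {"cell1": [18.0, 18.0, 18.0, np.nan]},
            index=["Atp5a1", "Ppia", "Gapdh", "Nanog"],
        )
        norm = rg.delta_ct_normalize(CtMatrix(ct=ct))
        assert np.isnan(norm.loc["Nanog", "cell1"])

    def test_no_housekeeping_rejected(self):
        ct = pd.DataFrame({"cell1": [20.0]}, index=["Nanog"])
        with pytest.raises(ExpressionError):
            rg.delta_ct_normalize(CtMatrix(ct=ct, housekeeping=("Gapdh",)))


class TestHcluster:
    def test_two_populations_form_contiguous_blocks(self):
        cfg = rg.SimConfig(seed=35, ct_separation=6.0)
        ct, labels = rg.simulate_ct(cfg)
        norm = rg.delta_ct_normalize(ct)
        _, cell_order = rg.hcluster_genes_cells(norm)
        ordered = labels.loc[cell_order].to_numpy()
        # longest run of each label; blocks recovered for >= 90% of cells
        best = {}
        for lab in ("A", "B"):
            runs, cur = [], 0
            for v in ordered:
                cur = cur + 1 if v == lab else 0
                runs.append(cur)
            best[lab] = max(runs)
        frac = (best["A"] + best["B"]) / len(ordered)
        assert frac >= 0.9

    def test_identical_rows_adjacent(self):
        rng = np.random.default_rng(5)
        x = pd.DataFrame(rng.normal(size=(6, 20)))
        x.iloc[5] = x.iloc[0]
        x.index = [f"r{i}" for i in range(6)]
        order, _ = rg.hcluster_genes_cells(x)
        assert abs(order.index("r0") - order.index("r5")) == 1


class TestRelativeExpression:
    def test_ddct_zero_gives_fold_one(self):
        assert rg.relative_expression(20, 18, 22, 20) == pytest.approx(1.0)

    def test_two_cycles_earlier_gives_fold_four(self):
        assert rg.relative_expression(18, 18, 20, 18) == pytest.approx(4.0)

    def test_missing_in_gives_nan_out(self):
        assert np.isnan(rg.relative_expression(np.nan, 18, 20, 18))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_formula_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ct_t, hk_t, ct_c, hk_c = rng.uniform(10, 30, size=4)
        want = 2.0 ** -((ct_t - hk_t) - (ct_c - hk_c))
        assert rg.relative_expression(ct_t, hk_t, ct_c, hk_c) == pytest.approx(want)
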