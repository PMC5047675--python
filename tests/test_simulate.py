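"""The synthetic-data generators: determinism, planted truth, limits."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import regulomics as rg
from regulomics.simulate import ConfigError, simulate_score_pairs


class TestMakeGenome:
    def test_cardinality_matches_config(self, genome, sim_config):
        assert len(genome) == sim_config.n_genes
        assert genome.genes["tss"].notna().all()
        assert len(genome.enhancers) == sim_config.n_enhancers

    def test_same_seed_identical(self, sim_config, genome):
        again = rg.make_genome(rg.SimConfig(seed=sim_config.seed))
        pd.testing.assert_frame_equal(genome.genes, again.genes)
        pd.testing.assert_frame_equal(genome.enhancers, again.enhancers)

    def test_genes_do_not_overlap(self, genome):
        for _, grp in genome.genes.groupby("chrom"):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()

    def test_capacity_error(self):
        with pytest.raises(ConfigError):
            rg.make_genome(rg.SimConfig(seed=0, n_genes=10_000, chrom_length=100_000))

    def test_tss_strand_convention(self, genome):
        g = genome.genes
        plus = g[g["strand"] == "+"]
        minus = g[g["strand"] == "-"]
        assert (plus["tss"] == plus["start"]).all()
        assert (minus["tss"] == minus["end"] - 1).all()


class TestPeakReplicates:
    def test_pi1_one_every_peak_pairs(self, genome):
        cfg = rg.SimConfig(seed=1, pi1=1.0)
        peaks, _ = rg.simulate_peak_replicates(genome, cfg)
        r1, r2 = peaks["Sall4"]
        assert rg.overlap_any(r1, r2).all()
        assert rg.overlap_any(r2, r1).all()

    def test_latent_reproducible_fraction_within_binomial_ci(self, genome):
        cfg = rg.SimConfig(seed=3, pi1=0.7)
        _, truth = rg.simulate_peak_replicates(genome, cfg)
        all_truth = pd.concat(truth.values())
        n = len(all_truth)
        k = int(all_truth["reproducible"].sum())
        lo, hi = stats.binom.interval(0.99, n, 0.7)
        assert lo <= k <= hi

    def test_full_cooccupancy_forces_identical_loci(self, genome):
        cfg = rg.SimConfig(seed=2, factors=("A", "B"), cooccupancy=(1.0, 1.0))
        _, truth = rg.simulate_peak_replicates(genome, cfg)
        loci_a = set(zip(truth["A"]["chrom"], truth["A"]["centre"]))
        loci_b = set(zip(truth["B"]["chrom"], truth["B"]["centre"]))
        assert loci_a == loci_b

    def test_determinism(self, genome, sim_config, peak_replicates):
        peaks, truth = peak_replicates
        peaks2, truth2 = rg.simulate_peak_replicates(genome, rg.SimConfig(seed=sim_config.seed))
        for f in peaks:
            pd.testing.assert_frame_equal(peaks[f][0].intervals, peaks2[f][0].intervals)
            pd.testing.assert_frame_equal(truth[f], truth2[f])

    def test_empty_factor_list_rejected(self, genome):
        with pytest.raises(ConfigError):
            rg.simulate_peak_replicates(
                genome, rg.SimConfig(seed=0, factors=(), cooccupancy=())
            )


class TestScorePairs:
    def test_latent_fraction_and_determinism(self):
        pairs, rep = simulate_score_pairs(0.7, 2000, seed=3)
        lo, hi = stats.binom.interval(0.99, 2000, 0.7)
        assert lo <= rep.sum() <= hi
        pairs2, rep2 = simulate_score_pairs(0.7, 2000, seed=3)
        pd.testing.assert_frame_equal(pairs, pairs2)
        assert np.array_equal(rep, rep2)


class TestSignal:
    def test_zero_multiplier_gives_pure_background(self, genome):
        cfg = rg.SimConfig(seed=4, mark_enrichment={"H3K4me3": 0.0})
        tracks = rg.simulate_signal(genome, None, cfg)
        t = tracks["H3K4me3"]
        vals = np.concatenate(list(t.values.values()))
        se = np.sqrt(cfg.background_rate / len(vals))
        assert abs(vals.mean() - cfg.background_rate) < 3 * se

    def test_promoter_k4me3_beats_background(self, genome, mark_tracks, sim_config):
        t = mark_tracks["H3K4me3"]
        g = genome.genes.iloc[0]
        prom = t.window_mean(g["chrom"], g["tss"] - 500, g["tss"] + 500)
        bg_windows = [
            t.window_mean("chr1", s, s + 1000) for s in (501_000, 761_000, 981_000)
        ]
        assert prom > max(bg_windows)

    def test_unknown_mark_rejected(self, genome):
        cfg = rg.SimConfig(seed=0, mark_enrichment={"H3K9me3": 2.0})
        with pytest.raises(ConfigError):
            rg.simulate_signal(genome, None, cfg)

    def test_determinism(self, genome, sim_config, mark_tracks):
        again = rg.simulate_signal(genome, None, rg.SimConfig(seed=sim_config.seed))
        for mark, t in mark_tracks.items():
            for chrom in t.chroms():
                np.testing.assert_array_equal(t.values[chrom], again[mark].values[chrom])


class TestCounts:
    def test_null_config_has_no_planted_effects(self, genome):
        cfg = rg.SimConfig(seed=5, planted_lfc={"KO": {}})
        design = rg.default_design(cfg, ["2iLIF_WT", "KO"])
        _, truth = rg.simulate_counts(genome, design, cfg)
        assert (truth["KO"] == 0).all()

    def test_planted_lfc_recovered_empirically(self, genome):
        planted = {f"gene{i:04d}": 2.0 for i in range(50)}
        cfg = rg.SimConfig(
            seed=6, planted_lfc={"KO": planted}, base_mean_log=5.5, base_mean_sd=0.5
        )
        design = rg.default_design(cfg, ["2iLIF_WT", "KO"], n_rep=4)
        cm, truth = rg.simulate_counts(genome, design, cfg)
        sf = rg.size_factors(cm.counts)
        norm = cm.counts / sf
        wt = [s for s in design.index if "WT" in s]
        ko = [s for s in design.index if "KO" in s]
        sel = [g for g in planted if truth.loc[g, "base_mean"] >= 100]
        ratios = np.log2(norm.loc[sel, ko].mean(axis=1) / norm.loc[sel, wt].mean(axis=1))
        assert abs(ratios.mean() - 2.0) < 0.5

    def test_poisson_limit_variance_over_mean_near_one(self, genome):
        cfg = rg.SimConfig(seed=7, nb_dispersion=0.0, libsize_cv=0.0, planted_lfc={"KO": {}},
                           base_mean_log=6.0, base_mean_sd=0.1)
        design = rg.default_design(cfg, ["2iLIF_WT", "KO"], n_rep=10)
        cm, _ = rg.simulate_counts(genome, design, cfg)
        vmr = (cm.counts.var(axis=1) / cm.counts.mean(axis=1)).mean()
        assert 0.7 < vmr < 1.3

    def test_missing_condition_in_planted_lfc_rejected(self, genome):
        cfg = rg.SimConfig(seed=0)
        design = rg.default_design(cfg, ["2iLIF_WT", "mystery"])
        with pytest.raises(ConfigError):
            rg.simulate_counts(genome, design, cfg)


class TestLfq:
    def test_noiseless_ratios_equal_copies(self):
        cfg = rg.SimConfig(seed=8, noise_cv=0.0, censor_quantile=0.0,
                           n_background_proteins=0, bait_excess=1.0)
        table, truth = rg.simulate_lfq(cfg)
        st = rg.stoichiometry(table, list(cfg.complex_spec), list(cfg.anchors), cfg.bait)
        for p, copies in cfg.complex_spec.items():
            if p == cfg.bait:
                continue
            assert st.table.loc[p, "ratio_to_anchor"] == pytest.approx(copies)

    def test_bait_excess_recovered_with_noise(self):
        vals = []
        for seed in range(10):
            cfg = rg.SimConfig(seed=seed, bait_excess=14.0, noise_cv=0.2)
            table, _ = rg.simulate_lfq(cfg)
            st = rg.stoichiometry(table, list(cfg.complex_spec), list(cfg.anchors), cfg.bait)
            vals.append(st.s_bait)
        assert abs(np.mean(vals) - 14.0) / 14.0 < 0.2

    def test_no_missing_in_top_quartile(self):
        cfg = rg.SimConfig(seed=11)
        table, _ = rg.simulate_lfq(cfg)
        for run in table.intensities.columns:
            col = table.intensities[run]
            ranks = col.rank(pct=True)
            assert col[ranks > 0.75].notna().all()

    def test_s_below_one_rejected(self):
        with pytest.raises(ConfigError):
            rg.SimConfig(seed=0, bait_excess=0.5)


class TestCt:
    def test_no_dropout_no_missing(self):
        cfg = rg.SimConfig(seed=9, dropout_p=0.0)
        ct, _ = rg.simulate_ct(cfg)
        assert ct.ct.notna().all().all()

    def test_two_populations_recovered_by_kmeans(self):
        from sklearn.cluster import KMeans

        cfg = rg.SimConfig(seed=10, ct_separation=6.0)
        ct, labels = rg.simulate_ct(cfg)
        norm = rg.delta_ct_normalize(ct)
        x = norm.T.fillna(norm.T.mean()).to_numpy()
        km = KMeans(2, n_init=10, random_state=0).fit(x)
        truth = (labels == "B").to_numpy().astype(int)
        acc = max((km.labels_ == truth).mean(), (km.labels_ != truth).mean())
        assert acc >= 0.95

    def test_determinism(self):
        a, la = rg.simulate_ct(rg.SimConfig(seed=12))
        b, lb = rg.simulate_ct(rg.SimConfig(seed=12))
        pd.testing.assert_frame_equal(a.ct, b.ct)
        assert (la == lb).all()

    def test_bad_dropout_rejected(self):
        with pytest.raises(ConfigError):
            rg.SimConfig(seed=0, dropout_p=1.5)
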