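import numpy as np
import pandas as pd
import pytest

import triage as tg
from triage.errors import ValidationError


class TestPca:
    def test_rank_one_fixture(self, rng):
        pattern = rng.uniform(1, 10, 8)
        scale = rng.uniform(0.1, 5, 60)
        breadth = pd.DataFrame(np.outer(scale, pattern),
                               index=[f"g{i:02d}" for i in range(60)])
        pc = tg.fit_h3k27me3_pca(breadth, n_pcs=3)
        assert pc.explained_variance_ratio[0] > 0.999

    def test_duplicate_samples_have_identical_loadings(self, rng):
        base = rng.uniform(0, 100, size=(50, 4))
        breadth = pd.DataFrame(np.column_stack([base, base[:, 0]]),
                               index=[f"g{i:02d}" for i in range(50)],
                               columns=list("abcde"))
        pc = tg.fit_h3k27me3_pca(breadth, n_pcs=3)
        assert np.allclose(np.abs(pc.loadings.loc["a"]),
                           np.abs(pc.loadings.loc["e"]), atol=1e-8)

    def test_planted_programs_recovered(self, program_breadth):
        breadth, programs, _ = program_breadth
        pc = tg.fit_h3k27me3_pca(breadth, n_pcs=5)
        # program genes separate along the top PCs: their scores must be
        # far from the background along at least one of PC1/PC2
        prog_genes = programs.index
        bg = pc.scores.drop(index=prog_genes)
        for p in range(3):
            gs = pc.scores.loc[programs.index[programs == p], ["PC1", "PC2"]]
            dist = np.linalg.norm(gs.mean() - bg[["PC1", "PC2"]].mean())
            assert dist > 10 * bg[["PC1", "PC2"]].std().max()

    def test_variance_ratios_non_increasing(self, breadth):
        pc = tg.fit_h3k27me3_pca(breadth, n_pcs=10)
        assert (np.diff(pc.explained_variance_ratio) <= 1e-12).all()
        assert pc.explained_variance_ratio.sum() <= 1 + 1e-9

    def test_reconstruction_from_scores_and_loadings(self, rng):
        breadth = pd.DataFrame(rng.uniform(0, 1000, size=(40, 6)),
                               index=[f"g{i:02d}" for i in range(40)])
        pc = tg.fit_h3k27me3_pca(breadth, n_pcs=6)
        recon = pc.scores.values @ pc.loadings.values.T + pc.mean_
        assert np.allclose(recon, breadth.values, atol=1e-6)

    def test_n_pcs_beyond_rank_rejected(self, rng):
        breadth = pd.DataFrame(rng.uniform(0, 1, size=(10, 4)))
        with pytest.raises(ValidationError):
            tg.fit_h3k27me3_pca(breadth, n_pcs=5)


class TestEnrichment:
    def test_p_value_formula_extremes(self, rng):
        # a gene far above every null statistic -> r = 0 -> p = 1/(n+1);
        # a gene below every null -> r = n -> p = 1
        scores = pd.DataFrame(rng.normal(0, 1, size=(500, 2)),
                              index=[f"g{i:03d}" for i in range(500)],
                              columns=["PC1", "PC2"])
        scores.loc["g000"] = [100.0, -100.0]
        pc = tg.parse.PCModel(scores=scores, loadings=None,
                              explained_variance_ratio=np.array([.5, .5]),
                              mean_=np.zeros(2))
        res = tg.pattern_enrichment(pc, ["g000"], n_perm=200, seed=1)
        assert res.p.loc["g000", "PC1"] == pytest.approx(1 / 201)
        assert res.p.loc["g000", "PC2"] == pytest.approx(1.0)
        assert bool(res.strong.loc["g000", "PC1"])
        assert not bool(res.strong.loc["g000", "PC2"])

    def test_p_bounds_and_determinism(self, program_breadth):
        breadth, _, gene_list = program_breadth
        pc = tg.fit_h3k27me3_pca(breadth, n_pcs=5)
        r1 = tg.pattern_enrichment(pc, gene_list[:20], n_perm=100, seed=3)
        r2 = tg.pattern_enrichment(pc, gene_list[:20], n_perm=100, seed=3)
        assert r1.p.equals(r2.p)
        assert (r1.p.values >= 1 / 101 - 1e-12).all()
        assert (r1.p.values <= 1.0).all()

    def test_unknown_gene_rejected(self, program_breadth):
        breadth, _, _ = program_breadth
        pc = tg.fit_h3k27me3_pca(breadth, n_pcs=3)
        with pytest.raises(ValidationError, match="ghost"):
            tg.pattern_enrichment(pc, ["ghost"], n_perm=10, seed=0)


class TestPcSelection:
    def test_planted_spread_pc_ranked_first(self, rng):
        scores = pd.DataFrame(rng.normal(0, 1, size=(200, 5)),
                              index=[f"g{i:03d}" for i in range(200)],
                              columns=[f"PC{i+1}" for i in range(5)])
        gene_set = [f"g{i:03d}" for i in range(30)]
        scores.loc[gene_set, "PC3"] *= 20
        pc = tg.parse.PCModel(scores=scores, loadings=None,
                              explained_variance_ratio=np.full(5, .2),
                              mean_=np.zeros(5))
        sel = tg.rank_pcs_by_gene_set_variance(pc, gene_set, m=2)
        assert sel[0] == "PC3"

    def test_m_equal_all_is_identity_by_variance(self, program_breadth):
        breadth, _, gene_list = program_breadth
        pc = tg.fit_h3k27me3_pca(breadth, n_pcs=4)
        sel = tg.rank_pcs_by_gene_set_variance(pc, gene_list, m=4)
        assert set(sel) == {"PC1", "PC2", "PC3", "PC4"}

    def test_tiny_gene_set_rejected(self, program_breadth):
        breadth, _, _ = program_breadth
        pc = tg.fit_h3k27me3_pca(breadth, n_pcs=3)
        with pytest.raises(ValidationError):
            tg.rank_pcs_by_gene_set_variance(pc, ["g0000"], m=2)


class TestBicScan:
    def test_three_planted_clusters(self):
        feats, _, _ = tg.simulate_pc_clusters(n_clusters=3, seed=0)
        scan = tg.scan_cluster_number(feats)
        assert scan.theta_star == 3

    def test_single_gaussian(self):
        feats, _, _ = tg.simulate_pc_clusters(n_clusters=1, seed=0)
        assert tg.scan_cluster_number(feats).theta_star == 1

    def test_theta_max_one(self):
        feats, _, _ = tg.simulate_pc_clusters(n_clusters=1, seed=0)
        scan = tg.scan_cluster_number(feats, theta_max=1, repeats=2)
        assert scan.theta_star == 1

    def test_theta_max_above_n_rejected(self):
        feats, _, _ = tg.simulate_pc_clusters(n_genes=20, n_clusters=1,
                                              seed=0)
        with pytest.raises(ValidationError):
            tg.scan_cluster_number(feats, theta_max=50)

    def test_deterministic_for_seed(self):
        feats, _, _ = tg.simulate_pc_clusters(n_clusters=3, seed=1)
        s1 = tg.scan_cluster_number(feats, theta_max=10, repeats=3, seed=7)
        s2 = tg.scan_cluster_number(feats, theta_max=10, repeats=3, seed=7)
        assert s1.theta_star == s2.theta_star
        assert s1.theta_per_repeat == s2.theta_per_repeat
        pd.testing.assert_frame_equal(s1.bic, s2.bic)


class TestAssignment:
    def test_single_cluster_posterior_one(self):
        feats, _, _ = tg.simulate_pc_clusters(n_clusters=1, seed=0)
        gm = tg.assign_gene_clusters(feats, 1)
        assert (gm.posteriors.values == 1.0).all()
        assert (gm.assignments == 0).all()

    def test_three_cluster_recovery(self):
        feats, labels, _ = tg.simulate_pc_clusters(n_clusters=3, seed=0)
        gm = tg.assign_gene_clusters(feats, 3)
        assert tg.adjusted_rand_index(gm.assignments, labels) > 0.9

    def test_posterior_rows_sum_to_one(self):
        feats, _, _ = tg.simulate_pc_clusters(n_clusters=3, seed=2)
        gm = tg.assign_gene_clusters(feats, 3)
        assert np.allclose(gm.posteriors.sum(axis=1), 1.0, atol=1e-9)
        assert gm.weights.sum() == pytest.approx(1.0)

    def test_duplicate_rows_identical_posteriors(self):
        feats, _, _ = tg.simulate_pc_clusters(n_clusters=3, seed=0)
        feats.iloc[1] = feats.iloc[0]
        gm = tg.assign_gene_clusters(feats, 3)
        assert np.allclose(gm.posteriors.iloc[0], gm.posteriors.iloc[1])


class TestEndToEnd:
    def test_program_recovery(self, program_breadth):
        breadth, programs, gene_list = program_breadth
        res = tg.TriageParse(gene_list, breadth=breadth, n_pcs=20).fit(
            run_enrichment=False)
        assert res.theta_star == 3
        ct = pd.crosstab(res.assignments, programs.loc[res.assignments.index])
        purity = ct.max(axis=1).sum() / ct.values.sum()
        assert purity > 0.9

    def test_bitwise_determinism(self, program_breadth):
        breadth, _, gene_list = program_breadth
        kw = dict(breadth=breadth, n_pcs=10, theta_max=20, repeats=3,
                  n_perm=50)
        r1 = tg.TriageParse(gene_list, **kw).fit()
        r2 = tg.TriageParse(gene_list, **kw).fit()
        assert r1.theta_star == r2.theta_star
        assert r1.assignments.equals(r2.assignments)
        assert r1.enrichment.p.equals(r2.enrichment.p)
        assert r1.gmm.posteriors.equals(r2.gmm.posteriors)
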