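import numpy as np
import pandas as pd
import pytest
from sklearn.neighbors import KernelDensity

import triage as tg
from triage.cluster import Peak, jaccard_similarity, peak_dendrogram
from triage.errors import ValidationError
from triage.rts import PriorityGeneSet


def _priority(d):
    genes = sorted(d, key=lambda g: (-d[g], g))
    return PriorityGeneSet(genes=genes, rts=pd.Series(d).loc[genes],
                           threshold=0.0, method="fixed")


class TestCellWeights:
    def test_max_expression_wins(self):
        pri = _priority({"A": 0.3, "B": 0.9})
        expr = pd.DataFrame({"c": [5.0, 2.0]}, index=["A", "B"])
        w = tg.assign_cell_weights(expr, pri)
        assert w.loc["c", "weight"] == 0.3
        assert w.loc["c", "anchor_candidate"] == "A"

    def test_expression_tie_broken_by_rts(self):
        pri = _priority({"A": 0.3, "B": 0.9})
        expr = pd.DataFrame({"c": [5.0, 5.0]}, index=["A", "B"])
        w = tg.assign_cell_weights(expr, pri)
        assert w.loc["c", "weight"] == 0.9

    def test_no_priority_expression_weight_zero(self):
        pri = _priority({"A": 0.3})
        expr = pd.DataFrame({"c": [0.0]}, index=["A"])
        w = tg.assign_cell_weights(expr, pri)
        assert w.loc["c", "weight"] == 0.0
        assert w.loc["c", "anchor_candidate"] is None

    def test_empty_priority_rejected(self):
        expr = pd.DataFrame({"c": [1.0]}, index=["A"])
        with pytest.raises(ValidationError):
            tg.assign_cell_weights(expr, PriorityGeneSet(
                genes=[], rts=pd.Series(dtype=float), threshold=0,
                method="fixed"))


class TestBandwidth:
    def test_closed_form_values(self):
        assert tg.kde_bandwidth(1, 2) == pytest.approx(0.3)
        assert tg.kde_bandwidth(64, 2) == pytest.approx(0.15)
        assert tg.kde_bandwidth(116312, 2) == pytest.approx(0.0429, abs=5e-4)

    def test_invalid_n(self):
        with pytest.raises(ValidationError):
            tg.kde_bandwidth(0)


def _emb(coords):
    return pd.DataFrame(coords, columns=["x", "y"],
                        index=[f"c{i}" for i in range(len(coords))])


class TestWeightedKde:
    def test_single_cell_closed_form(self):
        emb = _emb([[0.0, 0.0]])
        dm = tg.weighted_kde(emb, np.array([0.7]), h=0.5)
        assert dm.cell_density[0] == pytest.approx(1 / (2 * np.pi * 0.25))

    def test_mirror_symmetry(self):
        emb = _emb([[-1.0, 0.0], [1.0, 0.0]])
        dm = tg.weighted_kde(emb, np.array([0.4, 0.4]), h=0.7)
        grid = np.array([[0.3, 0.2], [-0.3, 0.2]])
        d = dm.evaluate(grid)
        assert d[0] == pytest.approx(d[1])

    def test_integrates_to_one(self, rng):
        pts = rng.normal(0, 1, size=(150, 2))
        w = rng.uniform(0.1, 1, 150)
        dm = tg.weighted_kde(_emb(pts), w, h=0.4)
        g = np.linspace(-7, 7, 301)
        xx, yy = np.meshgrid(g, g)
        z = dm.evaluate(np.column_stack([xx.ravel(), yy.ravel()]))
        integral = z.sum() * (g[1] - g[0]) ** 2
        assert integral == pytest.approx(1.0, abs=0.01)

    def test_equal_weights_match_unweighted_oracle(self, rng):
        pts = rng.normal(0, 1, size=(80, 2))
        h = 0.35
        dm = tg.weighted_kde(_emb(pts), np.full(80, 0.42), h=h)
        oracle = KernelDensity(bandwidth=h, kernel="gaussian").fit(pts)
        expected = np.exp(oracle.score_samples(pts))
        assert np.allclose(dm.cell_density, expected, atol=1e-9)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValidationError, match="no priority signal"):
            tg.weighted_kde(_emb([[0, 0], [1, 1]]), np.zeros(2), h=0.3)


def _blobs(rng, centres, n_per, sd=0.4):
    pts = np.vstack([c + rng.normal(0, sd, size=(n_per, 2))
                     for c in centres])
    return _emb(pts)


class TestSuperlevel:
    def test_threshold_nesting_exact(self, rng):
        emb = _blobs(rng, [(0, 0), (6, 0)], 150)
        dm = tg.weighted_kde(emb, np.ones(300), h=0.3)
        lv = tg.superlevel_clusters(dm, emb)
        assert (np.diff(lv.thresholds) > 0).all()
        for k in range(len(lv.labels) - 1):
            upper = set(np.flatnonzero(lv.labels[k + 1] > -2))
            lower = set(np.flatnonzero(lv.labels[k] > -2))
            assert upper <= lower

    def test_two_separated_blobs_two_clusters_low_level(self, rng):
        emb = _blobs(rng, [(0, 0), (8, 0)], 100)
        dm = tg.weighted_kde(emb, np.ones(200), h=0.3)
        lv = tg.superlevel_clusters(dm, emb)
        labs = lv.labels[1]
        assert len(set(labs[labs >= 0])) == 2

    def test_density_rescaling_leaves_peaks_unchanged(self, rng):
        emb = _blobs(rng, [(0, 0), (8, 0)], 120)
        w = rng.uniform(0.2, 0.8, 240)
        dm1 = tg.weighted_kde(emb, w, h=0.3)
        dm2 = tg.weighted_kde(emb, w * 7.3, h=0.3)  # normalised: identical
        p1 = tg.select_peaks(tg.superlevel_clusters(dm1, emb), emb)
        p2 = tg.select_peaks(tg.superlevel_clusters(dm2, emb), emb)
        pd.testing.assert_series_equal(p1.membership, p2.membership)

    def test_min_levels_validated(self, rng):
        emb = _blobs(rng, [(0, 0)], 30)
        dm = tg.weighted_kde(emb, np.ones(30), h=0.3)
        with pytest.raises(ValidationError):
            tg.superlevel_clusters(dm, emb, n_levels=1)


class TestSelectPeaks:
    def test_single_blob_single_peak_contains_mode(self, rng):
        emb = _blobs(rng, [(0, 0)], 500)
        dm = tg.weighted_kde(emb, np.ones(500), h=0.3)
        peaks = tg.select_peaks(tg.superlevel_clusters(dm, emb), emb)
        assert len(peaks) == 1
        densest = emb.index[int(np.argmax(dm.cell_density))]
        assert densest in set(peaks.membership.index)

    def test_two_blobs_recovered_with_high_ari(self, rng):
        emb = _blobs(rng, [(0, 0), (8, 0)], 250)
        truth = pd.Series(["a"] * 250 + ["b"] * 250, index=emb.index)
        dm = tg.weighted_kde(emb, np.ones(500), h=0.3)
        peaks = tg.select_peaks(tg.superlevel_clusters(dm, emb), emb)
        assert len(peaks) == 2
        mem = peaks.membership
        assert tg.adjusted_rand_index(truth.loc[mem.index], mem) > 0.95

    def test_small_cluster_excluded(self, rng):
        emb = _blobs(rng, [(0, 0)], 300)
        extra = _emb(np.vstack([emb.values,
                                (50, 50) + rng.normal(0, 0.1, (8, 2))]))
        dm = tg.weighted_kde(extra, np.ones(308), h=0.3)
        peaks = tg.select_peaks(tg.superlevel_clusters(dm, extra), extra,
                                min_cells=20)
        assert len(peaks) == 1          # 8-cell blob below the floor

    def test_no_qualifying_cluster_errors(self, rng):
        emb = _blobs(rng, [(0, 0)], 30)
        dm = tg.weighted_kde(emb, np.ones(30), h=0.3)
        with pytest.raises(ValidationError, match="no peaks"):
            tg.select_peaks(tg.superlevel_clusters(dm, emb), emb,
                            min_cells=1000)

    def test_unweighted_modes_match_equal_weight_peaks(self, rng):
        # with equal weights the peak locations coincide with the plain
        # density modes of the embedding
        centres = [(0, 0), (7, 0), (0, 7)]
        emb = _blobs(rng, centres, 150)
        dm = tg.weighted_kde(emb, np.ones(450), h=0.3)
        peaks = tg.select_peaks(tg.superlevel_clusters(dm, emb), emb)
        assert len(peaks) == 3
        cent = np.array([p.centroid for p in peaks.peaks])
        for c in centres:
            assert np.min(np.linalg.norm(cent - np.array(c), axis=1)) < 0.5


class TestAnchors:
    def test_highest_mean_priority_gene(self):
        pri = _priority({"A": 0.2, "B": 0.4})
        expr = pd.DataFrame({"c0": [1.0, 3.0], "c1": [2.0, 4.0]},
                            index=["A", "B"])
        peak = Peak("p0", 1, ["c0", "c1"], (0, 0))
        assert tg.anchor_gene(peak, expr, pri) == "B"

    def test_mean_tie_broken_by_rts(self):
        pri = _priority({"A": 0.2, "B": 0.4})
        expr = pd.DataFrame({"c0": [3.0, 3.0]}, index=["A", "B"])
        peak = Peak("p0", 1, ["c0"], (0, 0))
        assert tg.anchor_gene(peak, expr, pri) == "B"

    def test_no_expression_returns_none(self, caplog):
        pri = _priority({"A": 0.2})
        expr = pd.DataFrame({"c0": [0.0]}, index=["A"])
        peak = Peak("p0", 1, ["c0"], (0, 0))
        with caplog.at_level("WARNING", logger="triage"):
            assert tg.anchor_gene(peak, expr, pri) is None

    def test_peak_anchors_are_planted_markers(self, cluster_results, atlas):
        anchors = set(cluster_results.peak_table()["anchor_gene"])
        markers = {g for gl in atlas["markers"].values() for g in gl}
        assert anchors <= markers


class TestJaccardDendrogram:
    def test_identical_disjoint_half(self):
        a = [f"g{i}" for i in range(100)]
        b = [f"h{i}" for i in range(100)]
        half = a[:50] + b[:50]
        sim = jaccard_similarity({"p": a, "q": a, "r": b, "s": half})
        assert sim.loc["p", "q"] == 1.0
        assert sim.loc["p", "r"] == 0.0
        assert sim.loc["p", "s"] == pytest.approx(1 / 3)

    def test_first_merge_joins_identical_pair(self):
        a = [f"g{i}" for i in range(100)]
        b = [f"h{i}" for i in range(100)]
        sim = jaccard_similarity({"p": a, "q": a, "r": b})
        dend = peak_dendrogram(sim)
        first = dend.linkage[0]
        assert {int(first[0]), int(first[1])} == {0, 1}
        assert first[2] == pytest.approx(0.0)

    def test_block_structure_top_split(self):
        fam1 = [f"g{i}" for i in range(100)]
        fam2 = [f"h{i}" for i in range(100)]
        lists = {"a1": fam1, "a2": fam1[:90] + fam2[:10],
                 "b1": fam2, "b2": fam2[:90] + fam1[:10]}
        dend = peak_dendrogram(jaccard_similarity(lists))
        order = dend.leaf_order
        side = {pid: order.index(pid) < 2 for pid in lists}
        assert side["a1"] == side["a2"] and side["b1"] == side["b2"]
        assert side["a1"] != side["b1"]

    def test_newick_contains_all_leaves(self):
        a = [f"g{i}" for i in range(10)]
        sim = jaccard_similarity({"p": a, "q": a[:5], "r": a[5:]})
        nwk = peak_dendrogram(sim).to_newick()
        assert nwk.endswith(";") and all(x in nwk for x in ("p", "q", "r"))

    def test_nan_similarity_rejected(self):
        sim = pd.DataFrame([[1.0, np.nan], [np.nan, 1.0]],
                           index=["p", "q"], columns=["p", "q"])
        with pytest.raises(ValidationError):
            peak_dendrogram(sim)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            jaccard_similarity({"p": [], "q": ["g1"]})
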