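"""Graph construction, embedding, Leiden clustering and phase annotation."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import igraph as ig
from cyclemap.mapping import (
    CellCycleMapper,
    annotate_phases,
    build_knn_graph,
    embed_2d,
    leiden_cluster,
    phase_marker_summary,
    scan_resolution,
)
from cyclemap.synthetic import MARKERS


def _table_from_matrix(X: np.ndarray) -> pd.DataFrame:
    cols = {m: X[:, i % X.shape[1]] for i, m in enumerate(MARKERS)}
    tab = pd.DataFrame(cols)
    tab.insert(0, "sample_id", "s")
    return tab


def _blobs(n_per=60, gap=50.0, seed=0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, (n_per, 3))
    b = rng.normal(gap, 1, (n_per, 3))
    return _table_from_matrix(np.vstack([a, b]))


class TestKnnGraph:
    def test_equidistant_triangle_all_connected(self):
        X = np.array([[0.0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        g = build_knn_graph(_table_from_matrix(X), k=1)
        assert g.vcount() == 3
        assert min(g.degree()) >= 1  # union symmetrization keeps everyone linked

    def test_duplicated_cells_are_first_neighbors(self):
        X = np.array([[0.0, 0], [0.0, 0], [5.0, 5], [9.0, 9]])
        g = build_knn_graph(_table_from_matrix(X), k=1)
        assert g.are_adjacent(0, 1)

    def test_two_blobs_disconnect_for_small_k(self):
        g = build_knn_graph(_blobs(), k=5)
        comps = g.connected_components()
        assert len(comps) == 2
        assert sorted(map(len, comps)) == [60, 60]

    def test_bad_k_rejected(self):
        tab = _blobs()
        with pytest.raises(ValueError):
            build_knn_graph(tab, k=0)
        with pytest.raises(ValueError):
            build_knn_graph(tab, k=len(tab))


class TestEmbedding:
    def test_shape_and_determinism(self, small_gated):
        kept, _, _ = small_gated
        a = embed_2d(kept, seed=3)
        b = embed_2d(kept, seed=3)
        assert a.shape == (len(kept), 2)
        np.testing.assert_array_equal(a, b)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            embed_2d(_blobs(n_per=5), n_neighbors=30)

    def test_trajectory_adjacency_preserved(self, small_gated):
        """Adjacent planted phases must sit closer on the map than
        non-adjacent ones; the endocycle branch leaves the cycle at G2."""
        kept, _, _ = small_gated
        emb = embed_2d(kept, seed=0)
        truth = kept["true_phase"].to_numpy()
        phases = ("G1", "S", "G2", "M", "endocycle")
        cent = {p: emb[truth == p].mean(axis=0) for p in phases}

        def d(a, b):
            return float(np.linalg.norm(cent[a] - cent[b]))

        # the endocycle branch leaves the cycle from G2, not from S
        assert d("endocycle", "G2") < d("endocycle", "S")
        # mean distance of adjacent phase pairs (cycle order plus the G2
        # branch point) is below the mean over non-adjacent pairs
        adjacent = {("G1", "S"), ("S", "G2"), ("G2", "M"), ("M", "G1"),
                    ("G2", "endocycle")}
        adj, non = [], []
        for i, a in enumerate(phases):
            for b in phases[i + 1:]:
                pair = d(a, b)
                ((adj if (a, b) in adjacent or (b, a) in adjacent else non)
                 .append(pair))
        assert np.mean(adj) < np.mean(non)


class TestLeiden:
    def test_two_cliques_two_clusters(self):
        g = ig.Graph.Full(8) + ig.Graph.Full(8)
        labels = leiden_cluster(g, resolution=0.5, seed=1)
        assert len(set(labels)) == 2
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1

    def test_singleton_graph(self):
        labels = leiden_cluster(ig.Graph(n=1), resolution=1.0, seed=0)
        assert list(labels) == [0]

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            leiden_cluster(ig.Graph(n=0))

    def test_seed_determinism(self, small_gated):
        kept, _, _ = small_gated
        g = build_knn_graph(kept, k=15)
        a = leiden_cluster(g, resolution=0.3, seed=5)
        b = leiden_cluster(g, resolution=0.3, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_resolution_scan_reaches_target(self, small_gated):
        kept, _, _ = small_gated
        g = build_knn_graph(kept, k=15)
        res, labels = scan_resolution(g, target=5, seed=0)
        assert labels.max() + 1 >= 5


class TestAnnotation:
    @staticmethod
    def _synthetic_cluster_table(means: dict) -> tuple[pd.DataFrame, np.ndarray]:
        # 20 identical cells per cluster with the given marker means
        rows, clusters = [], []
        for cid, m in means.items():
            for _ in range(20):
                rows.append(m)
                clusters.append(cid)
        tab = pd.DataFrame(rows)
        for marker in MARKERS:
            if marker not in tab.columns:
                tab[marker] = 0.0
        tab.insert(0, "sample_id", "s")
        return tab, np.array(clusters)

    def test_signature_cluster_labeled_endocycle(self):
        base = {"RAIDD": 0.0, "CDK1": 0.0, "Wee1": 0.0, "CDK2": 0.0,
                "Cyclin D1": 0.0, "Cyclin E1": 0.0, "Cyclin E2": 0.0}
        tab, clusters = self._synthetic_cluster_table({
            0: {**base, "Cyclin D1": 2.0},
            1: {**base, "Cyclin E1": 2.0, "Cyclin E2": 2.0},
            2: {**base, "CDK1": 1.0, "Wee1": 1.0},
            3: {**base, "CDK1": 3.0},
            4: {**base, "RAIDD": 3.0, "Wee1": 2.5, "CDK2": 2.5, "CDK1": -1.0},
        })
        cc = annotate_phases(tab, clusters)
        assert cc.cluster_phases == {0: "G1", 1: "S", 2: "G2", 3: "M", 4: "endocycle"}

    def test_identical_clusters_all_unassigned(self):
        base = {m: 1.0 for m in MARKERS}
        tab, clusters = self._synthetic_cluster_table({i: dict(base) for i in range(5)})
        with pytest.warns(UserWarning):
            cc = annotate_phases(tab, clusters)
        assert set(cc.cluster_phases.values()) == {"unassigned"}

    def test_wrong_cluster_count_warns(self):
        base = {m: 0.0 for m in MARKERS}
        tab, clusters = self._synthetic_cluster_table({
            0: {**base, "RAIDD": 2.0, "Wee1": 2.0, "CDK2": 2.0, "CDK1": -1.0},
            1: {**base, "CDK1": 2.0},
            2: {**base, "Cyclin D1": 2.0},
        })
        with pytest.warns(UserWarning, match="expected 5"):
            annotate_phases(tab, clusters)

    def test_missing_markers_rejected(self):
        tab = pd.DataFrame({"sample_id": ["s", "s"], "pRB": [1.0, 2.0]})
        with pytest.raises(ValueError, match="annotation requires"):
            annotate_phases(tab, np.array([0, 1]))


class TestEndToEnd:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted(small_gated):
        kept, _, _ = small_gated
        return kept, CellCycleMapper(n_neighbors=15, random_state=0).fit(kept)

    def test_planted_phases_recovered(self, fitted):
        kept, mapper = fitted
        ari = adjusted_rand_score(kept["true_phase"], mapper.labels_)
        assert ari >= 0.8

    def test_annotation_agrees_with_truth(self, fitted):
        kept, mapper = fitted
        agree = (mapper.map_.phases.to_numpy() == kept["true_phase"].to_numpy()).mean()
        assert agree >= 0.9
        assert "endocycle" in set(mapper.map_.cluster_phases.values())

    def test_every_cell_mapped(self, fitted):
        kept, mapper = fitted
        cells = mapper.map_.cells
        assert len(cells) == len(kept)
        assert cells[["embed_x", "embed_y"]].notna().all().all()
        assert cells["cluster"].ge(0).all()

    def test_mapper_determinism(self, small_gated):
        kept, _, _ = small_gated
        a = CellCycleMapper(n_neighbors=15, random_state=0).fit(kept)
        b = CellCycleMapper(n_neighbors=15, random_state=0).fit(kept)
        np.testing.assert_array_equal(a.labels_, b.labels_)
        np.testing.assert_array_equal(a.embedding_, b.embedding_)

    def test_phase_marker_summary(self, fitted):
        kept, mapper = fitted
        summ = phase_marker_summary(mapper.map_, kept)
        means = summ["mean"]
        assert means.loc["endocycle", "RAIDD"] > means.loc["G2", "RAIDD"]
        # phases partition the cells: the size-weighted phase means must
        # reproduce the table's column means exactly
        sizes = mapper.map_.phases.value_counts()
        weighted = (means.mul(sizes.reindex(means.index), axis=0).sum()
                    / sizes.sum())
        np.testing.assert_allclose(weighted, kept[list(MARKERS)].mean(), atol=1e-9)

    def test_single_phase_summary_is_column_means(self, small_gated):
        kept, _, _ = small_gated
        from cyclemap.mapping import CellCycleMap

        cells = pd.DataFrame({"cluster": 0, "phase": "G1"}, index=kept.index)
        cc = CellCycleMap(cells=cells, cluster_phases={0: "G1"})
        summ = phase_marker_summary(cc, kept)
        np.testing.assert_allclose(
            summ["mean"].loc["G1"], kept[list(MARKERS)].mean(), atol=1e-12
        )
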