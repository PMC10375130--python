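"""The clustered-latent transform: PCA + K-means + patient matrices."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from srmc.kpca import (
    CohortTransform,
    cluster1_pc1_roc,
    fit_kpca,
    patient_matrix,
    rank_marker_cluster,
    transform_cells,
)


def blob_cells(rng, n_per_blob=200, centers=((0, 0), (30, 0), (0, 30)),
               spread=1.5, n_features=4):
    rows, truth = [], []
    for b, c in enumerate(centers):
        pts = rng.normal(0, spread, (n_per_blob, n_features))
        pts[:, 0] += c[0]
        pts[:, 1] += c[1]
        rows.append(pts)
        truth += [b] * n_per_blob
    X = np.vstack(rows)
    cells = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    cells["patient_id"] = "P"
    return cells, np.array(truth)


FEATURES = ["f0", "f1", "f2", "f3"]


class TestFitKpca:
    def test_blobs_recovered(self, rng):
        cells, truth = blob_cells(rng)
        t = fit_kpca(cells, FEATURES, seed=0)
        latent = transform_cells(t, cells)
        assert adjusted_rand_score(truth, latent["cluster"]) >= 0.95

    def test_variance_target_one_keeps_all_components(self, rng):
        cells, _ = blob_cells(rng)
        t = fit_kpca(cells, FEATURES, variance_target=1.0, seed=0)
        assert t.n_components == len(FEATURES)

    def test_component_floor_is_two(self, rng):
        cells, _ = blob_cells(rng)
        t = fit_kpca(cells, FEATURES, variance_target=0.01, seed=0)
        assert t.n_components == 2

    def test_determinism(self, rng):
        cells, _ = blob_cells(rng)
        t1 = fit_kpca(cells, FEATURES, seed=3)
        t2 = fit_kpca(cells, FEATURES, seed=3)
        np.testing.assert_array_equal(t1.kmeans_centers, t2.kmeans_centers)
        np.testing.assert_array_equal(t1.components, t2.components)
        assert t1.cluster_order == t2.cluster_order

    def test_degenerate_inputs(self, rng):
        cells, _ = blob_cells(rng, n_per_blob=1)
        with pytest.raises(ValueError):
            fit_kpca(cells.iloc[:2], FEATURES, k=3)
        flat = cells.copy()
        flat[FEATURES] = 1.0
        with pytest.raises(ValueError):
            fit_kpca(flat, FEATURES, k=3)

    def test_loadings_orthonormal_and_reconstruction(self, rng):
        cells, _ = blob_cells(rng)
        t = fit_kpca(cells, FEATURES, variance_target=1.0, seed=0)
        gram = t.components @ t.components.T
        np.testing.assert_allclose(gram, np.eye(t.n_components), atol=1e-9)
        X = cells[FEATURES].to_numpy()
        latent = (X - t.center) @ t.components.T
        np.testing.assert_allclose(latent @ t.components,
                                   X - t.center, atol=1e-9)

    def test_assignments_are_nearest_center(self, rng):
        cells, _ = blob_cells(rng)
        t = fit_kpca(cells, FEATURES, seed=0)
        latent_df = transform_cells(t, cells)
        pcs = latent_df[[f"PC{j+1}" for j in range(t.n_components)]].to_numpy()
        d2 = ((pcs[:, None] - t.kmeans_centers[None]) ** 2).sum(-1)
        nearest_raw = d2.argmin(1)
        reported = np.array([t.reported_index()[r] for r in nearest_raw])
        np.testing.assert_array_equal(reported, latent_df["cluster"])


class TestTransformCells:
    def test_global_mean_maps_to_origin(self, rng):
        cells, _ = blob_cells(rng)
        t = fit_kpca(cells, FEATURES, seed=0)
        mean_cell = pd.DataFrame([cells[FEATURES].mean()])
        mean_cell["patient_id"] = "P"
        latent = transform_cells(t, mean_cell)
        for j in range(t.n_components):
            assert latent[f"PC{j+1}"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_heldout_blob_cells_follow_their_blob(self, rng):
        cells, truth = blob_cells(rng)
        t = fit_kpca(cells, FEATURES, seed=0)
        train_latent = transform_cells(t, cells)
        held, held_truth = blob_cells(np.random.default_rng(99))
        held_latent = transform_cells(t, held)
        # map blob id -> modal training cluster, check >= 95% agreement
        agree = 0
        for b in range(3):
            modal = train_latent.loc[truth == b, "cluster"].mode()[0]
            agree += (held_latent.loc[held_truth == b, "cluster"]
                      == modal).sum()
        assert agree / len(held) >= 0.95

    def test_missing_feature_column(self, rng):
        cells, _ = blob_cells(rng)
        t = fit_kpca(cells, FEATURES, seed=0)
        with pytest.raises(KeyError):
            transform_cells(t, cells.drop(columns=["f2"]))

    def test_row_order_invariance(self, rng):
        cells, _ = blob_cells(rng)
        t = fit_kpca(cells, FEATURES, seed=0)
        latent = transform_cells(t, cells)
        shuffled = cells.sample(frac=1.0, random_state=1)
        latent_s = transform_cells(t, shuffled)
        merged = latent.assign(idx=cells.index)
        merged_s = latent_s.assign(idx=shuffled.index).sort_values("idx")
        np.testing.assert_array_equal(merged["cluster"],
                                      merged_s["cluster"].to_numpy())


class TestMarkerRanking:
    def _toy_transform(self, centers):
        return CohortTransform(
            feature_names=["a", "b"], center=np.zeros(2),
            components=np.eye(2), explained_variance_fractions=np.ones(2),
            n_components=2, kmeans_centers=np.asarray(centers, float),
            cluster_order=list(range(len(centers))), seed=0)

    def test_widest_pc1_cluster_is_reported_first(self, rng):
        latent = np.vstack([
            rng.normal(0, 0.5, (100, 2)),
            rng.normal([10, 0], [6.0, 0.5], (50, 2)),   # wide in PC1
            rng.normal([-10, 0], 0.5, (80, 2)),
        ])
        labels = np.r_[np.zeros(100, int), np.ones(50, int),
                       np.full(80, 2, int)]
        t = self._toy_transform([[0, 0], [10, 0], [-10, 0]])
        order = rank_marker_cluster(t, latent, labels)
        assert order[0] == 1
        assert order[1:] == [0, 2]  # remaining by descending size

    def test_relabeling_invariance(self, rng):
        latent = np.vstack([
            rng.normal(0, 0.5, (100, 2)),
            rng.normal([10, 0], [6.0, 0.5], (50, 2)),
            rng.normal([-10, 0], 0.5, (80, 2)),
        ])
        labels = np.r_[np.zeros(100, int), np.ones(50, int),
                       np.full(80, 2, int)]
        centers = np.array([[0, 0], [10, 0], [-10, 0]], float)
        order1 = rank_marker_cluster(self._toy_transform(centers),
                                     latent, labels)
        perm = np.array([2, 0, 1])  # new raw label j holds old perm[j]
        inv = np.argsort(perm)
        order2 = rank_marker_cluster(self._toy_transform(centers[perm]),
                                     latent, inv[labels])
        assert [perm[c] for c in order2] == order1

    def test_tie_break_is_deterministic(self, rng):
        latent = np.vstack([rng.normal([c, 0], 1.0, (50, 2))
                            for c in (-8, 0, 8)])
        labels = np.repeat([0, 1, 2], 50)
        t = self._toy_transform([[-8, 0], [0, 0], [8, 0]])
        o1 = rank_marker_cluster(t, latent, labels)
        o2 = rank_marker_cluster(t, latent, labels)
        assert o1 == o2


class TestPatientMatrix:
    def _latent(self, pcs, clusters, pid="P1"):
        df = pd.DataFrame({"PC1": pcs, "PC2": np.zeros(len(pcs)),
                           "cluster": clusters})
        df["patient_id"] = pid
        return df

    def test_median_example(self):
        m = patient_matrix(self._latent([1, 2, 9], [1, 1, 1]), k=3)
        assert m.pc_center[0, 0] == 2.0
        assert m.counts[0] == 3

    def test_empty_clusters_flagged(self):
        m = patient_matrix(self._latent([1, 2], [1, 1]), k=3)
        assert list(m.counts) == [2, 0, 0]
        assert list(m.imputed) == [False, True, True]
        assert m.pc_center[1].tolist() == [0.0, 0.0]

    def test_count_conservation(self, rng):
        for _ in range(5):
            n = int(rng.integers(1, 40))
            clusters = rng.integers(1, 4, n)
            m = patient_matrix(self._latent(rng.random(n), clusters), k=3)
            assert m.counts.sum() == m.total_cells == n

    def test_zero_cells_is_an_error(self):
        with pytest.raises(ValueError):
            patient_matrix(self._latent([], []), k=3)

    def test_mixed_patients_rejected(self):
        df = pd.concat([self._latent([1], [1], "A"),
                        self._latent([2], [2], "B")])
        with pytest.raises(ValueError):
            patient_matrix(df, k=3)


class TestCluster1Pc1Roc:
    def _matrices(self, scores):
        mats = []
        for i, s in enumerate(scores):
            from srmc.kpca import PatientFeatureMatrix
            mats.append(PatientFeatureMatrix(
                patient_id=f"P{i}", pc_center=np.array([[s, 0.0]]),
                counts=np.array([5]), total_cells=5,
                imputed=np.array([False])))
        return mats

    def test_perfect_separation(self):
        mats = self._matrices([10, 11, 12, 1, 2, 3])
        labels = {f"P{i}": ("POS" if i < 3 else "NEG") for i in range(6)}
        roc, auc, thr = cluster1_pc1_roc(mats, labels)
        assert auc == 1.0
        assert 3 < thr <= 10

    def test_constant_scores_are_chance(self):
        mats = self._matrices([5.0] * 6)
        labels = {f"P{i}": ("POS" if i < 3 else "NEG") for i in range(6)}
        _, auc, _ = cluster1_pc1_roc(mats, labels)
        assert auc == pytest.approx(0.5)

    def test_single_class_is_an_error(self):
        mats = self._matrices([1, 2])
        with pytest.raises(ValueError):
            cluster1_pc1_roc(mats, {"P0": "POS", "P1": "POS"})


def test_transform_json_roundtrip(tmp_path, rng):
    cells, _ = blob_cells(rng)
    t = fit_kpca(cells, FEATURES, seed=0)
    path = tmp_path / "t.json"
    t.to_json(path)
    back = CohortTransform.from_json(path)
    np.testing.assert_array_equal(back.components, t.components)
    np.testing.assert_array_equal(back.kmeans_centers, t.kmeans_centers)
    assert back.cluster_order == t.cluster_order
    latent1 = transform_cells(t, cells)
    latent2 = transform_cells(back, cells)
    np.testing.assert_array_equal(latent1["cluster"], latent2["cluster"])
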