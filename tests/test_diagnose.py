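"""Patient-level classification, LOOCV, metrics and interpretation."""

import numpy as np
import pandas as pd
import pytest

from srmc.diagnose import (
    FEATURE_GROUPS,
    LoocvConfig,
    ablate_feature_groups,
    diagnostic_metrics,
    fit_pm_classifier,
    importance,
    loocv,
    ml_pca_cell_classifier,
    youden_cutoff,
)
from srmc.kpca import PatientFeatureMatrix


def toy_matrices(n_pos=6, n_neg=6, gap=10.0, rng=None):
    rng = rng or np.random.default_rng(0)
    mats, labels = [], {}
    for i in range(n_pos + n_neg):
        pos = i < n_pos
        pid = f"P{i}"
        base = gap if pos else 0.0
        mats.append(PatientFeatureMatrix(
            patient_id=pid,
            pc_center=rng.normal(base, 1.0, (3, 2)),
            counts=rng.integers(5, 20, 3),
            total_cells=30,
            imputed=np.zeros(3, bool)))
        labels[pid] = "POS" if pos else "NEG"
    return mats, labels


class TestFitPmClassifier:
    @pytest.mark.parametrize("model", ["LR", "SVM", "LDA"])
    def test_separable_training_accuracy(self, model):
        mats, labels = toy_matrices()
        clf = fit_pm_classifier(mats, labels, model=model, seed=0)
        X, _ = clf.mean[None] * 0, None  # noqa: F841
        from srmc.diagnose import matrices_to_X
        X, _ = matrices_to_X(mats)
        prob = clf.predict_proba(X)
        pred = prob >= 0.5
        truth = np.array([labels[m.patient_id] == "POS" for m in mats])
        assert (pred == truth).all()

    def test_refit_is_deterministic(self):
        mats, labels = toy_matrices()
        from srmc.diagnose import matrices_to_X
        X, _ = matrices_to_X(mats)
        p1 = fit_pm_classifier(mats, labels, seed=1).predict_proba(X)
        p2 = fit_pm_classifier(mats, labels, seed=1).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_is_an_error(self):
        mats, labels = toy_matrices()
        with pytest.raises(ValueError):
            fit_pm_classifier(mats, {k: "POS" for k in labels})


class TestDiagnosticMetrics:
    def test_cohort_arithmetic(self):
        """27 positives / 53 negatives with TP=22, FN=5, TN=45, FP=8."""
        prob = np.r_[np.full(22, 0.9), np.full(5, 0.1),
                     np.full(45, 0.2), np.full(8, 0.8)]
        truth = np.r_[np.ones(27, bool), np.zeros(53, bool)]
        rep = diagnostic_metrics(prob, truth, cutoff=0.5)
        assert (rep.tp, rep.fn, rep.tn, rep.fp) == (22, 5, 45, 8)
        assert rep.sensitivity == pytest.approx(0.8148, abs=1e-4)
        assert rep.specificity == pytest.approx(0.8491, abs=1e-4)
        assert rep.accuracy == pytest.approx(0.8375, abs=1e-4)
        assert rep.npv == pytest.approx(0.9, abs=1e-4)
        assert rep.ppv == pytest.approx(22 / 30, abs=1e-4)

    def test_perfect_probabilities(self):
        prob = np.r_[np.ones(4), np.zeros(4)]
        truth = np.r_[np.ones(4, bool), np.zeros(4, bool)]
        rep = diagnostic_metrics(prob, truth, cutoff=0.5)
        for v in (rep.sensitivity, rep.specificity, rep.accuracy,
                  rep.npv, rep.ppv, rep.auc):
            assert v == 1.0

    def test_all_positive_predictions(self):
        prob = np.full(6, 0.9)
        truth = np.r_[np.ones(3, bool), np.zeros(3, bool)]
        rep = diagnostic_metrics(prob, truth, cutoff=0.5)
        assert rep.sensitivity == 1.0
        assert rep.specificity == 0.0

    def test_metric_identities_hold(self, rng):
        prob = rng.random(40)
        truth = rng.random(40) > 0.4
        rep = diagnostic_metrics(prob, truth, cutoff=0.3)
        total = rep.tp + rep.fp + rep.tn + rep.fn
        assert total == 40
        assert rep.accuracy == pytest.approx((rep.tp + rep.tn) / total)
        if rep.tp + rep.fn:
            assert rep.sensitivity == pytest.approx(rep.tp / (rep.tp + rep.fn))
        assert 0.0 <= rep.auc <= 1.0

    def test_single_class_truth_is_an_error(self):
        with pytest.raises(ValueError):
            diagnostic_metrics([0.2, 0.8], [True, True], cutoff=0.5)

    def test_youden_tie_breaks_low(self):
        # two cutoffs reach the same J; the lower one must win
        prob = np.array([0.2, 0.4, 0.6, 0.8])
        truth = np.array([False, False, True, True])
        assert youden_cutoff(prob, truth) == 0.6


class TestLoocv:
    def test_signal_cohort_is_separable(self, small_cohort):
        cells, pm_labels, _ = small_cohort
        rep = loocv(cells, pm_labels, LoocvConfig(seed=0))
        assert rep.auc >= 0.8
        assert len(rep.patients) == len(pm_labels)
        assert rep.patients["pm_probability"].between(0, 1).all()

    def test_determinism(self, small_cohort):
        cells, pm_labels, _ = small_cohort
        r1 = loocv(cells, pm_labels, LoocvConfig(seed=4))
        r2 = loocv(cells, pm_labels, LoocvConfig(seed=4))
        pd.testing.assert_frame_equal(r1.patients, r2.patients)
        assert r1.auc == r2.auc

    def test_no_leakage_from_held_out_patient(self, small_cohort):
        """Perturbing the held-out patient's cells must not change the
        transform fitted for that fold."""
        cells, pm_labels, _ = small_cohort
        cfg = LoocvConfig(seed=0)
        target = cells["patient_id"].iloc[0]
        r1 = loocv(cells, pm_labels, cfg, capture_folds=True)
        perturbed = cells.copy()
        mask = perturbed["patient_id"] == target
        from srmc.features import ALL_FEATURES
        perturbed.loc[mask, list(ALL_FEATURES)] *= 3.0
        r2 = loocv(perturbed, pm_labels, cfg, capture_folds=True)
        t1 = r1.folds[target]["transform"]
        t2 = r2.folds[target]["transform"]
        np.testing.assert_array_equal(t1.center, t2.center)
        np.testing.assert_array_equal(t1.components, t2.components)
        np.testing.assert_array_equal(t1.kmeans_centers, t2.kmeans_centers)
        assert (r1.folds[target]["selection"].selected
                == r2.folds[target]["selection"].selected)

    def test_too_few_patients_per_class(self, small_cohort):
        cells, pm_labels, _ = small_cohort
        labels = dict(pm_labels)
        for pid in list(labels)[:3]:
            labels[pid] = "NEG"
        with pytest.raises(ValueError):
            loocv(cells, labels, LoocvConfig(seed=0))

    def test_frozen_transform_mode_runs(self, small_cohort):
        cells, pm_labels, _ = small_cohort
        rep = loocv(cells, pm_labels,
                    LoocvConfig(seed=0, refit_per_fold=False))
        assert 0.0 <= rep.auc <= 1.0


class TestMlPcaCellClassifier:
    def _cells_with_truth(self, cohort):
        cells, pm_labels, truth = cohort
        merged = cells.merge(
            truth[["patient_id", "frame_id", "cell_label", "is_marker"]],
            on=["patient_id", "frame_id", "cell_label"])
        return merged, merged["is_marker"].to_numpy()

    def test_marker_cells_recognized(self, small_cohort):
        from srmc.features import ALL_FEATURES

        cells, y = self._cells_with_truth(small_cohort)
        _, pred, metrics, mats = ml_pca_cell_classifier(
            cells, y, list(ALL_FEATURES), model="LDA", seed=0)
        assert metrics["accuracy"] >= 0.9
        assert set(mats) == set(cells["patient_id"].unique())

    def test_single_class_is_an_error(self, small_cohort):
        from srmc.features import ALL_FEATURES

        cells, y = self._cells_with_truth(small_cohort)
        with pytest.raises(ValueError):
            ml_pca_cell_classifier(cells, np.zeros_like(y),
                                   list(ALL_FEATURES))

    def test_prediction_order_invariance(self, small_cohort):
        from srmc.features import ALL_FEATURES

        cells, y = self._cells_with_truth(small_cohort)
        _, pred, _, _ = ml_pca_cell_classifier(cells, y,
                                               list(ALL_FEATURES), seed=0)
        idx = np.random.default_rng(0).permutation(len(cells))
        _, pred_s, _, _ = ml_pca_cell_classifier(
            cells.iloc[idx].reset_index(drop=True), y[idx],
            list(ALL_FEATURES), seed=0)
        np.testing.assert_array_equal(pred[idx], pred_s)


class TestImportance:
    def test_signs_and_loading_norms(self):
        rng = np.random.default_rng(1)
        mats, labels = [], {}
        for i in range(16):
            pos = i < 8
            pc = rng.normal(0, 1.0, (3, 2))
            pc[0, 0] += 8.0 if pos else 0.0  # C1_PC1 drives PM
            pid = f"P{i}"
            mats.append(PatientFeatureMatrix(
                patient_id=pid, pc_center=pc,
                counts=rng.integers(5, 20, 3), total_cells=30,
                imputed=np.zeros(3, bool)))
            labels[pid] = "POS" if pos else "NEG"
        clf = fit_pm_classifier(mats, labels, model="LR", seed=0)

        from srmc.kpca import CohortTransform
        comp = np.array([[0.8, 0.6], [-0.6, 0.8]])
        transform = CohortTransform(
            feature_names=["a", "b"], center=np.zeros(2), components=comp,
            explained_variance_fractions=np.array([0.9, 0.1]),
            n_components=2, kmeans_centers=np.zeros((3, 2)),
            cluster_order=[0, 1, 2], seed=0)
        rep = importance(clf, transform)
        c1pc1 = rep.matrix_importance.set_index("feature")["coefficient"]
        assert c1pc1["C1_PC1"] > 0
        for pc in ("PC1", "PC2"):
            sub = rep.loading_contributions.query("pc == @pc")["loading"]
            assert np.linalg.norm(sub) == pytest.approx(1.0)

    def test_nonlinear_model_rejected(self):
        from sklearn.svm import SVC

        from srmc.diagnose import PMClassifier
        clf = PMClassifier("SVM", SVC(kernel="rbf"), ["x"],
                           np.zeros(1), np.ones(1), np.ones(1, bool))
        with pytest.raises(ValueError):
            importance(clf, None)

    def test_constant_matrix_feature_dropped(self):
        mats, labels = toy_matrices()
        for m in mats:
            m.counts = np.array([7, 7, 7])  # constant counts
        clf = fit_pm_classifier(mats, labels, model="LR", seed=0)
        coef = clf.coefficients()
        names = clf.feature_names
        for c in ("C1_n", "C2_n", "C3_n"):
            assert coef[names.index(c)] == 0.0


class TestAblation:
    def test_group_contract(self):
        both = set(FEATURE_GROUPS["both"])
        assert set(FEATURE_GROUPS["morphology"]) < both
        assert set(FEATURE_GROUPS["composition"]) < both
        with pytest.raises(ValueError):
            ablate_feature_groups(pd.DataFrame(), {}, groups=("bogus",))
        with pytest.raises(ValueError):
            ablate_feature_groups(pd.DataFrame(), {}, groups=())

    def test_composition_driven_cohort(self):
        """When the planted contrast is compositional, composition-only
        LOOCV must beat morphology-only sensitivity."""
        from srmc.simulate import (CohortSpec, default_phenotypes,
                                   simulate_cohort_cells)

        ph = default_phenotypes()
        marker = ph["marker"]
        meso = ph["mesothelial"]
        # marker inherits normal geometry; only chemistry differs
        marker.area_log_mean = meso.area_log_mean
        marker.area_log_sd = meso.area_log_sd
        marker.axis_ratio_range = meso.axis_ratio_range
        marker.boundary_waviness = meso.boundary_waviness
        marker.lipid_level = 1.3
        marker.protein_level = 1.7
        marker.ld_count_mean = 8.0
        spec = CohortSpec(n_pos=4, n_neg=5, frames_per_patient=5,
                          cells_per_frame_mean=10,
                          marker_fraction_pos=0.30, marker_fraction_neg=0.02,
                          marker_divergence_scale=1.0, phenotypes=ph, seed=13)
        cells, pm_labels, _ = simulate_cohort_cells(spec)
        table = ablate_feature_groups(cells, pm_labels,
                                      config=LoocvConfig(seed=0))
        t = table.set_index("group")
        assert t.loc["composition", "auc"] > t.loc["morphology", "auc"]
        assert (t.loc["composition", "sensitivity"]
                >= t.loc["morphology", "sensitivity"])
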