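"""Patient-level peritoneal-metastasis diagnosis and interpretation.

Patients are represented by their clustered latent feature matrices
(cluster-wise PC medians + cell counts) and classified PM+/PM− with
logistic regression (default), a linear SVM, or LDA, evaluated by
patient-level leave-one-out cross-validation. Every fold refits the
entire upstream pipeline — feature selection, K-PCA, marker ranking,
standardization, classifier — on the training patients only, so no
statistic of the held-out patient leaks into its own score. A
"frozen" mode that fits the transform once on all patients is kept
for comparison with that laxer protocol.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .features import ALL_FEATURES, FeatureSelection, select_features
from .kpca import (
    CohortTransform,
    PatientFeatureMatrix,
    fit_kpca,
    patient_matrix,
    transform_cells,
)

__all__ = [
    "DiagnosisReport",
    "ImportanceReport",
    "PMClassifier",
    "fit_pm_classifier",
    "loocv",
    "diagnostic_metrics",
    "ml_pca_cell_classifier",
    "importance",
    "ablate_feature_groups",
    "FEATURE_GROUPS",
]

MODELS = ("LR", "SVM", "LDA")

FEATURE_GROUPS = {
    "morphology": tuple(f for f in ALL_FEATURES[:10]),
    "composition": tuple(f for f in ALL_FEATURES[10:]),
    "both": tuple(ALL_FEATURES),
}


@dataclass
class PMClassifier:
    """A fitted patient-level model plus its training statistics."""

    model_name: str
    estimator: object
    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray  # mask of non-constant inputs

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.mean) / self.sd
        return Z[:, self.kept]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """PM-positive probability per row."""
        return self.estimator.predict_proba(self._prepare(X))[:, 1]

    def coefficients(self) -> np.ndarray:
        """Signed coefficients on standardized inputs; 0 for dropped."""
        coef = np.zeros(len(self.feature_names))
        coef[self.kept] = np.ravel(self.estimator.coef_)
        return coef


class PlattSVC:
    """Linear SVM with sigmoid (Platt) calibration on the training data.

    The margin classifier is a hard-margin-style linear SVC (C=1); a
    one-dimensional logistic fit on its training decision values maps
    margins to probabilities.
    """

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.svc = SVC(kernel="linear", C=C, random_state=seed)
        self.platt = LogisticRegression(max_iter=2000)

    def fit(self, X, y):
        self.svc.fit(X, y)
        d = self.svc.decision_function(X)
        self.platt.fit(d[:, None], y)
        return self

    def predict_proba(self, X):
        d = self.svc.decision_function(X)
        return self.platt.predict_proba(d[:, None])

    def predict(self, X):
        return self.svc.predict(X)

    @property
    def coef_(self):
        # chain rule: probability-scale direction is the SVC direction
        # scaled by the (positive) Platt slope
        return self.svc.coef_ * float(self.platt.coef_[0, 0])

    @property
    def kernel(self):
        return self.svc.kernel


def _make_estimator(model: str, seed: int):
    if model == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if model == "SVM":
        return PlattSVC(C=1.0, seed=seed)
    if model == "LDA":
        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def matrices_to_X(matrices: list[PatientFeatureMatrix],
                  include_counts: bool = True,
                  normalize_counts: bool = False
                  ) -> tuple[np.ndarray, list[str]]:
    rows, names = [], None
    for m in matrices:
        v, names = m.flatten(include_counts=include_counts,
                             normalize_counts=normalize_counts)
        rows.append(v)
    return np.vstack(rows), names


def fit_pm_classifier(matrices: list[PatientFeatureMatrix],
                      pm_labels: dict[str, str], model: str = "LR",
                      seed: int = 0, include_counts: bool = True,
                      normalize_counts: bool = False) -> PMClassifier:
    """Fit a PM classifier on flattened, z-scored patient matrices.

    Constant inputs are dropped (reported via the classifier's ``kept``
    mask) so standardization is well-defined.
    """
    y = np.array([pm_labels[m.patient_id] == "POS" for m in matrices])
    if y.all() or not y.any():
        raise ValueError("training set must contain both PM classes")
    if y.sum() < 2 or (~y).sum() < 2:
        # reachable inside LOOCV folds of a minimal cohort
        warnings.warn("fewer than 2 training patients in a class; "
                      "the fitted model will be unstable")
    X, names = matrices_to_X(matrices, include_counts, normalize_counts)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    kept = sd > 0
    sd = np.where(kept, sd, 1.0)
    est = _make_estimator(model, seed)
    clf = PMClassifier(model_name=model, estimator=est,
                       feature_names=names, mean=mean, sd=sd, kept=kept)
    est.fit(clf._prepare(X), y.astype(int))
    return clf


@dataclass
class DiagnosisReport:
    """Per-patient probabilities plus pooled diagnostic metrics."""

    model: str
    patients: pd.DataFrame  # patient_id, pm_probability, predicted, true
    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    npv: float
    ppv: float
    auc: float
    roc: pd.DataFrame
    excluded_patients: list[str] = field(default_factory=list)
    folds: dict = field(default_factory=dict)  # optional instrumentation

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "cutoff": self.cutoff,
            "confusion": {"TP": self.tp, "FP": self.fp,
                          "TN": self.tn, "FN": self.fn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "npv": self.npv,
            "ppv": self.ppv,
            "auc": self.auc,
            "excluded_patients": list(self.excluded_patients),
            "patients": self.patients.to_dict(orient="records"),
            "roc": self.roc.to_dict(orient="records"),
        }


def _safe_div(a: float, b: float) -> float:
    return float(a / b) if b else 0.0


def diagnostic_metrics(probabilities, truth, cutoff: float,
                       model: str = "") -> DiagnosisReport:
    """Confusion matrix and metric set at a fixed probability cutoff.

    ``truth`` is boolean (PM positive). AUC is the trapezoid area under
    the empirical ROC of the probabilities.
    """
    prob = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if not (0.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [0, 1]")
    if y.all() or not y.any():
        raise ValueError("AUC undefined for single-class truth")
    pred = prob >= cutoff
    tp = int((pred & y).sum())
    fp = int((pred & ~y).sum())
    tn = int((~pred & ~y).sum())
    fn = int((~pred & y).sum())
    fpr, tpr, thresholds = roc_curve(y, prob)
    auc = float(np.trapezoid(tpr, fpr))
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    patients = pd.DataFrame({
        "pm_probability": prob,
        "predicted": pred,
        "true": y,
    })
    return DiagnosisReport(
        model=model, patients=patients, cutoff=float(cutoff),
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        accuracy=_safe_div(tp + tn, tp + tn + fp + fn),
        npv=_safe_div(tn, tn + fn),
        ppv=_safe_div(tp, tp + fp),
        auc=auc, roc=roc,
    )


def youden_cutoff(probabilities, truth) -> float:
    """Cutoff maximizing sensitivity + specificity − 1; ties -> lower."""
    prob = np.asarray(probabilities, dtype=float)
    y = np.asarray(truth, dtype=bool)
    best_j, best_c = -np.inf, 0.5
    for c in sorted(np.unique(prob)):
        pred = prob >= c
        tp = (pred & y).sum()
        fn = (~pred & y).sum()
        tn = (~pred & ~y).sum()
        fp = (pred & ~y).sum()
        j = _safe_div(tp, tp + fn) + _safe_div(tn, tn + fp) - 1.0
        if j > best_j:  # strict: first (lowest) cutoff wins ties
            best_j, best_c = j, float(c)
    return best_c


@dataclass
class LoocvConfig:
    """Stage parameters threaded through a LOOCV run."""

    alpha: float = 0.05
    features: tuple = tuple(ALL_FEATURES)
    k: int = 3
    variance_target: float = 0.9
    model: str = "LR"
    seed: int = 0
    include_counts: bool = True
    normalize_counts: bool = False
    marker_strategy: str = "pc1_iqr"
    refit_per_fold: bool = True  # False = lax "frozen transform" mode


def _fit_stage(cells: pd.DataFrame, pm_labels: dict[str, str],
               cfg: LoocvConfig
               ) -> tuple[FeatureSelection, CohortTransform]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        selection = select_features(cells, pm_labels, alpha=cfg.alpha,
                                    features=cfg.features)
    selected = selection.selected
    if len(selected) < 2:
        # too few discriminative features to span a plane; fall back to
        # the full candidate set so every fold still yields a score
        selected = [f for f in cfg.features
                    if f not in selection.dropped_constant]
    transform = fit_kpca(cells, selected, k=cfg.k,
                         variance_target=cfg.variance_target,
                         seed=cfg.seed, marker_strategy=cfg.marker_strategy)
    return selection, transform


def _patient_matrices(cells: pd.DataFrame, transform: CohortTransform,
                      cfg: LoocvConfig) -> dict[str, PatientFeatureMatrix]:
    latent = transform_cells(transform, cells)
    out = {}
    for pid, sub in latent.groupby("patient_id", sort=False):
        out[str(pid)] = patient_matrix(sub, k=cfg.k,
                                       n_components=transform.n_components)
    return out


def loocv(cells: pd.DataFrame, pm_labels: dict[str, str],
          config: LoocvConfig | None = None,
          capture_folds: bool = False) -> DiagnosisReport:
    """Patient-level leave-one-out cross-validation.

    For each held-out patient the whole pipeline is refitted on the
    remaining patients' cells only; the held-out patient is then
    transformed and scored. Pooled LOOCV probabilities define the ROC,
    the AUC and the Youden-optimal cutoff. Patients with zero cells
    are excluded with a warning and listed in the report.
    """
    cfg = config or LoocvConfig()
    patient_ids = [p for p in dict.fromkeys(cells["patient_id"])
                   if pm_labels.get(p) in ("POS", "NEG")]
    counts = cells.groupby("patient_id").size()
    excluded = [p for p in pm_labels if pm_labels[p] in ("POS", "NEG")
                and counts.get(p, 0) == 0]
    for p in excluded:
        warnings.warn(f"patient {p} has zero cells; excluded from LOOCV")
    y = {p: pm_labels[p] == "POS" for p in patient_ids}
    n_pos = sum(y.values())
    if n_pos < 2 or len(y) - n_pos < 2:
        raise ValueError("need at least 2 patients per class")

    frozen = None
    if not cfg.refit_per_fold:
        frozen = _fit_stage(cells, pm_labels, cfg)

    probs, folds = {}, {}
    for pid in patient_ids:
        train = cells[cells["patient_id"] != pid]
        test = cells[cells["patient_id"] == pid]
        if cfg.refit_per_fold:
            selection, transform = _fit_stage(train, pm_labels, cfg)
        else:
            selection, transform = frozen
        train_mats = _patient_matrices(train, transform, cfg)
        clf = fit_pm_classifier(
            list(train_mats.values()), pm_labels, model=cfg.model,
            seed=cfg.seed, include_counts=cfg.include_counts,
            normalize_counts=cfg.normalize_counts)
        latent_test = transform_cells(transform, test)
        test_mat = patient_matrix(latent_test, k=cfg.k,
                                  n_components=transform.n_components)
        x, _ = test_mat.flatten(include_counts=cfg.include_counts,
                                normalize_counts=cfg.normalize_counts)
        probs[pid] = float(clf.predict_proba(x[None, :])[0])
        if capture_folds:
            folds[pid] = {"selection": selection, "transform": transform}

    prob_arr = np.array([probs[p] for p in patient_ids])
    truth = np.array([y[p] for p in patient_ids])
    cutoff = youden_cutoff(prob_arr, truth)
    report = diagnostic_metrics(prob_arr, truth, cutoff, model=cfg.model)
    report.patients.insert(0, "patient_id", patient_ids)
    report.excluded_patients = excluded
    if capture_folds:
        report.folds = folds
    return report


def ml_pca_cell_classifier(cells: pd.DataFrame, truth_labels,
                           feature_names, model: str = "LDA",
                           variance_target: float = 0.9, seed: int = 0,
                           k: int = 3):
    """Supervised cell-level tumor/normal classification on PC scores.

    PCA uses the same centered-unscaled convention as K-PCA; the
    classifier (linear SVM or LDA) is trained on the kept PC
    coordinates against the provided tumor/normal truth. Returns
    (classifier dict, per-cell predictions, metrics dict,
    per-patient matrices of predicted-tumor cells).
    """
    if model not in ("SVM", "LDA"):
        raise ValueError("cell-level model must be SVM or LDA")
    y = np.asarray(truth_labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("cell labels contain a single class")
    transform = fit_kpca(cells, feature_names, k=k,
                         variance_target=variance_target, seed=seed)
    latent = transform_cells(transform, cells)
    pc_cols = [f"PC{j + 1}" for j in range(transform.n_components)]
    Z = latent[pc_cols].to_numpy()
    mean, sd = Z.mean(0), Z.std(0)
    sd = np.where(sd > 0, sd, 1.0)
    Zs = (Z - mean) / sd
    est = _make_estimator(model, seed)
    est.fit(Zs, y.astype(int))
    pred = est.predict(Zs).astype(bool)
    prob = est.predict_proba(Zs)[:, 1]
    tp = int((pred & y).sum()); fn = int((~pred & y).sum())
    tn = int((~pred & ~y).sum()); fp = int((pred & ~y).sum())
    fpr, tpr, _ = roc_curve(y, prob)
    metrics = {
        "accuracy": _safe_div(tp + tn, len(y)),
        "sensitivity": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
        "auc": float(np.trapezoid(tpr, fpr)),
    }
    # patient-level input built from predicted-tumor-cell statistics
    latent = latent.assign(predicted_tumor=pred)
    matrices = {}
    for pid, sub in latent.groupby("patient_id", sort=False):
        tumor = sub[sub["predicted_tumor"]]
        med = (tumor[pc_cols].median().to_numpy()
               if len(tumor) else np.zeros(len(pc_cols)))
        matrices[str(pid)] = PatientFeatureMatrix(
            patient_id=str(pid),
            pc_center=med[None, :],
            counts=np.array([len(tumor)]),
            total_cells=len(sub),
            imputed=np.array([len(tumor) == 0]),
        )
    classifier = {"model": model, "estimator": est, "transform": transform,
                  "mean": mean, "sd": sd}
    return classifier, pred, metrics, matrices


@dataclass
class ImportanceReport:
    """Signed classifier coefficients and PCA loading contributions."""

    matrix_importance: pd.DataFrame   # feature, coefficient
    loading_contributions: pd.DataFrame  # raw feature x PC loadings
    dropped: list[str]

    def to_dict(self) -> dict:
        return {
            "matrix_importance": self.matrix_importance.to_dict("records"),
            "loading_contributions":
                self.loading_contributions.to_dict("records"),
            "dropped": list(self.dropped),
        }


def importance(classifier: PMClassifier,
               transform: CohortTransform) -> ImportanceReport:
    """Importance coefficients of the matrix features and PC loadings.

    Matrix-feature importances are the classifier's signed coefficients
    on standardized inputs (linear models only); constant inputs were
    dropped at fit time and reported with importance 0. Raw-feature
    contributions to each PC are the unit-norm PCA loading rows.
    """
    est = classifier.estimator
    if isinstance(est, SVC) and est.kernel != "linear":
        raise ValueError("importance requires a linear-family model")
    if not hasattr(est, "coef_"):
        raise ValueError("importance requires a linear-family model")
    coef = classifier.coefficients()
    matrix_importance = pd.DataFrame({
        "feature": classifier.feature_names,
        "coefficient": coef,
    })
    dropped = [n for n, k in zip(classifier.feature_names, classifier.kept)
               if not k]
    rows = []
    for j in range(transform.n_components):
        for name, loading in zip(transform.feature_names,
                                 transform.components[j]):
            rows.append({"pc": f"PC{j + 1}", "feature": name,
                         "loading": float(loading)})
    return ImportanceReport(
        matrix_importance=matrix_importance,
        loading_contributions=pd.DataFrame(rows),
        dropped=dropped,
    )


def ablate_feature_groups(cells: pd.DataFrame, pm_labels: dict[str, str],
                          groups=("morphology", "composition", "both"),
                          config: LoocvConfig | None = None) -> pd.DataFrame:
    """Rerun LOOCV restricted to each feature group; tabulate metrics."""
    if not groups:
        raise ValueError("no feature groups given")
    cfg = config or LoocvConfig()
    rows = []
    for group in groups:
        if group not in FEATURE_GROUPS:
            raise ValueError(f"unknown feature group {group!r}")
        feats = FEATURE_GROUPS[group]
        if not feats:
            raise ValueError(f"feature group {group!r} is empty")
        sub_cfg = LoocvConfig(**{**cfg.__dict__, "features": feats})
        report = loocv(cells, pm_labels, sub_cfg)
        rows.append({
            "group": group,
            "auc": report.auc,
            "sensitivity": report.sensitivity,
            "specificity": report.specificity,
            "accuracy": report.accuracy,
            "npv": report.npv,
            "ppv": report.ppv,
        })
    return pd.DataFrame(rows)
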