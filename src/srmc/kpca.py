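"""K-PCA: centered PCA + K-means clustered latent feature matrices.

The cohort's selected single-cell features are centered (not scaled)
and reduced by SVD-based PCA to the fewest components explaining at
least a target variance fraction (floor 2). K-means with k clusters is
then fitted in that latent space, pooled over all training patients so
latent coordinates and cluster identities are comparable across
patients. Each patient is summarized by a clustered feature matrix:
the median PC value of their cells per cluster plus the cluster cell
counts. Reported "Cluster 1" is the *marker* cluster — the cluster
whose within-cluster PC1 spread (IQR) is largest, operationalizing the
observation that the diagnostically informative cell population is the
one whose latent features diverge most.

Despite the name, this is not kernel PCA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "CohortTransform",
    "PatientFeatureMatrix",
    "fit_kpca",
    "transform_cells",
    "patient_matrix",
    "rank_marker_cluster",
    "cluster1_pc1_roc",
]

MARKER_RANKING_STRATEGIES = ("pc1_iqr", "pc1_variance", "centroid_distance")


@dataclass
class CohortTransform:
    """Fitted PCA basis + K-means centers + reported cluster order."""

    feature_names: list[str]
    center: np.ndarray                 # per-feature means
    components: np.ndarray             # (n_components, n_features), rows unit
    explained_variance_fractions: np.ndarray
    n_components: int
    kmeans_centers: np.ndarray         # (k, n_components), raw cluster order
    cluster_order: list[int]           # raw labels in reported order 1..k
    seed: int
    variance_target: float = 0.9

    @property
    def k(self) -> int:
        return len(self.cluster_order)

    def reported_index(self) -> dict[int, int]:
        """raw k-means label -> reported cluster number (1-based)."""
        return {raw: i + 1 for i, raw in enumerate(self.cluster_order)}

    def to_json(self, path=None) -> str:
        data = {
            "feature_names": self.feature_names,
            "center": self.center.tolist(),
            "components": self.components.tolist(),
            "explained_variance_fractions":
                self.explained_variance_fractions.tolist(),
            "n_components": self.n_components,
            "kmeans_centers": self.kmeans_centers.tolist(),
            "cluster_order": list(self.cluster_order),
            "seed": self.seed,
            "variance_target": self.variance_target,
        }
        text = json.dumps(data, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CohortTransform":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            data = json.loads(Path(source).read_text())
        else:
            data = json.loads(source)
        return cls(
            feature_names=list(data["feature_names"]),
            center=np.array(data["center"]),
            components=np.array(data["components"]),
            explained_variance_fractions=np.array(
                data["explained_variance_fractions"]),
            n_components=int(data["n_components"]),
            kmeans_centers=np.array(data["kmeans_centers"]),
            cluster_order=list(data["cluster_order"]),
            seed=int(data["seed"]),
            variance_target=float(data["variance_target"]),
        )


@dataclass
class PatientFeatureMatrix:
    """Per-patient cluster-wise latent summary fed to the classifiers."""

    patient_id: str
    pc_center: np.ndarray      # (k, n_components) medians, reported order
    counts: np.ndarray         # (k,) cells per reported cluster
    total_cells: int
    imputed: np.ndarray        # (k,) True where the cluster was empty

    def flatten(self, include_counts: bool = True,
                normalize_counts: bool = False) -> tuple[np.ndarray, list[str]]:
        """Vector form: C{c}_PC{j} medians then C{c}_n counts."""
        k, m = self.pc_center.shape
        values = [self.pc_center[c, j] for c in range(k) for j in range(m)]
        names = [f"C{c + 1}_PC{j + 1}" for c in range(k) for j in range(m)]
        if include_counts:
            counts = self.counts.astype(float)
            if normalize_counts and self.total_cells:
                counts = counts / self.total_cells
            values += list(counts)
            names += [f"C{c + 1}_n" for c in range(k)]
        return np.asarray(values, dtype=float), names


def _matrix_from_cells(cells: pd.DataFrame, feature_names) -> np.ndarray:
    missing = [f for f in feature_names if f not in cells.columns]
    if missing:
        raise KeyError(f"cells table missing feature columns: {missing}")
    return cells[list(feature_names)].to_numpy(dtype=float)


def _fix_component_signs(components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def fit_kpca(cells: pd.DataFrame, feature_names, k: int = 3,
             variance_target: float = 0.9, seed: int = 0,
             marker_strategy: str = "pc1_iqr") -> CohortTransform:
    """Fit the pooled K-PCA transform on a training cell table.

    PCA centers but does not scale the features; the kept component
    count is the smallest explaining at least ``variance_target`` of
    the variance, floored at 2 (or the feature count if lower).
    K-means runs with 10 restarts and a fixed seed on the kept PCs.
    """
    feature_names = list(feature_names)
    X = _matrix_from_cells(cells, feature_names)
    X = X[np.all(np.isfinite(X), axis=1)]
    if len(X) < k:
        raise ValueError(f"need at least k={k} cells, got {len(X)}")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("degenerate (zero-variance) feature matrix")

    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X)
    fractions = pca.explained_variance_ratio_
    cum = np.cumsum(fractions)
    m = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    m = min(max(m, min(2, X.shape[1])), X.shape[1])
    components = _fix_component_signs(pca.components_[:m])
    center = pca.mean_

    latent = (X - center) @ components.T
    km = KMeans(n_clusters=k, n_init=10, random_state=seed,
                tol=1e-4, max_iter=300)
    labels = km.fit_predict(latent)

    transform = CohortTransform(
        feature_names=feature_names,
        center=center,
        components=components,
        explained_variance_fractions=fractions,
        n_components=m,
        kmeans_centers=km.cluster_centers_,
        cluster_order=list(range(k)),  # provisional
        seed=seed,
        variance_target=variance_target,
    )
    transform.cluster_order = rank_marker_cluster(
        transform, latent, labels, strategy=marker_strategy)
    return transform


def _assign_raw(transform: CohortTransform, latent: np.ndarray) -> np.ndarray:
    d2 = ((latent[:, None, :] - transform.kmeans_centers[None]) ** 2).sum(-1)
    return np.argmin(d2, axis=1)


def transform_cells(transform: CohortTransform, cells: pd.DataFrame
                    ) -> pd.DataFrame:
    """Project cells into the latent space and assign reported clusters.

    Returns the id/flag columns of ``cells`` plus PC1..PCm coordinates
    and a 1-based ``cluster`` column. Assignment is nearest K-means
    center (Euclidean); among equidistant centers the lower *reported*
    cluster index wins.
    """
    X = _matrix_from_cells(cells, transform.feature_names)
    latent = (X - transform.center) @ transform.components.T

    centers = transform.kmeans_centers
    d2 = ((latent[:, None, :] - centers[None]) ** 2).sum(-1)
    reported_of_raw = transform.reported_index()
    # re-order distance columns by reported index so argmin tie-breaks
    # toward the lower reported cluster
    order = list(transform.cluster_order)
    d2_reported = d2[:, order]
    cluster = np.argmin(d2_reported, axis=1) + 1

    out = cells.drop(columns=[c for c in transform.feature_names
                              if c in cells.columns]).copy()
    out = out.reset_index(drop=True)
    for j in range(transform.n_components):
        out[f"PC{j + 1}"] = latent[:, j]
    out["cluster"] = cluster
    return out


def rank_marker_cluster(transform: CohortTransform, latent: np.ndarray,
                        raw_labels: np.ndarray,
                        strategy: str = "pc1_iqr") -> list[int]:
    """Order raw k-means labels into reported clusters 1..k.

    Reported Cluster 1 is the marker cluster under ``strategy``
    (default: greatest within-cluster PC1 interquartile range);
    remaining clusters are ordered by descending size with centroid-PC1
    (descending) as the deterministic tie-break.
    """
    if strategy not in MARKER_RANKING_STRATEGIES:
        raise ValueError(f"unknown marker strategy {strategy!r}")
    k = len(transform.kmeans_centers)
    raw = np.arange(k)
    scores = np.zeros(k)
    global_centroid = latent.mean(axis=0)
    for c in raw:
        pts = latent[raw_labels == c]
        if len(pts) == 0:
            scores[c] = -np.inf
            continue
        if strategy == "pc1_iqr":
            q75, q25 = np.percentile(pts[:, 0], [75, 25])
            scores[c] = q75 - q25
        elif strategy == "pc1_variance":
            scores[c] = pts[:, 0].var()
        else:  # centroid_distance
            scores[c] = np.linalg.norm(
                transform.kmeans_centers[c] - global_centroid)
    sizes = np.bincount(raw_labels, minlength=k)
    centroid_pc1 = transform.kmeans_centers[:, 0]
    # marker first; break marker ties deterministically the same way
    marker = max(raw, key=lambda c: (scores[c], centroid_pc1[c]))
    rest = sorted((c for c in raw if c != marker),
                  key=lambda c: (-sizes[c], -centroid_pc1[c]))
    return [int(marker)] + [int(c) for c in rest]


def patient_matrix(latent_cells: pd.DataFrame, k: int,
                   n_components: int | None = None) -> PatientFeatureMatrix:
    """Cluster-wise PC medians and counts for one patient's cells.

    Empty clusters get count 0 and zero-imputed medians with the
    ``imputed`` flag set; a patient with no cells at all is an error.
    """
    if len(latent_cells) == 0:
        raise ValueError("patient has zero cells")
    pids = latent_cells.get("patient_id")
    if pids is not None and pids.nunique() > 1:
        raise ValueError("latent cells must belong to a single patient")
    if n_components is None:
        n_components = sum(c.startswith("PC") for c in latent_cells.columns)
    pc_cols = [f"PC{j + 1}" for j in range(n_components)]
    pc_center = np.zeros((k, n_components))
    counts = np.zeros(k, dtype=int)
    imputed = np.zeros(k, dtype=bool)
    for c in range(k):
        sub = latent_cells[latent_cells["cluster"] == c + 1]
        counts[c] = len(sub)
        if counts[c] == 0:
            imputed[c] = True
        else:
            pc_center[c] = sub[pc_cols].median().to_numpy()
    return PatientFeatureMatrix(
        patient_id=str(pids.iloc[0]) if pids is not None else "",
        pc_center=pc_center,
        counts=counts,
        total_cells=int(len(latent_cells)),
        imputed=imputed,
    )


def cluster1_pc1_roc(matrices: list[PatientFeatureMatrix],
                     pm_labels: dict[str, str]
                     ) -> tuple[pd.DataFrame, float, float]:
    """ROC over the scalar Cluster1-PC1 patient score.

    Returns (roc table with threshold/sensitivity/specificity columns,
    trapezoid AUC, Youden-optimal threshold; ties resolved toward the
    lower threshold).
    """
    scores = np.array([m.pc_center[0, 0] for m in matrices])
    truth = np.array([pm_labels[m.patient_id] == "POS" for m in matrices])
    if truth.all() or not truth.any():
        raise ValueError("both PM classes must be present")
    thresholds = np.unique(scores)
    rows = []
    for t in thresholds:
        pred = scores >= t
        tp = int((pred & truth).sum())
        fn = int((~pred & truth).sum())
        tn = int((~pred & ~truth).sum())
        fp = int((pred & ~truth).sum())
        rows.append({
            "threshold": t,
            "sensitivity": tp / (tp + fn),
            "specificity": tn / (tn + fp),
        })
    roc = pd.DataFrame(rows)
    # trapezoid AUC over the empirical ROC (add the (0,0)/(1,1) corners)
    fpr = np.r_[1.0, 1.0 - roc["specificity"].to_numpy(), 0.0]
    tpr = np.r_[1.0, roc["sensitivity"].to_numpy(), 0.0]
    order = np.argsort(fpr)
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    youden = roc["sensitivity"] + roc["specificity"] - 1.0
    best = roc.loc[youden == youden.max(), "threshold"].min()
    return roc, auc, float(best)
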