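"""Single-cell feature extraction for three-channel SRS cytology.

Two steps of chemistry and geometry happen here:

* linear two-endmember unmixing of the lipid (2850 cm^-1) and protein
  (2930 cm^-1) detector channels into lipid/protein concentrations
  (C_L, C_P) with a calibration matrix measured on pure oil and BSA;
* extraction of 19 per-cell features — 10 morphology (from the cell
  mask) and 9 composition (from C_L/C_P under cell, cytoplasm and
  lipid-droplet masks) — followed by two-sample t-test selection of the
  features separating PM-positive from PM-negative specimens.

Note on naming: *eccentricity* here is the minor/major axis-length
ratio, as used throughout this pipeline, NOT the conic-section
eccentricity of the fitted ellipse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import measure

from .io import SRSFrame

__all__ = [
    "UnmixMatrix",
    "FeatureSelection",
    "MORPHOLOGY_FEATURES",
    "COMPOSITION_FEATURES",
    "ALL_FEATURES",
    "unmix",
    "morphology_features",
    "composition_features",
    "extract_cells",
    "t_test",
    "select_features",
]

#: 10 morphology features measured on the cell / nucleus masks
MORPHOLOGY_FEATURES = (
    "area",
    "eccentricity",
    "major_axis_length",
    "minor_axis_length",
    "perimeter",
    "solidity",
    "circularity",
    "roundness",
    "cytoplasm_area",
    "cytoplasm_area_fraction",
)

#: 9 composition features measured on unmixed C_L / C_P
COMPOSITION_FEATURES = (
    "lipid_intensity",
    "protein_intensity",
    "lipid_protein_ratio",
    "lipid_intensity_cytoplasm",
    "protein_intensity_cytoplasm",
    "ld_area",
    "ld_number",
    "ld_area_fraction",
    "lipid_intensity_ld",
)

ALL_FEATURES = MORPHOLOGY_FEATURES + COMPOSITION_FEATURES

ID_COLUMNS = ("patient_id", "frame_id", "cell_label")
FLAG_COLUMNS = ("border_touching", "empty_nucleus", "no_ld", "undefined_ratio")

#: calibration measured from pure BSA and oil, arbitrary detector units
DEFAULT_UNMIX_COEFFS = ((1.28583, -0.32401), (-0.13406, 1.28583))


@dataclass
class UnmixMatrix:
    """2x2 linear map from detector signals (S_L, S_P) to (C_L, C_P)."""

    m: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_UNMIX_COEFFS, dtype=float)
    )

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float)
        if self.m.shape != (2, 2):
            raise ValueError("unmix matrix must be 2x2")
        if np.isclose(np.linalg.det(self.m), 0.0):
            raise ValueError("unmix matrix must be invertible")

    @property
    def inverse(self) -> np.ndarray:
        """Forward mixing matrix: maps concentrations to detector signals."""
        return np.linalg.inv(self.m)


def unmix(s_l, s_p, matrix: UnmixMatrix | None = None):
    """Unmix detector signals into (C_L, C_P) concentrations.

    Works elementwise on scalars or equal-shaped arrays. Negative
    outputs are retained, not clipped: they are diagnostic of
    calibration mismatch and average out in mask means.
    """
    if matrix is None:
        matrix = UnmixMatrix()
    s_l = np.asarray(s_l, dtype=float)
    s_p = np.asarray(s_p, dtype=float)
    if s_l.shape != s_p.shape:
        raise ValueError("s_l and s_p must have the same shape")
    m = matrix.m
    c_l = m[0, 0] * s_l + m[0, 1] * s_p
    c_p = m[1, 0] * s_l + m[1, 1] * s_p
    return c_l, c_p


def _region_of(mask: np.ndarray):
    lab = mask.astype(np.uint8)
    regions = measure.regionprops(lab)
    if not regions:
        raise ValueError("empty mask")
    return regions[0]


def _boundary_perimeter(mask: np.ndarray) -> float:
    """Boundary length as the count of exposed pixel edges.

    Exact for axis-aligned rectangles (4*side); a digital disc of
    radius r measures 8r. Chosen as the default because its value on
    simple calibration shapes is an exact closed form.
    """
    padded = np.pad(mask, 1)
    edges = 0
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        edges += int((padded & ~np.roll(padded, shift, axis=axis)).sum())
    return float(edges)


def morphology_features(mask: np.ndarray,
                        perimeter_estimator: str = "boundary"
                        ) -> dict[str, float]:
    """8 base morphology values from a single-cell binary mask.

    area is the pixel count; perimeter is, by default, the exposed
    pixel-edge count (``"crofton"`` and ``"weighted"`` contour
    estimators are available — circularity is estimator-sensitive, see
    the methods note); axis lengths come from the second central
    moments of the region (best-fitting ellipse);
    circularity = 4*pi*area/perimeter^2 and
    roundness = 4*area/(pi*major^2); eccentricity = minor/major.
    Cytoplasm quantities are added by :func:`composition_features`.
    """
    mask = np.asarray(mask).astype(bool)
    region = _region_of(mask)
    area = float(region.area)
    if perimeter_estimator == "boundary":
        perimeter = _boundary_perimeter(mask)
    elif perimeter_estimator == "crofton":
        perimeter = float(region.perimeter_crofton)
    elif perimeter_estimator == "weighted":
        perimeter = float(region.perimeter)
    else:
        raise ValueError(f"unknown perimeter estimator {perimeter_estimator!r}")
    major = float(region.axis_major_length)
    minor = float(region.axis_minor_length)
    solidity = float(region.solidity)
    circularity = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else np.nan
    roundness = 4.0 * area / (np.pi * major**2) if major > 0 else np.nan
    eccentricity = minor / major if major > 0 else np.nan
    return {
        "area": area,
        "eccentricity": eccentricity,
        "major_axis_length": major,
        "minor_axis_length": minor,
        "perimeter": perimeter,
        "solidity": solidity,
        "circularity": circularity,
        "roundness": roundness,
    }


def composition_features(
    frame: SRSFrame,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    ld_mask: np.ndarray,
    matrix: UnmixMatrix | None = None,
    c_l: np.ndarray | None = None,
    c_p: np.ndarray | None = None,
) -> dict[str, float]:
    """Composition features plus cytoplasm areas for one cell.

    Intensity features are per-pixel means over the respective mask
    (size-independent by construction). ``c_l``/``c_p`` may be passed
    to reuse a frame-level unmixing. ``ld_mask`` is a labelled or
    binary map of this cell's lipid droplets.
    """
    cell_mask = np.asarray(cell_mask).astype(bool)
    nucleus_mask = np.asarray(nucleus_mask).astype(bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    if (nucleus_mask & ~cell_mask).any():
        raise ValueError("nucleus mask extends outside the cell mask")
    if c_l is None or c_p is None:
        c_l, c_p = unmix(frame.lipid, frame.protein, matrix)

    area = float(cell_mask.sum())
    cyto_mask = cell_mask & ~nucleus_mask
    cyto_area = float(cyto_mask.sum())

    lipid_intensity = float(c_l[cell_mask].mean())
    protein_intensity = float(c_p[cell_mask].mean())
    undefined_ratio = protein_intensity == 0.0
    ratio = np.nan if undefined_ratio else lipid_intensity / protein_intensity

    if cyto_mask.any():
        lipid_cyto = float(c_l[cyto_mask].mean())
        protein_cyto = float(c_p[cyto_mask].mean())
    else:  # nucleus fills the whole cell
        lipid_cyto = 0.0
        protein_cyto = 0.0

    ld_labels = np.asarray(ld_mask)
    ld_in_cell = ld_labels * cell_mask if ld_labels.dtype != bool else ld_labels & cell_mask
    ld_binary = ld_in_cell.astype(bool)
    ld_area = float(ld_binary.sum())
    if ld_area:
        if np.issubdtype(ld_labels.dtype, np.integer):
            ld_number = int(len(np.unique(ld_in_cell[ld_in_cell > 0])))
        else:
            ld_number = int(measure.label(ld_binary).max())
        lipid_ld = float(c_l[ld_binary].mean())
        no_ld = False
    else:
        ld_number = 0
        lipid_ld = 0.0
        no_ld = True

    return {
        "cytoplasm_area": cyto_area,
        "cytoplasm_area_fraction": cyto_area / area,
        "lipid_intensity": lipid_intensity,
        "protein_intensity": protein_intensity,
        "lipid_protein_ratio": ratio,
        "lipid_intensity_cytoplasm": lipid_cyto,
        "protein_intensity_cytoplasm": protein_cyto,
        "ld_area": ld_area,
        "ld_number": ld_number,
        "ld_area_fraction": ld_area / area,
        "lipid_intensity_ld": lipid_ld,
        "no_ld": no_ld,
        "undefined_ratio": undefined_ratio,
    }


def extract_cells(frame: SRSFrame, segmentation, matrix: UnmixMatrix | None = None,
                  patient_id: str = "") -> pd.DataFrame:
    """One row of 19 features per segmented cell in a frame.

    ``segmentation`` is a :class:`srmc.segment.SegmentationResult`
    (or any object with ``cells``/``nuclei``/``lds`` label maps and
    optional ``border_labels``). Rows are ordered by cell label.
    """
    cells = segmentation.cells.labels
    nuclei = segmentation.nuclei.labels
    lds = segmentation.lds.labels
    border = set(getattr(segmentation, "border_labels", ()) or ())
    c_l, c_p = unmix(frame.lipid, frame.protein, matrix)

    rows = []
    for label in np.unique(cells):
        if label == 0:
            continue
        cell_mask = cells == label
        nucleus_mask = (nuclei == label) & cell_mask
        ld_local = np.where(cell_mask, lds, 0)
        row: dict = {
            "patient_id": patient_id,
            "frame_id": frame.frame_id,
            "cell_label": int(label),
        }
        row.update(morphology_features(cell_mask))
        comp = composition_features(
            frame, cell_mask, nucleus_mask, ld_local, matrix, c_l=c_l, c_p=c_p
        )
        no_ld = comp.pop("no_ld")
        undefined_ratio = comp.pop("undefined_ratio")
        row.update(comp)
        row["border_touching"] = int(label) in border
        row["empty_nucleus"] = not nucleus_mask.any()
        row["no_ld"] = no_ld
        row["undefined_ratio"] = undefined_ratio
        rows.append(row)

    columns = list(ID_COLUMNS) + list(ALL_FEATURES) + list(FLAG_COLUMNS)
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns]


def t_test(group_a, group_b) -> tuple[float, float]:
    """Pooled-variance two-sample Student t-test, two-sided.

    t = (x̄₁ − x̄₂) / sqrt(s²·(1/n₁ + 1/n₂)) with the pooled variance
    s² on n₁+n₂−2 degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    s2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if s2 <= 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return float(t), float(p)


@dataclass
class FeatureSelection:
    """Per-feature t/p statistics and the selected feature list."""

    table: pd.DataFrame  # columns: feature, t_value, p_value
    selected: list[str]
    alpha: float
    dropped_constant: list[str] = field(default_factory=list)
    n_cells_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "selected": list(self.selected),
            "dropped_constant": list(self.dropped_constant),
            "n_cells_dropped": self.n_cells_dropped,
            "table": self.table.to_dict(orient="records"),
        }


def select_features(
    cells: pd.DataFrame,
    pm_labels: dict[str, str],
    alpha: float = 0.05,
    features=ALL_FEATURES,
    per_patient_mean: bool = False,
) -> FeatureSelection:
    """t-test every feature between PM+ and PM− cells; keep p < alpha.

    Cells are pooled across patients within each PM class (default), or
    reduced to per-patient means first with ``per_patient_mean``. Cells
    with an undefined lipid/protein ratio are dropped and counted. No
    multiple-testing correction is applied.
    """
    labels = cells["patient_id"].map(pm_labels)
    keep = labels.isin(["POS", "NEG"])
    if "undefined_ratio" in cells:
        keep &= ~cells["undefined_ratio"].astype(bool)
    n_dropped = int(len(cells) - keep.sum())
    data = cells.loc[keep]
    labels = labels.loc[keep]
    if not ((labels == "POS").any() and (labels == "NEG").any()):
        raise ValueError("both PM classes must be represented")

    if per_patient_mean:
        grouped = data.groupby("patient_id")[list(features)].mean()
        glabels = grouped.index.map(pm_labels)
        pos = grouped[glabels == "POS"]
        neg = grouped[glabels == "NEG"]
    else:
        pos = data.loc[labels == "POS", list(features)]
        neg = data.loc[labels == "NEG", list(features)]

    rows, selected, dropped = [], [], []
    for feat in features:
        a = pos[feat].to_numpy(dtype=float)
        b = neg[feat].to_numpy(dtype=float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        pooled = np.concatenate([a, b])
        if len(a) < 2 or len(b) < 2 or np.allclose(pooled, pooled[0]):
            dropped.append(feat)
            warnings.warn(f"feature {feat!r} constant or degenerate; excluded")
            rows.append({"feature": feat, "t_value": np.nan, "p_value": np.nan})
            continue
        t, p = t_test(a, b)
        rows.append({"feature": feat, "t_value": t, "p_value": p})
        if p < alpha:
            selected.append(feat)

    return FeatureSelection(
        table=pd.DataFrame(rows),
        selected=selected,
        alpha=alpha,
        dropped_constant=dropped,
        n_cells_dropped=n_dropped,
    )
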