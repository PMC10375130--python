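"""Single-cell, nucleus and lipid-droplet segmentation plus evaluation.

Cells are segmented from the DNA (2965 cm^-1) channel. The built-in
baseline is classical: Gaussian smoothing, Otsu foreground, distance-
transform peaks as markers, marker-controlled watershed. A pre-trained
deep model (e.g. StarDist) can be registered as a plug-in backend
behind the same contract; requesting an unregistered backend is an
explicit capability error, never a silent fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation as skseg

from .io import LabelMap, SRSFrame

__all__ = [
    "SegmentationResult",
    "SegEval",
    "CapabilityError",
    "register_backend",
    "segment_cells",
    "segment_nuclei",
    "segment_lds",
    "segment_frame",
    "dice",
    "iou",
    "count_rmse",
]


class CapabilityError(RuntimeError):
    """A requested segmentation backend is not available."""


#: plug-in registry: name -> callable(dna_image, **params) -> label array
_BACKENDS: dict[str, callable] = {}


def register_backend(name: str, fn) -> None:
    _BACKENDS[name] = fn


@dataclass
class SegmentationResult:
    """Cell, nucleus and LD label maps for one frame.

    Nuclei inherit their cell's label; LDs carry their own labels and
    ``ld_owner`` maps each LD label to its owning cell.
    """

    cells: LabelMap
    nuclei: LabelMap
    lds: LabelMap
    method: str = "baseline"
    params: dict = field(default_factory=dict)
    border_labels: tuple[int, ...] = ()
    empty_nucleus_labels: tuple[int, ...] = ()
    ld_owner: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cells = self.cells.labels
        nuc = self.nuclei.labels
        lds = self.lds.labels
        if not (cells.shape == nuc.shape == lds.shape):
            raise ValueError("label maps must share one shape")
        if ((nuc > 0) & (cells == 0)).any():
            raise ValueError("nucleus pixels outside cell masks")
        if ((nuc > 0) & (nuc != cells)).any():
            raise ValueError("nucleus labels must inherit cell labels")
        if ((lds > 0) & (cells == 0)).any():
            raise ValueError("LD pixels outside cell masks")


@dataclass
class SegEval:
    """Overlap and counting agreement between two segmentations."""

    dice: float
    iou: float
    count_rmse: float
    count_rrse_percent: float


def segment_cells(dna: np.ndarray, method: str = "baseline",
                  params: dict | None = None) -> tuple[LabelMap, tuple[int, ...]]:
    """Segment cells from the DNA channel.

    Returns the label map and the labels of regions touching the frame
    border (kept, but flagged for optional downstream exclusion).
    Baseline params: sigma (smoothing, px), min_area (px), min_distance
    (marker separation, px).
    """
    dna = np.asarray(dna, dtype=float)
    if dna.ndim != 2 or not np.all(np.isfinite(dna)):
        raise ValueError("dna must be a finite 2-D image")
    params = dict(params or {})
    if method == "baseline":
        labels = _baseline_segment(dna, **params)
    elif method in _BACKENDS:
        labels = np.asarray(_BACKENDS[method](dna, **params)).astype(np.int64)
    else:
        raise CapabilityError(
            f"segmentation backend {method!r} is not registered; "
            "available: baseline" + ("," + ",".join(_BACKENDS) if _BACKENDS else "")
        )
    labels = _filter_small(labels, params.get("min_area", 50))
    border = _border_labels(labels)
    return LabelMap(labels=labels, kind="cell"), border


def _baseline_segment(dna: np.ndarray, sigma: float = 2.0, min_area: int = 50,
                      min_distance: int = 12) -> np.ndarray:
    smoothed = filters.gaussian(dna, sigma=sigma)
    if np.allclose(smoothed, smoothed.flat[0]):
        return np.zeros(dna.shape, dtype=np.int64)
    # cells are brighter than background but dimmer than their nuclei:
    # take the lowest of the 3-class multi-Otsu thresholds so the whole
    # cell, not just the nucleus, becomes foreground
    try:
        thresh = filters.threshold_multiotsu(smoothed, classes=3)[0]
    except ValueError:  # too few distinct grey levels
        thresh = filters.threshold_otsu(smoothed)
    fg = smoothed > thresh
    fg = morphology.remove_small_holes(fg, max_size=64)
    fg = morphology.remove_small_objects(fg, max_size=min_area - 1)
    if not fg.any():
        return np.zeros(dna.shape, dtype=np.int64)
    distance = ndi.distance_transform_edt(fg)
    distance_s = filters.gaussian(distance, sigma=2.0)
    coords = feature.peak_local_max(
        distance_s, min_distance=min_distance, labels=fg, exclude_border=False
    )
    markers = np.zeros(dna.shape, dtype=np.int64)
    for i, (r, c) in enumerate(coords, start=1):
        markers[r, c] = i
    if markers.max() == 0:
        return measure.label(fg).astype(np.int64)
    labels = skseg.watershed(-distance, markers=markers, mask=fg)
    return labels.astype(np.int64)


def _filter_small(labels: np.ndarray, min_area: int) -> np.ndarray:
    out = morphology.remove_small_objects(labels, max_size=min_area - 1)
    return skseg.relabel_sequential(out)[0].astype(np.int64)


def _border_labels(labels: np.ndarray) -> tuple[int, ...]:
    edge = np.concatenate(
        [labels[0], labels[-1], labels[:, 0], labels[:, -1]]
    )
    return tuple(int(v) for v in np.unique(edge) if v > 0)


def segment_nuclei(frame: SRSFrame, cells: LabelMap,
                   alpha: float = 0.0) -> tuple[LabelMap, tuple[int, ...]]:
    """Per-cell adaptive (Otsu-within-mask) nucleus segmentation.

    Thresholds a DNA-specific image (DNA channel minus ``alpha`` times
    the lipid channel) inside each cell mask; the largest above-
    threshold component becomes the nucleus, inheriting the cell label.
    Cells with no usable threshold are flagged (empty nucleus), which
    is an outcome, not an error.
    """
    dna_specific = frame.dna - alpha * frame.lipid
    labels = cells.labels
    out = np.zeros_like(labels)
    empty: list[int] = []
    for region in measure.regionprops(labels):
        label = region.label
        sl = region.slice
        mask = labels[sl] == label
        values = dna_specific[sl][mask]
        if values.max() - values.min() < 1e-12:
            empty.append(label)
            continue
        thresh = filters.threshold_otsu(values)
        nuc = np.zeros_like(mask)
        nuc[mask] = dna_specific[sl][mask] > thresh
        if not nuc.any():
            empty.append(label)
            continue
        comp = measure.label(nuc)
        largest = np.argmax(np.bincount(comp.ravel())[1:]) + 1
        out[sl][comp == largest] = label
    return LabelMap(labels=out, kind="nucleus"), tuple(empty)


def segment_lds(lipid_intensity: np.ndarray, cells: LabelMap,
                percentile: float = 98.0, min_area: int = 2
                ) -> tuple[LabelMap, dict[int, int]]:
    """Detect lipid droplets as bright foci of the unmixed C_L image.

    The threshold is one per image: the given percentile of C_L over
    all within-cell pixels. Connected components of at least
    ``min_area`` px become LDs, each assigned to the cell containing
    its centroid. Returns the LD label map and an LD->cell owner map.
    """
    if not (50.0 < percentile < 100.0):
        raise ValueError("percentile must lie in (50, 100)")
    c_l = np.asarray(lipid_intensity, dtype=float)
    labels = cells.labels
    inside = labels > 0
    empty = LabelMap(labels=np.zeros_like(labels), kind="lipid_droplet")
    if not inside.any():
        return empty, {}
    thresh = np.percentile(c_l[inside], percentile)
    candidates = measure.label((c_l > thresh) & inside)
    out = np.zeros_like(labels)
    owner: dict[int, int] = {}
    next_label = 1
    for region in measure.regionprops(candidates):
        if region.area < min_area:
            continue
        r, c = (int(round(x)) for x in region.centroid)
        cell = int(labels[r, c])
        if cell == 0:
            continue
        # clip the LD to its owning cell so containment holds
        sl = region.slice
        ld_mask = (candidates[sl] == region.label) & (labels[sl] == cell)
        if ld_mask.sum() < min_area:
            continue
        out[sl][ld_mask] = next_label
        owner[next_label] = cell
        next_label += 1
    return LabelMap(labels=out, kind="lipid_droplet"), owner


def segment_frame(frame: SRSFrame, method: str = "baseline",
                  params: dict | None = None, nucleus_alpha: float = 0.0,
                  ld_percentile: float = 98.0, ld_min_area: int = 2,
                  unmix_matrix=None) -> SegmentationResult:
    """Full per-frame segmentation: cells, nuclei, lipid droplets."""
    from .features import unmix

    cells, border = segment_cells(frame.dna, method=method, params=params)
    nuclei, empty = segment_nuclei(frame, cells)
    c_l, _ = unmix(frame.lipid, frame.protein, unmix_matrix)
    lds, owner = segment_lds(c_l, cells, percentile=ld_percentile,
                             min_area=ld_min_area)
    return SegmentationResult(
        cells=cells, nuclei=nuclei, lds=lds, method=method,
        params=dict(params or {}), border_labels=border,
        empty_nucleus_labels=empty, ld_owner=owner,
    )


def _as_bool(mask) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def dice(a, b) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def iou(a, b) -> float:
    """Intersection over union; 1.0 when both masks are empty."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def count_rmse(pred_counts, true_counts, relative: bool = False) -> float:
    """Root-mean-square cell-counting error across frames.

    Plain mode: sqrt(mean((n_pred - n_true)^2)). Relative mode divides
    each difference by its true count and reports percent.
    """
    pred = np.asarray(pred_counts, dtype=float)
    true = np.asarray(true_counts, dtype=float)
    if pred.shape != true.shape or pred.size == 0:
        raise ValueError("count lists must be equal-length and non-empty")
    diff = pred - true
    if relative:
        if np.any(true == 0):
            raise ValueError("relative mode undefined when a true count is 0")
        diff = diff / true
        return float(np.sqrt(np.mean(diff**2)) * 100.0)
    return float(np.sqrt(np.mean(diff**2)))


def count_rrse_pooled(pred_counts, true_counts) -> float:
    """Alternative relative error: RMSE divided by the mean true count, %."""
    true = np.asarray(true_counts, dtype=float)
    if true.mean() == 0:
        raise ValueError("mean true count is 0")
    return float(count_rmse(pred_counts, true_counts) / true.mean() * 100.0)
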