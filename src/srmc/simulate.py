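"""Synthetic three-channel cytology cohorts with exact ground truth.

The generator emulates smears of exfoliated cells from peritoneal
lavage as seen by three-color SRS imaging: elliptical cells with a
DNA-bright nucleus, a protein-dominated cytoplasm, and bright lipid
droplets in the lipid channel. Three phenotypes are modelled —
*epithelial* and *mesothelial* normal cells and a tumor-like *marker*
phenotype that is larger, lipid-rich, protein-rich, droplet-rich and
boundary-irregular. PM-positive patients carry a higher marker
fraction, and their marker cells additionally receive an upward
half-normal excursion in log feature space (pleomorphism), which
widens the within-patient dispersion of the marker population; that
divergence is the diagnostic signal the downstream analysis is built
to recover.

Channel formation is the exact inverse of the unmixing step: planted
concentrations (C_L, C_P) are pushed through the inverse calibration
matrix to detector signals (S_L, S_P), so unmixing a noise-free frame
recovers the planted chemistry to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .features import UnmixMatrix
from .io import (
    CohortManifest,
    LabelMap,
    PatientEntry,
    SRSFrame,
    write_frame,
    write_label_map,
    write_manifest,
)

__all__ = [
    "PhenotypeSpec",
    "CohortSpec",
    "FrameTruth",
    "CapacityError",
    "default_phenotypes",
    "render_cell",
    "generate_frame",
    "generate_cohort",
    "iter_cohort",
    "simulate_cohort_cells",
]

FRAME_SHAPE = (400, 400)

#: the 12 features in which the marker phenotype is constructed to
#: diverge from the normal phenotypes (7 morphology + 5 composition)
MARKER_DIVERGENT_FEATURES = (
    "area",
    "major_axis_length",
    "minor_axis_length",
    "perimeter",
    "solidity",
    "cytoplasm_area",
    "roundness",
    "protein_intensity",
    "lipid_protein_ratio",
    "lipid_intensity_cytoplasm",
    "protein_intensity_cytoplasm",
    "ld_number",
)


class CapacityError(RuntimeError):
    """Requested cells cannot be placed in the frame without overlap."""


@dataclass
class PhenotypeSpec:
    """Distributional description of one cell phenotype.

    Areas are log-normal in px^2; the minor/major axis ratio and the
    nucleus area fraction are uniform on their ranges; channel levels
    are planted concentrations in detector units with log-normal
    per-cell jitter of coefficient ``intensity_cv``; lipid droplets are
    Poisson in number with uniform radii.
    """

    name: str
    area_log_mean: float
    area_log_sd: float
    axis_ratio_range: tuple[float, float] = (0.65, 0.95)
    nucleus_fraction_range: tuple[float, float] = (0.25, 0.40)
    lipid_level: float = 0.5
    protein_level: float = 1.2
    dna_cytoplasm_level: float = 0.4
    dna_nucleus_level: float = 1.2
    intensity_cv: float = 0.12
    ld_count_mean: float = 2.0
    ld_radius_range: tuple[float, float] = (2.2, 3.4)
    ld_amplitude: float = 5.0
    boundary_waviness: float = 0.04
    placement_overlap: float = 0.0  # allowed cell-cell contact fraction

    def __post_init__(self) -> None:
        if self.area_log_sd <= 0 or np.exp(self.area_log_mean) <= 0:
            raise ValueError("area distribution must yield positive samples")
        lo, hi = self.nucleus_fraction_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("nucleus_fraction must lie in (0, 1)")
        if self.ld_radius_range[0] < 1.0:
            raise ValueError("LD radii must be at least 1 px")
        if not (0.0 < self.axis_ratio_range[0] <= self.axis_ratio_range[1] <= 1.0):
            raise ValueError("axis ratio range must lie in (0, 1]")
        if not (0.0 <= self.placement_overlap < 1.0):
            raise ValueError("placement_overlap must lie in [0, 1)")


def default_phenotypes() -> dict[str, PhenotypeSpec]:
    """The stylized study conditions: two normal phenotypes + marker."""
    return {
        "epithelial": PhenotypeSpec(
            name="epithelial", area_log_mean=np.log(1100.0), area_log_sd=0.16,
            lipid_level=0.45, protein_level=1.10, ld_count_mean=1.5,
        ),
        "mesothelial": PhenotypeSpec(
            name="mesothelial", area_log_mean=np.log(2000.0), area_log_sd=0.16,
            lipid_level=0.55, protein_level=1.25, ld_count_mean=2.0,
        ),
        "marker": PhenotypeSpec(
            name="marker", area_log_mean=np.log(4500.0), area_log_sd=0.20,
            axis_ratio_range=(0.55, 0.88),  # tumor cells are more elongated
            lipid_level=0.95, protein_level=1.60, ld_count_mean=6.0,
            boundary_waviness=0.12,
        ),
    }


@dataclass
class CohortSpec:
    """Cohort-level structure of a synthetic study.

    ``marker_divergence_scale`` > 1 adds, to each marker cell of a
    PM-positive patient, an upward half-normal excursion in log space
    of scale (s-1)*sigma on area and (s-1)*cv on channel levels; this
    widens the within-patient marker dispersion and vanishes at s=1.
    """

    n_pos: int = 10
    n_neg: int = 16
    frames_per_patient: int = 42
    cells_per_frame_mean: float = 12.0
    marker_fraction_pos: float = 0.15
    marker_fraction_neg: float = 0.02
    marker_divergence_scale: float = 2.5
    noise_sd: float = 0.02
    seed: int = 0
    epithelial_fraction: float = 0.45  # of the non-marker cells
    phenotypes: dict[str, PhenotypeSpec] = field(default_factory=default_phenotypes)
    frame_shape: tuple[int, int] = FRAME_SHAPE
    allow_null: bool = False  # permit signal-free cohorts (null studies)

    def __post_init__(self) -> None:
        for f in (self.marker_fraction_pos, self.marker_fraction_neg,
                  self.epithelial_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if not self.allow_null and not (
                self.marker_fraction_pos > self.marker_fraction_neg
                or self.marker_divergence_scale > 1.0):
            raise ValueError(
                "spec carries no recoverable signal: need marker_fraction_pos > "
                "marker_fraction_neg or marker_divergence_scale > 1 "
                "(or set allow_null=True for a deliberate null cohort)"
            )
        if self.marker_divergence_scale < 1.0:
            raise ValueError("marker_divergence_scale must be >= 1")

    def patient_ids(self) -> list[tuple[str, str]]:
        return (
            [(f"POS{i + 1:02d}", "POS") for i in range(self.n_pos)]
            + [(f"NEG{i + 1:02d}", "NEG") for i in range(self.n_neg)]
        )


@dataclass
class CellSprite:
    """A rendered cell: local masks, concentration patches, truth."""

    cell_mask: np.ndarray       # bool, patch-local
    nucleus_mask: np.ndarray
    ld_labels: np.ndarray       # int, patch-local LD labels
    c_l: np.ndarray             # planted lipid concentration patch
    c_p: np.ndarray
    dna: np.ndarray
    truth: dict


def _half_normal_excursion(rng, scale: float, n: int = 1) -> np.ndarray:
    if scale <= 0:
        return np.zeros(n)
    return np.abs(rng.normal(0.0, scale, n))


def render_cell(phenotype: PhenotypeSpec, rng: np.random.Generator,
                divergence: float = 1.0) -> CellSprite:
    """Render one cell sprite on its own patch grid.

    Degenerate geometry (a semi-axis below 2 px) is resampled
    internally and never emitted. ``divergence`` >= 1 applies the
    PM-linked half-normal upward excursion to area and channel levels.
    """
    p = phenotype
    tau_area = (divergence - 1.0) * p.area_log_sd
    tau_int = (divergence - 1.0) * p.intensity_cv
    for _ in range(64):
        area = np.exp(rng.normal(p.area_log_mean, p.area_log_sd)
                      + _half_normal_excursion(rng, tau_area)[0])
        ratio = rng.uniform(*p.axis_ratio_range)
        a = np.sqrt(area / (np.pi * ratio))  # semi-major, px
        b = a * ratio
        if b >= 2.0:
            break
    else:
        raise ValueError("phenotype yields degenerate ellipses")
    theta0 = rng.uniform(0.0, np.pi)
    nf = rng.uniform(*p.nucleus_fraction_range)

    jit = np.exp(rng.normal(0.0, p.intensity_cv, 2)
                 + _half_normal_excursion(rng, tau_int, 2))
    lipid_level = p.lipid_level * jit[0]
    protein_level = p.protein_level * jit[1]

    half = int(np.ceil(a * (1.0 + 2.5 * p.boundary_waviness))) + 3
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(float)
    ct, st = np.cos(theta0), np.sin(theta0)
    u = ct * xx + st * yy       # along major axis
    v = -st * xx + ct * yy
    rho = np.hypot(u, v)
    ang = np.arctan2(v, u)

    r_ell = a * b / np.sqrt((b * np.cos(ang)) ** 2 + (a * np.sin(ang)) ** 2)
    if p.boundary_waviness > 0:
        ks = np.array([3, 4, 5])
        amps = rng.dirichlet(np.ones(len(ks)))
        amps = np.sqrt(amps)  # unit Euclidean norm across modes
        phases = rng.uniform(0, 2 * np.pi, len(ks))
        wav = sum(amp * np.cos(k * ang + ph)
                  for amp, k, ph in zip(amps, ks, phases))
        boundary = r_ell * (1.0 + p.boundary_waviness * wav)
    else:
        boundary = r_ell
    cell_mask = rho <= boundary

    scale_n = np.sqrt(nf)
    nucleus_mask = ((u / (a * scale_n)) ** 2 + (v / (b * scale_n)) ** 2) <= 1.0
    nucleus_mask &= cell_mask

    ld_count = int(rng.poisson(p.ld_count_mean))
    ld_labels = np.zeros(cell_mask.shape, dtype=np.int32)
    lipid_extra = np.zeros(cell_mask.shape)
    cyto = cell_mask & ~nucleus_mask
    cyto_idx = np.flatnonzero(cyto)
    placed = 0
    if ld_count > 0 and cyto_idx.size:
        order = rng.permutation(cyto_idx)
        ptr = 0
        while placed < ld_count and ptr < order.size:
            idx = order[ptr]
            ptr += 1
            cy, cx = np.unravel_index(idx, cell_mask.shape)
            radius = rng.uniform(*p.ld_radius_range)
            d2 = (yy - (cy - half)) ** 2 + (xx - (cx - half)) ** 2
            disc = (d2 <= radius**2) & cell_mask
            if (ld_labels[disc] > 0).any() or not disc.any():
                continue
            placed += 1
            ld_labels[disc] = placed
            sigma = radius / 1.6
            lipid_extra += p.ld_amplitude * np.exp(-d2 / (2 * sigma**2)) * cell_mask

    c_l = (lipid_level * cell_mask).astype(float) + lipid_extra
    c_p = (protein_level * cell_mask).astype(float)
    dna = (p.dna_cytoplasm_level * cell_mask).astype(float)
    dna[nucleus_mask] = p.dna_nucleus_level

    mask_area = int(cell_mask.sum())
    truth = {
        "phenotype": p.name,
        "is_marker": p.name == "marker",
        "area": mask_area,
        "major_axis_length": 2.0 * a,
        "minor_axis_length": 2.0 * b,
        "axis_ratio": ratio,
        "orientation": theta0,
        "nucleus_area": int(nucleus_mask.sum()),
        "nucleus_fraction": nf,
        "ld_number": placed,
        "ld_area": int((ld_labels > 0).sum()),
        "lipid_level": lipid_level,
        "protein_level": protein_level,
        "lipid_intensity": float(c_l[cell_mask].mean()),
        "protein_intensity": float(c_p[cell_mask].mean()),
    }
    return CellSprite(cell_mask, nucleus_mask, ld_labels, c_l, c_p, dna, truth)


@dataclass
class FrameTruth:
    """A generated frame with its exact ground-truth segmentation."""

    frame: SRSFrame
    cells: LabelMap
    nuclei: LabelMap
    lds: LabelMap
    table: pd.DataFrame  # one row per cell, truth columns + cell_label


def generate_frame(
    n_cells: int,
    mixture: list[tuple[PhenotypeSpec, float, float]],
    noise_sd: float,
    rng: np.random.Generator,
    shape: tuple[int, int] = FRAME_SHAPE,
    frame_id: str = "frame",
    pixel_size_um: float = 0.25,
    unmix_matrix: UnmixMatrix | None = None,
    max_tries_per_cell: int = 200,
) -> FrameTruth:
    """Render a full frame of ``n_cells`` cells.

    ``mixture`` is a list of (phenotype, weight, divergence) triples;
    weights are normalized. Cells are placed without overlap (up to the
    phenotype's ``placement_overlap`` contact fraction); an overfull
    frame raises :class:`CapacityError`. Gaussian noise of sd
    ``noise_sd`` is added to all three detector channels.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    matrix = unmix_matrix or UnmixMatrix()
    mix_inv = matrix.inverse  # concentrations -> detector signals
    h, w = shape
    c_l = np.zeros(shape)
    c_p = np.zeros(shape)
    dna = np.zeros(shape)
    cells = np.zeros(shape, dtype=np.int32)
    nuclei = np.zeros(shape, dtype=np.int32)
    lds = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)

    weights = np.array([m[1] for m in mixture], dtype=float)
    if n_cells and (weights.sum() <= 0 or len(mixture) == 0):
        raise ValueError("mixture weights must be positive")
    if weights.sum() > 0:
        weights = weights / weights.sum()

    rows = []
    ld_next = 0
    # render every sprite up front and place largest-first: big cells go
    # into the emptiest frame, which keeps the failure rate negligible
    # at realistic densities while still erroring on overfull requests
    rendered = []
    for _ in range(n_cells):
        pick = rng.choice(len(mixture), p=weights)
        phenotype, _, divergence = mixture[pick]
        sprite = render_cell(phenotype, rng, divergence=divergence)
        if sprite.cell_mask.shape[0] > h or sprite.cell_mask.shape[1] > w:
            raise CapacityError("cell sprite larger than the frame")
        rendered.append((phenotype, sprite))
    order = sorted(range(n_cells),
                   key=lambda i: -int(rendered[i][1].cell_mask.sum()))

    for label, idx in enumerate(order, start=1):
        phenotype, sprite = rendered[idx]
        ph, pw = sprite.cell_mask.shape
        half_h, half_w = ph // 2, pw // 2
        placed = False
        for _ in range(max_tries_per_cell):
            cy = rng.integers(half_h, h - (ph - half_h))
            cx = rng.integers(half_w, w - (pw - half_w))
            sl = (slice(cy - half_h, cy - half_h + ph),
                  slice(cx - half_w, cx - half_w + pw))
            overlap = (occupied[sl] & sprite.cell_mask).sum()
            if overlap <= phenotype.placement_overlap * sprite.cell_mask.sum():
                placed = True
                break
        if not placed:
            raise CapacityError(
                f"could not place cell {label}/{n_cells} after "
                f"{max_tries_per_cell} tries"
            )
        m = sprite.cell_mask
        cells[sl][m] = label
        nuclei[sl][sprite.nucleus_mask] = label
        ld_patch = sprite.ld_labels
        lds[sl][ld_patch > 0] = ld_patch[ld_patch > 0] + ld_next
        ld_next += sprite.truth["ld_number"]
        c_l[sl][m] = sprite.c_l[m]
        c_p[sl][m] = sprite.c_p[m]
        dna[sl][m] = sprite.dna[m]
        # keep a 2-px moat so touching is controlled by placement_overlap
        from scipy import ndimage as ndi
        pad = 2
        grown = ndi.binary_dilation(np.pad(m, pad), iterations=pad)
        gr0 = max(sl[0].start - pad, 0)
        gc0 = max(sl[1].start - pad, 0)
        gr1 = min(sl[0].stop + pad, h)
        gc1 = min(sl[1].stop + pad, w)
        occupied[gr0:gr1, gc0:gc1] |= grown[
            gr0 - (sl[0].start - pad):gr1 - (sl[0].start - pad),
            gc0 - (sl[1].start - pad):gc1 - (sl[1].start - pad)]
        row = dict(sprite.truth)
        row["cell_label"] = label
        row["center_y"], row["center_x"] = int(cy), int(cx)
        rows.append(row)

    s_l = mix_inv[0, 0] * c_l + mix_inv[0, 1] * c_p
    s_p = mix_inv[1, 0] * c_l + mix_inv[1, 1] * c_p
    if noise_sd > 0:
        s_l = s_l + rng.normal(0.0, noise_sd, shape)
        s_p = s_p + rng.normal(0.0, noise_sd, shape)
        dna = dna + rng.normal(0.0, noise_sd, shape)

    frame = SRSFrame(lipid=s_l, protein=s_p, dna=dna,
                     pixel_size_um=pixel_size_um, frame_id=frame_id)
    table = pd.DataFrame(rows) if rows else pd.DataFrame(
        columns=["phenotype", "is_marker", "area", "cell_label"])
    return FrameTruth(
        frame=frame,
        cells=LabelMap(cells, kind="cell"),
        nuclei=LabelMap(nuclei, kind="nucleus"),
        lds=LabelMap(lds, kind="lipid_droplet"),
        table=table,
    )


def _patient_rng(spec: CohortSpec, index: int) -> np.random.Generator:
    # per-patient substream: reproducible independently of other patients
    return np.random.default_rng([spec.seed, index])


def _patient_mixture(spec: CohortSpec, pm_label: str):
    mf = (spec.marker_fraction_pos if pm_label == "POS"
          else spec.marker_fraction_neg)
    div = spec.marker_divergence_scale if pm_label == "POS" else 1.0
    ph = spec.phenotypes
    normal = 1.0 - mf
    return [
        (ph["marker"], mf, div),
        (ph["epithelial"], normal * spec.epithelial_fraction, 1.0),
        (ph["mesothelial"], normal * (1.0 - spec.epithelial_fraction), 1.0),
    ]


def iter_cohort(spec: CohortSpec):
    """Yield (patient_id, pm_label, frame_index, FrameTruth) lazily."""
    for index, (pid, pm) in enumerate(spec.patient_ids()):
        rng = _patient_rng(spec, index)
        mixture = _patient_mixture(spec, pm)
        for f in range(spec.frames_per_patient):
            n = int(rng.poisson(spec.cells_per_frame_mean))
            ft = generate_frame(
                n, mixture, spec.noise_sd, rng, shape=spec.frame_shape,
                frame_id=f"{pid}_f{f:03d}",
            )
            yield pid, pm, f, ft


def generate_cohort(spec: CohortSpec, out_dir) -> CohortManifest:
    """Write a full cohort to disk: frames, truth label maps, truth CSV,
    and a YAML manifest. Returns the manifest."""
    out = Path(out_dir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    entries: dict[str, PatientEntry] = {
        pid: PatientEntry(patient_id=pid, pm_label=pm)
        for pid, pm in spec.patient_ids()
    }
    truth_rows = []
    for pid, pm, f, ft in iter_cohort(spec):
        frame_path = out / "frames" / f"{ft.frame.frame_id}.tiff"
        write_frame(ft.frame, frame_path)
        write_label_map(ft.cells, out / "truth" / f"{ft.frame.frame_id}_cells.tiff")
        write_label_map(ft.nuclei, out / "truth" / f"{ft.frame.frame_id}_nuclei.tiff")
        write_label_map(ft.lds, out / "truth" / f"{ft.frame.frame_id}_lds.tiff")
        # manifest stores paths relative to its own directory
        entries[pid].frame_paths.append(str(frame_path.relative_to(out)))
        t = ft.table.copy()
        t["patient_id"] = pid
        t["frame_id"] = ft.frame.frame_id
        truth_rows.append(t)
    manifest = CohortManifest(patients=list(entries.values()))
    write_manifest(manifest, out / "manifest.yaml")
    if truth_rows:
        pd.concat(truth_rows, ignore_index=True).to_csv(
            out / "truth" / "cells_truth.csv", index=False)
    return manifest


def simulate_cohort_cells(spec: CohortSpec, progress: bool = False
                          ) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Generate a cohort in memory and extract the 19-feature table.

    Features are extracted with :func:`srmc.features.extract_cells`
    from the ground-truth segmentation of each frame (no frames are
    kept). Returns (cells, pm_labels, truth) where truth carries the
    per-cell phenotype identity aligned with the cell table.
    """
    from .features import extract_cells
    from .segment import SegmentationResult

    cells_tables, truth_tables = [], []
    pm_labels: dict[str, str] = {}
    for pid, pm, f, ft in iter_cohort(spec):
        pm_labels[pid] = pm
        seg = SegmentationResult(
            cells=ft.cells, nuclei=ft.nuclei, lds=ft.lds, method="truth")
        cells_tables.append(extract_cells(ft.frame, seg, patient_id=pid))
        t = ft.table.copy()
        t["patient_id"] = pid
        t["frame_id"] = ft.frame.frame_id
        truth_tables.append(t)
    cells = pd.concat(cells_tables, ignore_index=True)
    truth = pd.concat(truth_tables, ignore_index=True)
    return cells, pm_labels, truth
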