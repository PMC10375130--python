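"""Shared fixtures: synthetic frames and cohorts at several scales.

Everything is generated programmatically with fixed seeds; session
scope keeps the larger cohorts to a single generation per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from srmc.simulate import (
    CohortSpec,
    default_phenotypes,
    generate_cohort,
    generate_frame,
    simulate_cohort_cells,
)


def default_mixture(marker_fraction: float = 0.15, divergence: float = 2.5):
    ph = default_phenotypes()
    normal = 1.0 - marker_fraction
    return [
        (ph["marker"], marker_fraction, divergence),
        (ph["epithelial"], normal * 0.45, 1.0),
        (ph["mesothelial"], normal * 0.55, 1.0),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def clean_frame():
    """One noise-free 10-cell frame with exact truth."""
    return generate_frame(10, default_mixture(), noise_sd=0.0,
                          rng=np.random.default_rng(5), frame_id="clean")


@pytest.fixture(scope="session")
def small_cohort():
    """A 4+5-patient cohort, ~500 cells: enough signal for LOOCV."""
    spec = CohortSpec(n_pos=4, n_neg=5, frames_per_patient=6,
                      cells_per_frame_mean=10, seed=2)
    cells, pm_labels, truth = simulate_cohort_cells(spec)
    return cells, pm_labels, truth


@pytest.fixture(scope="session")
def default_cohort():
    """The study-condition cohort: 10 PM+ / 16 PM−, ~500 cells/patient."""
    spec = CohortSpec(seed=7)
    cells, pm_labels, truth = simulate_cohort_cells(spec)
    return cells, pm_labels, truth


@pytest.fixture(scope="session")
def disk_cohort(tmp_path_factory):
    """A tiny cohort written to disk, for IO/pipeline/CLI tests."""
    out = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(n_pos=2, n_neg=2, frames_per_patient=2,
                      cells_per_frame_mean=6, seed=5)
    manifest = generate_cohort(spec, out)
    return out, manifest, spec


# ---------------------------------------------------------------------------
# independent naive oracles (plain pixel loops / set arithmetic), kept
# deliberately dumb and separate from the implementation they check

def naive_dice(a: np.ndarray, b: np.ndarray) -> float:
    sa = {tuple(p) for p in np.argwhere(a)}
    sb = {tuple(p) for p in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def naive_iou(a: np.ndarray, b: np.ndarray) -> float:
    sa = {tuple(p) for p in np.argwhere(a)}
    sb = {tuple(p) for p in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return len(sa & sb) / len(sa | sb)


def naive_count_rmse(pred, true) -> float:
    total = 0.0
    for p, t in zip(pred, true):
        total += (p - t) ** 2
    return (total / len(pred)) ** 0.5


def naive_composition(c_l, c_p, cell_mask, nucleus_mask, ld_labels):
    """Pixel-loop recomputation of all mask-based quantities."""
    h, w = cell_mask.shape
    area = nuc = 0
    lipid_sum = protein_sum = 0.0
    cyto_lipid = cyto_protein = 0.0
    cyto = 0
    ld_pixels = 0
    ld_lipid = 0.0
    ld_ids = set()
    for i in range(h):
        for j in range(w):
            if not cell_mask[i, j]:
                continue
            area += 1
            lipid_sum += c_l[i, j]
            protein_sum += c_p[i, j]
            if nucleus_mask[i, j]:
                nuc += 1
            else:
                cyto += 1
                cyto_lipid += c_l[i, j]
                cyto_protein += c_p[i, j]
            if ld_labels[i, j] > 0:
                ld_pixels += 1
                ld_lipid += c_l[i, j]
                ld_ids.add(int(ld_labels[i, j]))
    return {
        "area": area,
        "nucleus_area": nuc,
        "cytoplasm_area": cyto,
        "lipid_intensity": lipid_sum / area,
        "protein_intensity": protein_sum / area,
        "lipid_intensity_cytoplasm": cyto_lipid / cyto if cyto else 0.0,
        "protein_intensity_cytoplasm": cyto_protein / cyto if cyto else 0.0,
        "ld_area": ld_pixels,
        "ld_number": len(ld_ids),
        "lipid_intensity_ld": ld_lipid / ld_pixels if ld_pixels else 0.0,
    }
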