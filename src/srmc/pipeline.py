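"""End-to-end orchestration: frames in, diagnosis report out.

``run_pipeline`` executes segment -> extract -> select -> K-PCA ->
LOOCV diagnosis over a cohort manifest, writing every intermediate
(cell table, selection, transform, patient matrices, report, run log)
so any stage can be audited or rerun. The pipeline is a pure function
of (input files, config, seed).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diagnose import DiagnosisReport, LoocvConfig, loocv
from .features import ALL_FEATURES, extract_cells, select_features
from .io import CohortManifest, LabelMap, load_manifest, read_frame, write_report
from .kpca import fit_kpca
from .segment import (
    SegEval,
    count_rmse,
    count_rrse_pooled,
    dice,
    iou,
    segment_frame,
)

logger = logging.getLogger("srmc")

__all__ = ["RunConfig", "PipelineError", "run_pipeline",
           "evaluate_segmentation"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending item."""


@dataclass
class RunConfig:
    """All stage parameters of one pipeline run."""

    schema: str = "srmc-run/1"
    segmentation_method: str = "baseline"
    segmentation_params: dict = field(default_factory=dict)
    nucleus_alpha: float = 0.0
    ld_percentile: float = 98.0
    ld_min_area: int = 2
    alpha: float = 0.05
    features: tuple = tuple(ALL_FEATURES)
    k: int = 3
    variance_target: float = 0.9
    model: str = "LR"
    seed: int = 0
    include_counts: bool = True
    normalize_counts: bool = False
    refit_per_fold: bool = True
    pixel_size_um: float = 0.25

    def __post_init__(self) -> None:
        if self.model not in ("LR", "SVM", "LDA"):
            raise ValueError(f"unknown model {self.model!r}")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if not (50.0 < self.ld_percentile < 100.0):
            raise ValueError("ld_percentile must lie in (50, 100)")
        if self.k < 2:
            raise ValueError("k must be at least 2")
        self.features = tuple(self.features)

    # stage-specific sub-seeds by fixed offsets: reproducible per stage
    @property
    def kpca_seed(self) -> int:
        return (self.seed + 1) % 2**31

    @property
    def classifier_seed(self) -> int:
        return (self.seed + 2) % 2**31

    def to_yaml(self, path=None) -> str:
        data = asdict(self)
        data["features"] = list(data["features"])
        text = yaml.safe_dump(data, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        path = Path(str(source))
        data = yaml.safe_load(path.read_text() if path.exists() else source)
        return cls(**data)

    def loocv_config(self) -> LoocvConfig:
        return LoocvConfig(
            alpha=self.alpha, features=tuple(self.features), k=self.k,
            variance_target=self.variance_target, model=self.model,
            seed=self.kpca_seed, include_counts=self.include_counts,
            normalize_counts=self.normalize_counts,
            refit_per_fold=self.refit_per_fold,
        )


def _extract_cohort(manifest: CohortManifest, config: RunConfig,
                    out: Path | None) -> pd.DataFrame:
    tables = []
    for patient in manifest.patients:
        t0 = time.perf_counter()
        for frame_path in patient.frame_paths:
            try:
                frame = read_frame(frame_path, config.pixel_size_um)
                seg = segment_frame(
                    frame, method=config.segmentation_method,
                    params=config.segmentation_params,
                    nucleus_alpha=config.nucleus_alpha,
                    ld_percentile=config.ld_percentile,
                    ld_min_area=config.ld_min_area,
                )
                tables.append(extract_cells(frame, seg,
                                            patient_id=patient.patient_id))
            except Exception as exc:
                raise PipelineError(
                    f"stage=segment/extract patient={patient.patient_id} "
                    f"frame={frame_path}: {exc}"
                ) from exc
        logger.info("extract patient=%s frames=%d elapsed=%.2fs",
                    patient.patient_id, len(patient.frame_paths),
                    time.perf_counter() - t0)
    cells = (pd.concat(tables, ignore_index=True)
             if tables else pd.DataFrame())
    if out is not None:
        cells.to_csv(out / "cells.csv", index=False)
    return cells


def run_pipeline(manifest, config: RunConfig | None = None,
                 out_dir=None) -> DiagnosisReport:
    """Run the whole pipeline over a cohort manifest.

    ``manifest`` is a path or a loaded :class:`CohortManifest`. When
    ``out_dir`` is given, every intermediate artifact and a structured
    run log are written there. Any stage failure aborts with the stage
    and the offending patient/frame named.
    """
    config = config or RunConfig()
    if not isinstance(manifest, CohortManifest):
        manifest = load_manifest(manifest)
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    t0 = time.perf_counter()
    cells = _extract_cohort(manifest, config, out)
    pm_labels = manifest.pm_labels()

    try:
        selection = select_features(cells, pm_labels, alpha=config.alpha,
                                    features=config.features)
    except Exception as exc:
        raise PipelineError(f"stage=select: {exc}") from exc
    if out is not None:
        write_report(selection.to_dict(), out / "selection.json")

    try:
        selected = selection.selected if len(selection.selected) >= 2 else [
            f for f in config.features if f not in selection.dropped_constant]
        transform = fit_kpca(cells, selected, k=config.k,
                             variance_target=config.variance_target,
                             seed=config.kpca_seed)
    except Exception as exc:
        raise PipelineError(f"stage=kpca: {exc}") from exc
    if out is not None:
        transform.to_json(out / "transform.json")

    try:
        report = loocv(cells, pm_labels, config.loocv_config())
    except Exception as exc:
        raise PipelineError(f"stage=diagnose: {exc}") from exc

    if out is not None:
        write_report(report, out / "report.json")
        log = {
            "srmc_version": __version__,
            "config": yaml.safe_load(config.to_yaml()),
            "n_patients": len(manifest),
            "n_cells": int(len(cells)),
            "selected_features": selection.selected,
            "elapsed_s": round(time.perf_counter() - t0, 3),
        }
        (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return report


def evaluate_segmentation(pred_maps: list[LabelMap],
                          truth_maps: list[LabelMap]) -> pd.DataFrame:
    """Per-frame and pooled Dice/IoU (binarized) and count RMSE/RRSE.

    The returned table has one row per frame plus a ``pooled`` row;
    pooled Dice/IoU treat all frames as one mask, pooled RMSE/RRSE
    aggregate the per-frame counts.
    """
    if len(pred_maps) != len(truth_maps):
        raise ValueError("unpaired frames")
    if not pred_maps:
        raise ValueError("no frames to evaluate")
    rows = []
    pred_counts, true_counts = [], []
    inter = total = union = 0
    for i, (p, t) in enumerate(zip(pred_maps, truth_maps)):
        pb = p.labels > 0
        tb = t.labels > 0
        np_count = len(p.label_ids())
        nt_count = len(t.label_ids())
        pred_counts.append(np_count)
        true_counts.append(nt_count)
        inter += int((pb & tb).sum())
        union += int((pb | tb).sum())
        total += int(pb.sum() + tb.sum())
        rows.append({
            "frame": i, "dice": dice(pb, tb), "iou": iou(pb, tb),
            "pred_count": np_count, "true_count": nt_count,
        })
    pooled_dice = 2.0 * inter / total if total else 1.0
    pooled_iou = inter / union if union else 1.0
    rmse = count_rmse(pred_counts, true_counts)
    rrse = (count_rmse(pred_counts, true_counts, relative=True)
            if all(c > 0 for c in true_counts) else float("nan"))
    rrse_pooled = (count_rrse_pooled(pred_counts, true_counts)
                   if sum(true_counts) else float("nan"))
    rows.append({
        "frame": "pooled", "dice": pooled_dice, "iou": pooled_iou,
        "pred_count": int(np.sum(pred_counts)),
        "true_count": int(np.sum(true_counts)),
        "count_rmse": rmse, "count_rrse_percent": rrse,
        "count_rrse_pooled_percent": rrse_pooled,
    })
    return pd.DataFrame(rows)


def seg_eval_summary(table: pd.DataFrame) -> SegEval:
    pooled = table[table["frame"] == "pooled"].iloc[0]
    return SegEval(
        dice=float(pooled["dice"]), iou=float(pooled["iou"]),
        count_rmse=float(pooled["count_rmse"]),
        count_rrse_percent=float(pooled["count_rrse_percent"]),
    )
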