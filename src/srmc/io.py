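"""Reading and writing the pipeline's on-disk formats.

Frames are 3-channel TIFFs (channel order lipid 2850 cm^-1, protein
2930 cm^-1, DNA 2965 cm^-1), label maps are uint16 TIFFs, cohort
manifests are YAML/JSON, cell tables are CSV and diagnosis reports JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml

__all__ = [
    "SRSFrame",
    "LabelMap",
    "PatientEntry",
    "CohortManifest",
    "FormatError",
    "ValidationError",
    "CHANNEL_NAMES",
    "DEFAULT_PIXEL_SIZE_UM",
    "read_frame",
    "write_frame",
    "read_label_map",
    "write_label_map",
    "load_manifest",
    "write_manifest",
    "write_report",
]

#: channel order inside frame TIFFs, by Raman band
CHANNEL_NAMES = ("lipid", "protein", "dna")

#: 100 um field of view over 400 px
DEFAULT_PIXEL_SIZE_UM = 0.25

PM_LABELS = ("POS", "NEG", "unknown")


class FormatError(ValueError):
    """Raised when an image file does not match the expected layout."""


class ValidationError(ValueError):
    """Raised when a manifest or report violates its schema."""


@dataclass
class SRSFrame:
    """One co-registered three-channel field of view.

    ``lipid``/``protein`` hold the raw detector signals S_L and S_P;
    chemical concentrations are obtained from them by linear unmixing
    (see :mod:`srmc.features`). Intensities are arbitrary detector units.
    """

    lipid: np.ndarray
    protein: np.ndarray
    dna: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.lipid = np.asarray(self.lipid, dtype=float)
        self.protein = np.asarray(self.protein, dtype=float)
        self.dna = np.asarray(self.dna, dtype=float)
        if not (self.lipid.shape == self.protein.shape == self.dna.shape):
            raise FormatError("frame channels must share one shape")
        if self.lipid.ndim != 2:
            raise FormatError("frame channels must be 2-D")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name in CHANNEL_NAMES:
            if not np.all(np.isfinite(getattr(self, name))):
                raise FormatError(f"non-finite intensities in {name} channel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.lipid.shape

    def stack(self) -> np.ndarray:
        """Channels as one (3, H, W) array in canonical order."""
        return np.stack([self.lipid, self.protein, self.dna])


@dataclass
class LabelMap:
    """Integer image assigning pixels to objects; 0 is background."""

    labels: np.ndarray
    kind: str = "cell"  # cell | nucleus | lipid_droplet

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("label map must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError("label map must be integer-typed")
        if self.labels.min(initial=0) < 0:
            raise FormatError("labels must be non-negative")
        if self.kind not in ("cell", "nucleus", "lipid_droplet"):
            raise ValueError(f"unknown label-map kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class PatientEntry:
    patient_id: str
    pm_label: str = "unknown"
    cy_label: str | None = None
    frame_paths: list[str] = field(default_factory=list)


@dataclass
class CohortManifest:
    """Patients -> frames -> labels, in file order."""

    patients: list[PatientEntry]

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_id: {dupes}")
        for p in self.patients:
            if p.pm_label not in PM_LABELS:
                raise ValidationError(
                    f"unknown pm_label {p.pm_label!r} for {p.patient_id}"
                )

    def pm_labels(self) -> dict[str, str]:
        return {p.patient_id: p.pm_label for p in self.patients}

    def __len__(self) -> int:
        return len(self.patients)


def read_frame(path, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> SRSFrame:
    """Read a 3-channel TIFF into an :class:`SRSFrame`.

    Channel order is (lipid, protein, DNA); a shape or channel-count
    mismatch raises :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim != 3:
        raise FormatError(f"{path}: expected 3 channels, got shape {arr.shape}")
    # accept channel-first or channel-last layouts
    if arr.shape[0] == 3:
        pass
    elif arr.shape[-1] == 3:
        arr = np.moveaxis(arr, -1, 0)
    else:
        raise FormatError(f"{path}: expected 3 channels, got shape {arr.shape}")
    return SRSFrame(
        lipid=arr[0], protein=arr[1], dna=arr[2],
        pixel_size_um=pixel_size_um, frame_id=path.stem,
    )


def write_frame(frame: SRSFrame, path) -> None:
    """Write a frame as a channel-first float32 TIFF."""
    data = frame.stack().astype(np.float32)
    tifffile.imwrite(
        path, data,
        photometric="minisblack", planarconfig="separate",
        metadata={"axes": "CYX", "channels": list(CHANNEL_NAMES),
                  "pixel_size_um": frame.pixel_size_um},
    )


def read_label_map(path, kind: str = "cell") -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: label map must be a single-page 2-D TIFF")
    return LabelMap(labels=arr.astype(np.int64), kind=kind)


def write_label_map(label_map: LabelMap, path) -> None:
    """Write a label map as uint16 TIFF; labels above 65535 overflow."""
    labels = label_map.labels
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise OverflowError(
            f"label {labels.max()} exceeds uint16 range of the on-disk format"
        )
    tifffile.imwrite(path, labels.astype(np.uint16))


def _entry_from_mapping(d: dict, base: Path) -> PatientEntry:
    try:
        pid = str(d["patient_id"])
    except KeyError as exc:
        raise ValidationError("manifest entry missing patient_id") from exc
    frames = [str((base / f)) if not Path(f).is_absolute() else str(f)
              for f in d.get("frame_paths", [])]
    return PatientEntry(
        patient_id=pid,
        pm_label=str(d.get("pm_label", "unknown")),
        cy_label=d.get("cy_label"),
        frame_paths=frames,
    )


def load_manifest(path, check_paths: bool = True) -> CohortManifest:
    """Load a YAML/JSON cohort manifest, preserving patient order.

    Relative frame paths are resolved against the manifest's directory.
    """
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict) or "patients" not in data:
        raise ValidationError(f"{path}: manifest must be a mapping with 'patients'")
    manifest = CohortManifest(
        patients=[_entry_from_mapping(d, path.parent) for d in data["patients"]]
    )
    if check_paths:
        for p in manifest.patients:
            for f in p.frame_paths:
                if not Path(f).exists():
                    raise ValidationError(f"frame path does not resolve: {f}")
    return manifest


def write_manifest(manifest: CohortManifest, path) -> None:
    data = {
        "patients": [
            {
                "patient_id": p.patient_id,
                "pm_label": p.pm_label,
                "cy_label": p.cy_label,
                "frame_paths": list(p.frame_paths),
            }
            for p in manifest.patients
        ]
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_report(report, path) -> None:
    """Serialize a report (dataclass with ``to_dict`` or plain mapping) to JSON."""
    if hasattr(report, "to_dict"):
        report = report.to_dict()
    Path(path).write_text(json.dumps(_jsonable(report), indent=2))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
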