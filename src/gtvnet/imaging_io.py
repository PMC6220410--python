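"""Volume and tabular I/O: NIfTI/DICOM reading, manifests, metrics tables.

Internal convention: grids are (rows, cols, slices) with ``spacing_mm``
matched to the axes, voxel-centre coordinates, physical position =
index * spacing (0-based).  NIfTI is the canonical on-disk format; DICOM
series are converted on read.  Only axis-aligned orientations are accepted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .metrics import MetricsRecord

logger = logging.getLogger(__name__)

MODALITIES = ("CT", "PET", "MASK")

METRICS_COLUMNS = ["patient", "GTVm_cm3", "GTVa_cm3", "sensitivity",
                   "precision", "DSC", "MSD_mm", "group"]


@dataclass
class ImageVolume:
    """A 3-D intensity grid with physical spacing and a modality tag."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    modality: str = "CT"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a 3-D grid with all dims >= 1")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be 3 strictly positive values (mm)")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.modality == "MASK":
            vals = np.unique(self.voxels)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(
                    f"MASK volume must be binary; found values {vals[:5]}")
        if abs(self.spacing_mm[0] - self.spacing_mm[1]) > 1e-6:
            warnings.warn("non-isotropic in-plane spacing "
                          f"{self.spacing_mm[:2]}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm[0] * self.spacing_mm[1] * self.spacing_mm[2]


def _modality_from_path(path: Path) -> str | None:
    stem = path.name.lower()
    for tag in ("mask", "pet", "ct"):
        if tag in stem:
            return tag.upper()
    return None


def read_volume(path: str | Path, modality: str | None = None,
                patient_id: str = "") -> ImageVolume:
    """Read a NIfTI file or a DICOM series directory into an ImageVolume.

    Spacing is taken from the header; the orientation must be axis-aligned
    (diagonal affine up to sign) or a ValueError is raised.  The modality is
    taken from the ``modality`` argument or guessed from the filename
    (substrings ct/pet/mask).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if path.is_dir():
        voxels, spacing = _read_dicom_series(path)
    else:
        img = nib.load(str(path))
        affine = img.affine
        rot = affine[:3, :3]
        off_diag = rot - np.diag(np.diag(rot))
        if np.abs(off_diag).max() > 1e-3 * max(1.0, np.abs(rot).max()):
            raise ValueError(f"{path}: oblique orientation not supported; "
                             "only axis-aligned volumes are accepted")
        voxels = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    modality = modality or _modality_from_path(path) or "CT"
    if modality == "MASK":
        voxels = np.rint(voxels) if np.allclose(
            voxels, np.rint(voxels), atol=1e-6) else voxels
    return ImageVolume(voxels, spacing, modality=modality,
                       patient_id=patient_id)


def _read_dicom_series(directory: Path) -> tuple[np.ndarray, tuple]:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise IOError(f"no DICOM series found under {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    arr = sitk.GetArrayFromImage(img)          # (slices, rows, cols)
    voxels = np.transpose(arr, (1, 2, 0)).astype(np.float64)
    sx, sy, sz = img.GetSpacing()              # (cols, rows, slices)
    return voxels, (float(sy), float(sx), float(sz))


def write_volume(volume: ImageVolume, path: str | Path) -> Path:
    """Write an ImageVolume as NIfTI with a diagonal spacing affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.spacing_mm) + [1.0])
    data = volume.voxels
    if volume.modality == "MASK":
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))
    return path


MANIFEST_COLUMNS = ["patient_id", "center_id", "ct_path", "pet_path",
                    "mask_path", "ct_spacing_mm", "pet_spacing_mm",
                    "true_tumor_volume_cm3"]


def write_manifest(rows: Sequence[dict], path: str | Path) -> Path:
    """Write a cohort manifest CSV (one row per patient)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(list(rows))
    missing = [c for c in MANIFEST_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"manifest rows missing columns {missing}")
    df.to_csv(path, index=False)
    logger.info("wrote manifest with %d patients to %s", len(df), path)
    return path


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Load a cohort manifest, checking uniqueness and file existence.

    Relative volume paths are resolved against the working directory, the
    manifest's directory, then its parent; the returned frame carries the
    resolved paths.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df["patient_id"].duplicated().any():
        raise ValueError("manifest patient_id values must be unique")
    base = path.parent
    for col in ("ct_path", "pet_path", "mask_path"):
        resolved = []
        for p in df[col]:
            fp = Path(p)
            for candidate in ((fp,) if fp.is_absolute()
                              else (fp, base / fp, base.parent / fp)):
                if candidate.exists():
                    resolved.append(str(candidate))
                    break
            else:
                raise IOError(f"manifest references missing file: {p}")
        df[col] = resolved
    return df


def write_metrics_csv(records: Sequence[MetricsRecord],
                      path: str | Path) -> Path:
    """Write per-patient metrics rows with a fixed, deterministic column order."""
    if not records:
        raise ValueError("no metrics records to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [{
        "patient": r.patient_id,
        "GTVm_cm3": r.gtvm_cm3,
        "GTVa_cm3": r.gtva_cm3,
        "sensitivity": r.sensitivity,
        "precision": r.precision,
        "DSC": r.dsc,
        "MSD_mm": r.msd_mm,
        "group": r.group,
    } for r in records]
    pd.DataFrame(rows, columns=METRICS_COLUMNS).to_csv(
        path, index=False, float_format="%.10g")
    return path


def read_metrics_csv(path: str | Path) -> list[MetricsRecord]:
    df = pd.read_csv(path)
    return [MetricsRecord(
        patient_id=str(r["patient"]),
        gtvm_cm3=float(r["GTVm_cm3"]),
        gtva_cm3=float(r["GTVa_cm3"]),
        sensitivity=float(r["sensitivity"]),
        precision=float(r["precision"]),
        dsc=float(r["DSC"]),
        msd_mm=float(r["MSD_mm"]),
        group=str(r["group"]) if not pd.isna(r["group"]) else "",
    ) for _, r in df.iterrows()]


def load_config(path: str | Path) -> dict:
    """Load a YAML key/value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
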