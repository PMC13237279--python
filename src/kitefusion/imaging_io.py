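"""Slice-level I/O and preprocessing for paired PET/CT data.

The data model is 2-D throughout: one sample is a single-modality slice with
its binary lesion mask, patient identifier and optional benign/malignant
label.  A cohort on disk is a CSV manifest whose rows point at per-slice
image files (16-bit grayscale PNG or float32 NIfTI) for PET, CT and mask.

Preprocessing follows the clinical pipeline the models assume:

- CT Hounsfield values clipped to [-150, 250] HU (excludes air/bone extremes);
- PET intensities normalized per-image (min-max to [0,1] or z-score);
- isotropic in-plane resampling (bilinear image / nearest-neighbour mask);
- lesion delineation by thresholding a PET ROI at a fraction (default 40%)
  of its maximum uptake value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SlicePair",
    "ManifestRecord",
    "DatasetManifest",
    "LoadError",
    "load_manifest",
    "load_slice",
    "load_pair",
    "clip_ct_hu",
    "normalize_pet",
    "resample_isotropic",
    "suvmax_threshold_mask",
    "read_image",
    "write_image",
]

MODALITIES = ("PET", "CT")
LABELS = ("benign", "malignant")

# Fixed affine ranges used to quantize float slices into 16-bit PNGs.
PNG_RANGES = {"PET": (-1.0, 4.0), "CT": (-1024.0, 3071.0)}


class LoadError(RuntimeError):
    """Raised when a manifest record cannot be materialized."""


@dataclass
class SlicePair:
    """One 2-D image of a given modality with its binary lesion mask."""

    image: np.ndarray
    mask: np.ndarray
    modality: str
    patient_id: str
    label: str | None = None
    pixel_spacing: tuple = (1.0, 1.0)

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 2:
            raise ValueError(f"image must be 2-D, got shape {self.image.shape}")
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image/mask shape mismatch: {self.image.shape} vs {self.mask.shape}"
            )
        if not np.all(np.isin(np.unique(self.mask), (0, 1))):
            raise ValueError("mask must be binary {0,1}")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS} or None")
        if not all(s > 0 for s in self.pixel_spacing):
            raise ValueError("pixel_spacing must be positive")

    def with_(self, **kw) -> "SlicePair":
        return replace(self, **kw)


@dataclass
class ManifestRecord:
    patient_id: str
    pet_path: str
    ct_path: str
    mask_path: str
    label: str | None = None


@dataclass
class DatasetManifest:
    records: list = field(default_factory=list)
    root: Path = Path(".")

    @property
    def patients(self) -> list:
        seen = dict.fromkeys(r.patient_id for r in self.records)
        return list(seen)


def load_manifest(path) -> DatasetManifest:
    """Read a cohort manifest CSV and verify every referenced file exists."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"patient_id", "slice_path_pet", "slice_path_ct", "mask_path"}
    missing = required - set(df.columns)
    if missing:
        raise LoadError(f"manifest {path} lacks columns {sorted(missing)}")
    root = path.parent
    records = []
    for _, row in df.iterrows():
        rec = ManifestRecord(
            patient_id=row["patient_id"],
            pet_path=row["slice_path_pet"],
            ct_path=row["slice_path_ct"],
            mask_path=row["mask_path"],
            label=row.get("label") if isinstance(row.get("label"), str) else None,
        )
        for p in (rec.pet_path, rec.ct_path, rec.mask_path):
            if not (root / p).exists():
                raise LoadError(
                    f"patient {rec.patient_id}: referenced file {p} does not exist"
                )
        records.append(rec)
    return DatasetManifest(records=records, root=root)


def read_image(path, modality: str | None = None) -> np.ndarray:
    """Read a slice from PNG (de-quantizing via the fixed modality range) or
    NIfTI (returned as stored, float32)."""
    path = Path(path)
    if path.suffix == ".png":
        raw = iio.imread(path).astype(np.float64)
        if modality in PNG_RANGES:
            lo, hi = PNG_RANGES[modality]
            return (raw / 65535.0 * (hi - lo) + lo).astype(np.float32)
        return raw.astype(np.float32)
    img = np.asanyarray(nib.load(str(path)).dataobj)
    return np.squeeze(img).astype(np.float32)


def write_image(arr: np.ndarray, path, modality: str | None = None):
    path = Path(path)
    if path.suffix == ".png":
        if modality in PNG_RANGES:
            lo, hi = PNG_RANGES[modality]
            q = np.clip((arr - lo) / (hi - lo), 0, 1) * 65535.0
            iio.imwrite(path, np.round(q).astype(np.uint16))
        else:  # e.g. a binary mask
            iio.imwrite(path, (np.asarray(arr) * 255).astype(np.uint8))
    else:
        nib.save(
            nib.Nifti1Image(np.asarray(arr, dtype=np.float32), np.eye(4)), str(path)
        )


def _binarize(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask, dtype=np.float64)
    if m.max() > 1:
        m = m / m.max()
    return (m >= 0.5).astype(np.uint8)


def load_slice(record: ManifestRecord, modality: str, root=Path(".")) -> SlicePair:
    """Materialize one modality of a manifest record as a SlicePair."""
    if modality not in MODALITIES:
        raise ValueError(f"modality must be one of {MODALITIES}")
    root = Path(root)
    img_path = record.pet_path if modality == "PET" else record.ct_path
    try:
        image = read_image(root / img_path, modality)
        mask = _binarize(read_image(root / record.mask_path))
    except FileNotFoundError as e:
        raise LoadError(f"patient {record.patient_id}: {e}") from e
    if image.shape != mask.shape:
        raise LoadError(
            f"patient {record.patient_id}: image shape {image.shape} "
            f"!= mask shape {mask.shape}"
        )
    return SlicePair(
        image=image,
        mask=mask,
        modality=modality,
        patient_id=record.patient_id,
        label=record.label,
    )


def load_pair(record: ManifestRecord, root=Path(".")) -> tuple:
    """(PET SlicePair, CT SlicePair) of one record."""
    return load_slice(record, "PET", root), load_slice(record, "CT", root)


# --- preprocessing ------------------------------------------------------------


def clip_ct_hu(image: np.ndarray, lo: float = -150.0, hi: float = 250.0) -> np.ndarray:
    """Clip CT Hounsfield values into [lo, hi]."""
    if lo >= hi:
        raise ValueError(f"invalid HU window: lo={lo} >= hi={hi}")
    return np.clip(np.asarray(image, dtype=np.float32), lo, hi)


def normalize_pet(image: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Per-image PET intensity normalization.

    minmax maps to [0,1]; zscore to mean 0 / sd 1.  A constant image maps to
    all zeros under either method (degenerate inputs must not crash training).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("empty image")
    if method == "minmax":
        lo, hi = img.min(), img.max()
        if hi == lo:
            return np.zeros_like(img, dtype=np.float32)
        return ((img - lo) / (hi - lo)).astype(np.float32)
    if method == "zscore":
        sd = img.std()
        if sd == 0:
            return np.zeros_like(img, dtype=np.float32)
        return ((img - img.mean()) / sd).astype(np.float32)
    raise ValueError(f"unknown normalization method {method!r}")


def resample_isotropic(
    image: np.ndarray,
    mask: np.ndarray,
    spacing: tuple,
    target_spacing: float = 1.0,
) -> tuple:
    """Resample image (bilinear) and mask (nearest) to isotropic pixel size.

    Returns (image, mask, new_spacing); the mask stays binary.
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    zoom = (spacing[0] / target_spacing, spacing[1] / target_spacing)
    img = ndimage.zoom(np.asarray(image, dtype=np.float32), zoom, order=1)
    msk = ndimage.zoom(np.asarray(mask, dtype=np.uint8), zoom, order=0)
    return img, msk.astype(np.uint8), (target_spacing, target_spacing)


def suvmax_threshold_mask(pet_roi: np.ndarray, fraction: float = 0.4) -> np.ndarray:
    """Binary mask of pixels at or above `fraction` of the ROI maximum uptake
    (the clinical 40%-of-SUVmax delineation rule)."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    roi = np.asarray(pet_roi, dtype=np.float64)
    if roi.size == 0:
        raise ValueError("empty ROI")
    peak = roi.max()
    if peak <= 0:
        warnings.warn("ROI has no positive uptake: returning empty mask", stacklevel=2)
        return np.zeros(roi.shape, dtype=np.uint8)
    return (roi >= fraction * peak).astype(np.uint8)
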