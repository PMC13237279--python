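"""Synthetic PET/CT-like phantom cohorts.

No public PET/CT ovarian-tumor cohort exists, so every other module is
exercised on generated phantoms that keep the statistical structure the
method assumes: co-registered PET and CT renderings of the same lesion
geometry, one simply-connected bright lesion per slice, several slices per
synthetic patient, and a benign/malignant contrast expressed through lesion
boundary irregularity and intensity statistics.

Lesion geometry is a star-convex polygon: the boundary radius is
``r(theta) = R * (1 + irregularity * sum of low-order random harmonics)``,
rasterized and morphologically closed.  A single irregularity amplitude per
class therefore controls the benign (near-elliptical, high circularity) vs
malignant (spiculated, low circularity) shape difference, which makes the
classification task learnable by construction.

Rendering: PET shows a bright lesion over a dim smooth background in
normalized-uptake units; CT shows a mildly hyperdense lesion over a textured
soft-tissue background in pseudo-HU spanning the clinical [-150, 250] window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import binary_closing
from skimage.draw import polygon as draw_polygon
from skimage.morphology import disk

from .imaging_io import SlicePair, write_image

__all__ = [
    "PhantomSpec",
    "PairedSlice",
    "SyntheticCohort",
    "generate_lesion_mask",
    "generate_patient",
    "generate_cohort",
    "write_cohort",
    "mask_circularity",
]


@dataclass
class PhantomSpec:
    """Parameters of the phantom generator.

    Defaults are desk-scale (128 px); 512 px is reserved for full-fidelity
    runs.  Intensities are normalized-uptake units for PET and pseudo-HU for
    CT; radii in pixels.
    """

    image_size: int = 128
    slices_per_patient: tuple = (3, 6)  # inclusive range
    lesion_radius: tuple = (6.0, 20.0)
    irregularity: dict = field(
        default_factory=lambda: {"benign": 0.06, "malignant": 0.40}
    )
    lesion_intensity: dict = field(
        default_factory=lambda: {
            "PET": {"benign": (1.4, 0.10), "malignant": (1.9, 0.10)},
            "CT": {"benign": (60.0, 10.0), "malignant": (95.0, 10.0)},
        }
    )
    background_texture: dict = field(
        default_factory=lambda: {
            "PET": {"level": 0.25, "noise_sd": 0.05, "field_amplitude": 0.08},
            "CT": {"level": 40.0, "noise_sd": 12.0, "field_amplitude": 25.0},
        }
    )
    pixel_spacing: tuple = (1.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        if self.image_size <= 0:
            raise ValueError("image_size must be positive")
        lo, hi = self.lesion_radius
        if lo > hi:
            raise ValueError(f"empty lesion radius range ({lo}, {hi})")
        if lo < 3:
            raise ValueError("minimum lesion radius must be >= 3 px")
        if hi > self.image_size / 4:
            raise ValueError("maximum lesion radius must be <= image_size/4")
        if self.slices_per_patient[0] > self.slices_per_patient[1]:
            raise ValueError("empty slices_per_patient range")
        if not self.irregularity["benign"] < self.irregularity["malignant"]:
            raise ValueError("benign irregularity must be < malignant irregularity")


@dataclass
class PairedSlice:
    """One co-registered PET/CT slice pair sharing a single lesion mask."""

    pet: np.ndarray
    ct: np.ndarray
    mask: np.ndarray
    patient_id: str
    label: str
    pixel_spacing: tuple = (1.0, 1.0)

    def as_slice_pairs(self) -> tuple:
        """(PET SlicePair, CT SlicePair) views of this pair."""
        common = dict(
            mask=self.mask,
            patient_id=self.patient_id,
            label=self.label,
            pixel_spacing=self.pixel_spacing,
        )
        return (
            SlicePair(image=self.pet, modality="PET", **common),
            SlicePair(image=self.ct, modality="CT", **common),
        )


@dataclass
class SyntheticCohort:
    patients: list  # list of (patient_id, label, list[PairedSlice])

    @property
    def counts(self) -> dict:
        by_label = {"benign": 0, "malignant": 0}
        n_slices = 0
        for _, label, slices in self.patients:
            by_label[label] += 1
            n_slices += len(slices)
        return {"patients": by_label, "slices": n_slices}

    def all_slices(self) -> list:
        return [s for _, _, slices in self.patients for s in slices]


def _star_convex_radii(rng, base_radius, irregularity, n_theta=256):
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    perturb = np.zeros_like(theta)
    for m in range(2, 7):
        amp = rng.normal(0.0, 1.0) / m
        phase = rng.uniform(0, 2 * np.pi)
        perturb += amp * np.cos(m * theta + phase)
    radii = base_radius * (1.0 + irregularity * perturb)
    return theta, np.clip(radii, 2.0, None)


def generate_lesion_mask(spec: PhantomSpec, label: str, rng) -> np.ndarray:
    """Rasterize one star-convex lesion; guaranteed simply connected with at
    least one foreground pixel."""
    size = spec.image_size
    r_lo, r_hi = spec.lesion_radius
    base = rng.uniform(r_lo, r_hi)
    margin = r_hi * 1.6 + 2
    cy, cx = rng.uniform(margin, size - margin, size=2) if size > 2 * margin else (
        size / 2,
        size / 2,
    )
    # mild ellipticity only: stronger elongation would confound the
    # circularity contrast between the classes
    axis_ratio = rng.uniform(0.85, 1.0)
    theta, radii = _star_convex_radii(rng, base, spec.irregularity[label])
    rows = cy + radii * axis_ratio * np.sin(theta)
    cols = cx + radii * np.cos(theta)
    rr, cc = draw_polygon(rows, cols, shape=(size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    mask = binary_closing(mask, structure=disk(2))
    if not mask.any():  # degenerate rasterization fallback: a small disk
        yy, xx = np.ogrid[:size, :size]
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= 9.0
    return mask.astype(np.uint8)


def _smooth_field(rng, size, amplitude, dtype=np.float64):
    """Low-frequency background modulation from a coarse random grid."""
    from scipy.ndimage import zoom

    coarse = rng.normal(0.0, 1.0, size=(8, 8))
    f = zoom(coarse, size / 8.0, order=3)[:size, :size]
    return (amplitude * f).astype(dtype)


def _render(spec: PhantomSpec, mask: np.ndarray, label: str, modality: str, rng):
    bt = spec.background_texture[modality]
    mean, sd = spec.lesion_intensity[modality][label]
    size = spec.image_size
    img = np.full((size, size), bt["level"], dtype=np.float64)
    img += _smooth_field(rng, size, bt["field_amplitude"])
    lesion_level = rng.normal(mean, sd)
    img[mask.astype(bool)] = bt["level"] + lesion_level
    img += rng.normal(0.0, bt["noise_sd"], size=(size, size))
    return img.astype(np.float32)


def generate_patient(
    spec: PhantomSpec, patient_id: str, label: str, rng_seed: int
) -> list:
    """Generate the paired PET/CT slices of one synthetic patient.

    Deterministic in (spec, patient_id, label, rng_seed); every slice shares
    the patient id and class label, and PET and CT share the lesion mask.
    """
    if label not in ("benign", "malignant"):
        raise ValueError(f"label must be benign or malignant, got {label!r}")
    rng = np.random.default_rng(rng_seed)
    lo, hi = spec.slices_per_patient
    n_slices = int(rng.integers(lo, hi + 1))
    slices = []
    for _ in range(n_slices):
        mask = generate_lesion_mask(spec, label, rng)
        pet = _render(spec, mask, label, "PET", rng)
        ct = _render(spec, mask, label, "CT", rng)
        slices.append(
            PairedSlice(
                pet=pet,
                ct=ct,
                mask=mask,
                patient_id=patient_id,
                label=label,
                pixel_spacing=spec.pixel_spacing,
            )
        )
    return slices


def generate_cohort(
    spec: PhantomSpec, n_benign: int, n_malignant: int, seed: int | None = None
) -> SyntheticCohort:
    """Generate a cohort with distinct patient ids, reproducible by seed."""
    if n_benign < 0 or n_malignant < 0:
        raise ValueError("patient counts must be >= 0")
    seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    patients = []
    labels = ["benign"] * n_benign + ["malignant"] * n_malignant
    child_seeds = ss.generate_state(max(len(labels), 1)) % (2**31)
    for i, label in enumerate(labels):
        pid = f"P{i:04d}"
        patients.append(
            (pid, label, generate_patient(spec, pid, label, int(child_seeds[i])))
        )
    return SyntheticCohort(patients=patients)


def mask_circularity(mask: np.ndarray) -> float:
    """4*pi*A / P^2 of a binary mask (1.0 for a perfect disk)."""
    from skimage.measure import perimeter

    area = float(np.count_nonzero(mask))
    perim = float(perimeter(mask.astype(bool), neighborhood=8))
    if perim == 0:
        return 0.0
    return 4.0 * np.pi * area / perim**2


def write_cohort(cohort: SyntheticCohort, out_dir, fmt: str = "png") -> Path:
    """Write per-slice files plus a CSV manifest; returns the manifest path.

    fmt 'png' stores 16-bit quantized grayscale; 'nifti' stores float32.
    """
    if fmt not in ("png", "nifti"):
        raise ValueError("fmt must be 'png' or 'nifti'")
    ext = ".png" if fmt == "png" else ".nii.gz"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pid, label, slices in cohort.patients:
        for j, s in enumerate(slices):
            names = {
                "pet": f"{pid}_s{j:02d}_pet{ext}",
                "ct": f"{pid}_s{j:02d}_ct{ext}",
                "mask": f"{pid}_s{j:02d}_mask{ext}",
            }
            write_image(s.pet, out_dir / names["pet"], "PET")
            write_image(s.ct, out_dir / names["ct"], "CT")
            write_image(s.mask, out_dir / names["mask"])
            rows.append(
                {
                    "patient_id": pid,
                    "slice_path_pet": names["pet"],
                    "slice_path_ct": names["ct"],
                    "mask_path": names["mask"],
                    "label": label,
                }
            )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
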