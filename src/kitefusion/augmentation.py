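"""Lesion-aware and generic data augmentation.

CarveMix (segmentation): the lesion region of one slice, as delimited by its
mask, is hard-pasted at the same pixel coordinates onto another slice's
background — a pure replacement, never a weighted blend.  The synthetic mask
is the union of the two source masks, with the carved lesion taking priority
inside its own footprint.  Per-pixel provenance tags record which source each
output pixel came from, so the partition can be asserted exactly.

Mixup (classification): lambda-convex combinations of image pairs and their
one-hot labels, with lambda drawn from a symmetric Beta(alpha, alpha).

"M + kM" expansion: a training set of M samples is extended with round(k*M)
synthetic samples whose sources are drawn only from that same training set,
so cross-fold leakage is structurally impossible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging_io import SlicePair

__all__ = [
    "AugmentationError",
    "CarveMixResult",
    "MixupSample",
    "ExpandedDataset",
    "carvemix",
    "mixup",
    "sample_mixup_lambda",
    "hflip",
    "vflip",
    "rotate",
    "basic_augment",
    "expand_dataset",
]

FROM_A, FROM_B = 1, 2


class AugmentationError(ValueError):
    pass


@dataclass
class CarveMixResult:
    image: np.ndarray
    mask: np.ndarray
    provenance: np.ndarray  # FROM_A on the carved lesion, FROM_B elsewhere
    patient_id: str
    modality: str
    label: str | None = None

    def as_slice_pair(self) -> SlicePair:
        return SlicePair(
            image=self.image,
            mask=self.mask,
            modality=self.modality,
            patient_id=self.patient_id,
            label=self.label,
        )


@dataclass
class MixupSample:
    image: np.ndarray
    soft_label: np.ndarray  # 2-vector summing to 1
    lam: float
    lam_alpha: float


def carvemix(a: SlicePair, b: SlicePair) -> CarveMixResult:
    """Paste a's lesion (per a.mask) onto b's background at the same location.

    Output image: a.image where a.mask is 1, b.image elsewhere.
    Output mask: union of the two masks.
    """
    if a.image.shape != b.image.shape:
        raise AugmentationError(
            f"carvemix shape mismatch: {a.image.shape} vs {b.image.shape}"
        )
    if a.modality != b.modality:
        raise AugmentationError(
            f"carvemix modality mismatch: {a.modality} vs {b.modality}"
        )
    carve = a.mask.astype(bool)
    image = np.where(carve, a.image, b.image)
    mask = np.logical_or(carve, b.mask.astype(bool)).astype(np.uint8)
    provenance = np.where(carve, FROM_A, FROM_B).astype(np.uint8)
    return CarveMixResult(
        image=image,
        mask=mask,
        provenance=provenance,
        patient_id=f"synthetic:{a.patient_id}+{b.patient_id}",
        modality=a.modality,
        label=b.label,
    )


def sample_mixup_lambda(alpha: float, rng) -> float:
    """Draw the mixing coefficient from Beta(alpha, alpha)."""
    if alpha <= 0:
        raise AugmentationError("mixup alpha must be positive")
    return float(rng.beta(alpha, alpha))


def mixup(x1, y1, x2, y2, lam: float) -> MixupSample:
    """lambda-convex combination of two images and their one-hot labels."""
    x1, x2 = np.asarray(x1, dtype=np.float32), np.asarray(x2, dtype=np.float32)
    y1, y2 = np.asarray(y1, dtype=np.float64), np.asarray(y2, dtype=np.float64)
    if x1.shape != x2.shape:
        raise AugmentationError(f"mixup shape mismatch: {x1.shape} vs {x2.shape}")
    if not 0.0 <= lam <= 1.0:
        raise AugmentationError(f"lambda must be in [0,1], got {lam}")
    return MixupSample(
        image=lam * x1 + (1.0 - lam) * x2,
        soft_label=lam * y1 + (1.0 - lam) * y2,
        lam=lam,
        lam_alpha=float("nan"),
    )


# --- basic geometric augmentation --------------------------------------------


def hflip(pair: SlicePair) -> SlicePair:
    return pair.with_(image=pair.image[:, ::-1].copy(), mask=pair.mask[:, ::-1].copy())


def vflip(pair: SlicePair) -> SlicePair:
    return pair.with_(image=pair.image[::-1].copy(), mask=pair.mask[::-1].copy())


def rotate(pair: SlicePair, angle_deg: float) -> SlicePair:
    """Rotate about the image center; bilinear for the image, nearest for the
    mask (which therefore stays binary)."""
    if angle_deg % 360 == 0:
        return pair.with_(image=pair.image.copy(), mask=pair.mask.copy())
    img = ndimage.rotate(
        pair.image, angle_deg, reshape=False, order=1, mode="nearest"
    ).astype(pair.image.dtype)
    msk = ndimage.rotate(
        pair.mask.astype(np.uint8), angle_deg, reshape=False, order=0, mode="constant"
    )
    return pair.with_(image=img, mask=(msk > 0).astype(np.uint8))


def basic_augment(pair: SlicePair, rng, rotation_deg: float = 15.0) -> SlicePair:
    """Random horizontal/vertical flip and rotation in [-rotation_deg, +]."""
    out = pair
    if rng.random() < 0.5:
        out = hflip(out)
    if rng.random() < 0.5:
        out = vflip(out)
    angle = float(rng.uniform(-rotation_deg, rotation_deg))
    return rotate(out, angle)


# --- M + kM expansion ---------------------------------------------------------


@dataclass
class ExpandedDataset:
    """Original samples followed by synthetic ones, with source bookkeeping.

    sources[i] is None for an original sample and a (j, l) index pair into
    the original training set for a synthetic one.
    """

    samples: list
    sources: list

    def __len__(self):
        return len(self.samples)

    @property
    def n_synthetic(self):
        return sum(1 for s in self.sources if s is not None)


def expand_dataset(
    train_set: list,
    k: float,
    method: str = "carvemix",
    seed: int = 0,
    mixup_alpha: float = 0.2,
) -> ExpandedDataset:
    """Extend M training samples with round(k*M) synthetic ones.

    method 'carvemix' expects SlicePair samples (segmentation); 'mixup'
    expects (image, one-hot label) tuples (classification).  Source pairs are
    drawn uniformly without self-pairing, from the training set only.
    """
    if k < 0:
        raise AugmentationError(f"k must be >= 0, got {k}")
    if method not in ("carvemix", "mixup"):
        raise AugmentationError(f"unknown expansion method {method!r}")
    if not train_set:
        raise AugmentationError("train_set must be nonempty")
    m = len(train_set)
    n_new = int(round(k * m))
    rng = np.random.default_rng(seed)
    samples = list(train_set)
    sources: list = [None] * m
    for _ in range(n_new):
        i = int(rng.integers(m))
        j = int(rng.integers(m - 1)) if m > 1 else 0
        if m > 1 and j >= i:
            j += 1
        if method == "carvemix":
            samples.append(carvemix(train_set[i], train_set[j]).as_slice_pair())
        else:
            lam = sample_mixup_lambda(mixup_alpha, rng)
            x1, y1 = train_set[i]
            x2, y2 = train_set[j]
            s = mixup(x1, y1, x2, y2, lam)
            s.lam_alpha = mixup_alpha
            samples.append(s)
        sources.append((i, j))
    return ExpandedDataset(samples=samples, sources=sources)
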