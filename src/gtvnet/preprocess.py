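"""Slice-sample preparation: resampling, normalisation, filtering, balancing,
augmentation.

The network consumes two-channel 2-D samples: one CT slice plus the
coregistered PET slice resampled onto the CT grid, both min-max normalised to
[0, 1] per patient volume, with the manual mask as the training target.
Frames of reference are assumed hardware-aligned (hybrid PET-CT), so
coregistration reduces to trilinear grid resampling.

Slices whose tumor cross-section is positive but smaller than 0.5 cm^2 are
discarded (partial-volume effect makes such lesions unreliable on PET);
tumor-free slices are kept as negatives and subsampled to match the positive
count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import affine_transform, map_coordinates

from .imaging_io import ImageVolume
from .phantom import PatientCase

logger = logging.getLogger(__name__)

__all__ = [
    "SamplePair",
    "resample_pet_to_ct",
    "minmax_normalize",
    "filter_small_tumor_slices",
    "balance_samples",
    "augment",
    "apply_geometric",
    "apply_gamma",
    "slice_area_cm2",
]

DEFAULT_MIN_AREA_CM2 = 0.5

# augmentation magnitudes (conservative defaults; see docs/methods.md)
ROTATION_DEG = 15.0
GAMMA_RANGE = (0.8, 1.25)
SCALE_RANGE = (0.9, 1.1)
MIRROR_PROB = 0.5


@dataclass
class SamplePair:
    """One training/testing unit: CT slice + coregistered PET slice + mask."""

    ct_slice: np.ndarray
    pet_slice: np.ndarray
    gold_mask: np.ndarray
    pixel_spacing_mm: tuple[float, float]
    slice_thickness_mm: float
    patient_id: str = ""
    slice_index: int = -1
    is_positive: bool = False

    def __post_init__(self) -> None:
        if not (self.ct_slice.shape == self.pet_slice.shape
                == self.gold_mask.shape):
            raise ValueError("CT, PET and mask slices must share H x W")
        if len(self.pixel_spacing_mm) != 2 or min(self.pixel_spacing_mm) <= 0:
            raise ValueError("pixel spacing must be a positive pair (mm)")

    @property
    def pixel_area_cm2(self) -> float:
        return self.pixel_spacing_mm[0] * self.pixel_spacing_mm[1] / 100.0

    @property
    def mask_area_cm2(self) -> float:
        return float(np.count_nonzero(self.gold_mask)) * self.pixel_area_cm2


def resample_pet_to_ct(pet: ImageVolume, ct: ImageVolume) -> ImageVolume:
    """Resample a PET volume onto the CT grid by trilinear interpolation.

    Both volumes share an axis-aligned physical frame with the origin at the
    centre of voxel (0,0,0).  Each CT voxel centre's physical position is
    interpolated in the PET grid; positions outside the PET extent take the
    nearest-edge value.
    """
    if min(pet.spacing_mm) <= 0 or min(ct.spacing_mm) <= 0:
        raise ValueError("spacings must be strictly positive")
    if pet.shape == ct.shape and np.allclose(pet.spacing_mm, ct.spacing_mm):
        return ImageVolume(pet.voxels.copy(), ct.spacing_mm, "PET",
                           ct.patient_id)
    coords = [np.arange(n) * cs / ps
              for n, cs, ps in zip(ct.shape, ct.spacing_mm, pet.spacing_mm)]
    grid = np.meshgrid(*coords, indexing="ij")
    out = map_coordinates(pet.voxels.astype(np.float64), grid, order=1,
                          mode="nearest")
    return ImageVolume(out, ct.spacing_mm, "PET", ct.patient_id)


def minmax_normalize(volume: ImageVolume) -> ImageVolume:
    """Rescale a whole patient volume to [0, 1] by (v - min)/(max - min)."""
    v = volume.voxels
    lo, hi = float(v.min()), float(v.max())
    if hi <= lo:
        raise ValueError(
            f"cannot min-max normalize a constant volume (value {lo})")
    return ImageVolume((v - lo) / (hi - lo), volume.spacing_mm,
                       volume.modality, volume.patient_id)


def slice_area_cm2(mask_slice: np.ndarray,
                   pixel_spacing_mm: tuple[float, float]) -> float:
    """Tumor cross-section area of one mask slice: count x pixel area."""
    return (float(np.count_nonzero(mask_slice))
            * pixel_spacing_mm[0] * pixel_spacing_mm[1] / 100.0)


def filter_small_tumor_slices(case: PatientCase,
                              min_area_cm2: float = DEFAULT_MIN_AREA_CM2
                              ) -> list[SamplePair]:
    """Convert a patient case into normalised samples, dropping small-tumor
    slices.

    The PET is resampled onto the CT grid, both modalities are min-max
    normalised over the patient volume, and the case is cut into axial
    slices.  Slices whose tumor area lies in (0, min_area_cm2) are dropped
    entirely; tumor-free slices are retained as negatives; slices at or above
    the threshold are retained as positives.
    """
    pet_on_ct = minmax_normalize(resample_pet_to_ct(case.pet_native, case.ct))
    ct_norm = minmax_normalize(case.ct)
    spacing = case.ct.spacing_mm
    pixel_spacing = (spacing[0], spacing[1])
    samples: list[SamplePair] = []
    dropped = 0
    for k in range(case.ct.shape[2]):
        mask = case.gold_mask.voxels[:, :, k].astype(np.uint8)
        area = slice_area_cm2(mask, pixel_spacing)
        if 0.0 < area < min_area_cm2:
            dropped += 1
            continue
        samples.append(SamplePair(
            ct_slice=ct_norm.voxels[:, :, k],
            pet_slice=pet_on_ct.voxels[:, :, k],
            gold_mask=mask,
            pixel_spacing_mm=pixel_spacing,
            slice_thickness_mm=spacing[2],
            patient_id=case.patient_id,
            slice_index=k,
            is_positive=area >= min_area_cm2,
        ))
    logger.info("%s: %d slices kept (%d positive), %d dropped by the "
                "%.2f cm^2 filter", case.patient_id, len(samples),
                sum(s.is_positive for s in samples), dropped, min_area_cm2)
    return samples


def balance_samples(samples: list[SamplePair],
                    rng: np.random.Generator) -> list[SamplePair]:
    """Keep all positive slices; subsample negatives to the positive count.

    When fewer negatives than positives exist, all negatives are kept and a
    warning is logged.  Selection is uniform without replacement from the
    supplied generator, so a fixed seed reproduces the draw.
    """
    positives = [s for s in samples if s.is_positive]
    negatives = [s for s in samples if not s.is_positive]
    if not positives:
        raise ValueError("cannot balance a sample set with no positive slices")
    if len(negatives) <= len(positives):
        if len(negatives) < len(positives):
            warnings.warn(
                f"only {len(negatives)} negatives for {len(positives)} "
                "positives; keeping all negatives")
        chosen = negatives
    else:
        idx = rng.choice(len(negatives), size=len(positives), replace=False)
        chosen = [negatives[i] for i in sorted(idx)]
    return positives + chosen


def apply_gamma(sample: SamplePair, gamma: float) -> SamplePair:
    """Contrast change v -> v**gamma on the image channels only."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return replace(sample,
                   ct_slice=np.clip(sample.ct_slice, 0, 1) ** gamma,
                   pet_slice=np.clip(sample.pet_slice, 0, 1) ** gamma)


def apply_geometric(sample: SamplePair, angle_deg: float = 0.0,
                    scale: float = 1.0, mirror: bool = False) -> SamplePair:
    """Rotate/scale/mirror CT, PET and mask identically about the centre.

    Images are interpolated bilinearly and re-clipped to [0, 1]; the mask is
    re-binarized at 0.5 after interpolation.  A pure mirror is an exact pixel
    permutation (involution).
    """
    if mirror and angle_deg == 0.0 and scale == 1.0:
        return replace(sample,
                       ct_slice=sample.ct_slice[:, ::-1].copy(),
                       pet_slice=sample.pet_slice[:, ::-1].copy(),
                       gold_mask=sample.gold_mask[:, ::-1].copy())
    theta = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    flip = np.diag([1.0, -1.0 if mirror else 1.0])
    # affine_transform maps output -> input: invert the forward rot*scale*flip
    mat = np.linalg.inv(rot @ (scale * np.eye(2)) @ flip)
    center = (np.array(sample.ct_slice.shape) - 1) / 2.0
    offset = center - mat @ center
    def warp(img, order):
        return affine_transform(img.astype(np.float64), mat, offset=offset,
                                order=order, mode="constant", cval=0.0)
    return replace(
        sample,
        ct_slice=np.clip(warp(sample.ct_slice, 1), 0.0, 1.0),
        pet_slice=np.clip(warp(sample.pet_slice, 1), 0.0, 1.0),
        gold_mask=(warp(sample.gold_mask, 1) >= 0.5).astype(np.uint8),
    )


def augment(sample: SamplePair, rng: np.random.Generator,
            factor: int = 1) -> list[SamplePair]:
    """Emit ``factor`` random variants of one sample.

    Each variant composes a rotation (uniform in +/-15 deg), a horizontal
    mirror (probability 0.5), a contrast (gamma) change in [0.8, 1.25] on the
    image channels only, and an isotropic scaling in [0.9, 1.1]; geometric
    transforms are applied identically to CT, PET and mask.
    """
    if factor < 1:
        raise ValueError("augmentation factor must be >= 1")
    out = []
    for _ in range(factor):
        angle = rng.uniform(-ROTATION_DEG, ROTATION_DEG)
        mirror = bool(rng.random() < MIRROR_PROB)
        gamma = rng.uniform(*GAMMA_RANGE)
        scale = rng.uniform(*SCALE_RANGE)
        var = apply_geometric(sample, angle_deg=angle, scale=scale,
                              mirror=mirror)
        out.append(apply_gamma(var, gamma))
    return out
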