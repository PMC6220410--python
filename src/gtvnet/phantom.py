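"""Synthetic coregistered PET-CT phantom cohorts with known tumor masks.

Each patient is a head-like axial ellipse (bright skull rim, textured soft
tissue) carrying one or more tumor lesions and optional inflammation
confounders.  Lesions are unions of 1-3 overlapping ellipsoids, visible as a
subtle sharp-edged contrast on CT and as blurred high-uptake foci on PET.
Inflammation foci share the tumors' PET uptake distribution but have no CT
correlate and sit adjacent to the skull rim, so tumor-vs-inflammation
discrimination requires the CT channel.  The PET signal is synthesised on the
CT grid, blurred with a Gaussian point-spread function (partial-volume
effect), downsampled to the coarser PET grid, and degraded with noise.

Intensities are abstract units (min-max normalised downstream); no HU/SUV
calibration is attempted.  Slices are axial along the third index; physical
position = index * spacing (voxel centres, 0-based).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .imaging_io import ImageVolume

logger = logging.getLogger(__name__)

__all__ = [
    "PhantomParams",
    "PatientCase",
    "generate_patient",
    "generate_cohort",
    "desk_params",
    "center1_params",
    "center2_params",
]

# head ellipse: in-plane semi-axes as fraction of the field of view, and the
# normalised radius where the skull rim begins
_HEAD_AX = 0.42
_HEAD_AY = 0.45
_RIM_RHO = 0.88
_TUMOR_MAX_RHO = 0.55            # tumors sit well inside the soft tissue
_INFLAM_RHO = (0.70, 0.84)       # confounders sit adjacent to the rim
_CT_BACKGROUND = 0.02
_CT_SOFT = 0.35
_CT_RIM = 0.90
_CT_TUMOR_CONTRAST = 0.18
_PET_SOFT_UPTAKE = 1.0


@dataclass
class PhantomParams:
    """Generator configuration for one scanner/center.

    Spacings are mm triplets (rows, cols, slices); the PET grid must be at
    least as coarse as the CT grid componentwise.  ``tumor_uptake_ratio`` and
    ``inflammation_uptake_ratio`` are lesion-to-soft-tissue PET intensity
    ratios; ``pet_blur_fwhm_mm`` emulates the scanner's reconstructed
    resolution (partial-volume effect).
    """

    image_extent_mm: tuple[float, float, float] = (128.0, 128.0, 48.0)
    ct_spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)
    pet_spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    n_slices: int = 12
    tumor_count_range: tuple[int, int] = (1, 2)
    tumor_radius_range_mm: tuple[float, float] = (5.0, 17.0)
    tumor_uptake_ratio: float = 4.0
    pet_blur_fwhm_mm: float = 5.0
    inflammation_count_range: tuple[int, int] = (1, 2)
    inflammation_uptake_ratio: float = 4.0
    ct_noise_sd: float = 0.02
    pet_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.ct_spacing + self.pet_spacing):
            raise ValueError("spacings must be strictly positive")
        if any(p < c - 1e-9 for p, c in zip(self.pet_spacing, self.ct_spacing)):
            raise ValueError("pet_spacing must be >= ct_spacing componentwise")
        if self.tumor_uptake_ratio <= 1 or self.inflammation_uptake_ratio <= 1:
            raise ValueError("uptake ratios must exceed 1 (lesions are hot)")
        if self.pet_blur_fwhm_mm < 0:
            raise ValueError("pet_blur_fwhm_mm must be >= 0")
        if self.tumor_count_range[0] > self.tumor_count_range[1]:
            raise ValueError("tumor_count_range must be a valid interval")
        rmax = self.tumor_radius_range_mm[1]
        if 2 * rmax >= min(self.image_extent_mm[0], self.image_extent_mm[1]):
            raise ValueError(
                f"tumor radius {rmax} mm exceeds the field of view "
                f"{self.image_extent_mm[:2]} mm")

    @property
    def ct_shape(self) -> tuple[int, int, int]:
        nx = int(round(self.image_extent_mm[0] / self.ct_spacing[0]))
        ny = int(round(self.image_extent_mm[1] / self.ct_spacing[1]))
        return nx, ny, self.n_slices

    @property
    def pet_shape(self) -> tuple[int, int, int]:
        nx = int(round(self.image_extent_mm[0] / self.pet_spacing[0]))
        ny = int(round(self.image_extent_mm[1] / self.pet_spacing[1]))
        nz = max(1, int(round(self.n_slices * self.ct_spacing[2]
                              / self.pet_spacing[2])))
        return nx, ny, nz


@dataclass
class PatientCase:
    """One synthetic patient: CT, native-grid PET, and the true tumor mask."""

    patient_id: str
    center_id: str
    ct: ImageVolume
    pet_native: ImageVolume
    gold_mask: ImageVolume
    true_tumor_volume_cm3: float
    inflammation_mask: ImageVolume | None = None
    pet_clean_ct: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.gold_mask.shape != self.ct.shape:
            raise ValueError("gold mask must live on the CT grid")
        if self.inflammation_mask is not None:
            overlap = np.logical_and(self.inflammation_mask.voxels > 0,
                                     self.gold_mask.voxels > 0)
            if overlap.any():
                raise ValueError("inflammation overlaps the tumor mask")


def _voxel_centers(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


class _Ellipsoid:
    __slots__ = ("center", "semi")

    def __init__(self, center, semi):
        self.center = np.asarray(center, dtype=float)
        self.semi = np.asarray(semi, dtype=float)

    def contains(self, x, y, z):
        return (((x - self.center[0]) / self.semi[0]) ** 2
                + ((y - self.center[1]) / self.semi[1]) ** 2
                + ((z - self.center[2]) / self.semi[2]) ** 2) <= 1.0


def _lesion_mask(components, shape, spacing):
    x, y, z = _voxel_centers(shape, spacing)
    mask = np.zeros(shape, dtype=bool)
    for e in components:
        mask |= e.contains(x, y, z)
    return mask


def _lesion_volume_cm3(components: Sequence[_Ellipsoid],
                       step_mm: float = 0.5) -> float:
    """Volume of a union of ellipsoids by fine-grid integration (0.5 mm)."""
    lo = np.min([e.center - e.semi for e in components], axis=0)
    hi = np.max([e.center + e.semi for e in components], axis=0)
    axes = [np.arange(l, h + step_mm, step_mm) for l, h in zip(lo, hi)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    inside = np.zeros(x.shape, dtype=bool)
    for e in components:
        inside |= e.contains(x, y, z)
    return float(inside.sum()) * step_mm ** 3 / 1000.0


def _draw_lesion(rng, radius_mm, center, n_components):
    comps = [_Ellipsoid(center, rng.uniform(0.7, 1.0, 3) * radius_mm)]
    for _ in range(n_components - 1):
        offset = rng.uniform(-0.5, 0.5, 3) * radius_mm
        semi = rng.uniform(0.4, 0.8, 3) * radius_mm
        comps.append(_Ellipsoid(center + offset, semi))
    return comps


def _head_rho(params, x, y):
    ext = params.image_extent_mm
    cx = (params.ct_shape[0] - 1) * params.ct_spacing[0] / 2.0
    cy = (params.ct_shape[1] - 1) * params.ct_spacing[1] / 2.0
    ax = _HEAD_AX * ext[0]
    ay = _HEAD_AY * ext[1]
    return np.sqrt(((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2), (cx, cy, ax, ay)


def _place_center(rng, params, rho_lo, rho_hi, margin_z_mm):
    """Draw a lesion centre with in-plane normalised radius in [rho_lo, rho_hi]."""
    shape = params.ct_shape
    cx = (shape[0] - 1) * params.ct_spacing[0] / 2.0
    cy = (shape[1] - 1) * params.ct_spacing[1] / 2.0
    ax = _HEAD_AX * params.image_extent_mm[0]
    ay = _HEAD_AY * params.image_extent_mm[1]
    rho = np.sqrt(rng.uniform(rho_lo ** 2, rho_hi ** 2))
    theta = rng.uniform(0, 2 * np.pi)
    zmax = (shape[2] - 1) * params.ct_spacing[2]
    z_lo = min(margin_z_mm, zmax / 2.0)
    z = rng.uniform(z_lo, max(z_lo, zmax - z_lo))
    return np.array([cx + rho * np.cos(theta) * ax,
                     cy + rho * np.sin(theta) * ay, z])


def _resample_to_grid(src, src_spacing, dst_shape, dst_spacing):
    coords = [np.arange(n) * d / s
              for n, d, s in zip(dst_shape, dst_spacing, src_spacing)]
    grid = np.meshgrid(*coords, indexing="ij")
    return map_coordinates(src, grid, order=1, mode="nearest")


def generate_patient(params: PhantomParams, patient_id: str,
                     center_id: str = "center1") -> PatientCase:
    """Generate one synthetic PET-CT patient case, deterministic in the seed.

    Tumor lesions are disjoint unions of 1-3 ellipsoids; the analytic tumor
    volume is computed by fine-grid (0.5 mm) integration of the generative
    shapes, independent of the CT voxelisation.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.ct_shape
    spacing = params.ct_spacing
    x, y, z = _voxel_centers(shape, spacing)
    rho, _ = _head_rho(params, x, y)

    soft = rho < _RIM_RHO
    head = rho <= 1.0
    rim = head & ~soft

    # smooth soft-tissue texture (Gaussian-filtered white noise, ~4 mm scale)
    texture = gaussian_filter(rng.standard_normal(shape),
                              sigma=[4.0 / s for s in spacing])
    tstd = texture.std()
    if tstd > 0:
        texture *= 0.04 / tstd

    ct = np.full(shape, _CT_BACKGROUND)
    ct[soft] = _CT_SOFT + texture[soft]
    ct[rim] = _CT_RIM

    # --- tumors -----------------------------------------------------------
    n_tumors = int(rng.integers(params.tumor_count_range[0],
                                params.tumor_count_range[1] + 1))
    gold = np.zeros(shape, dtype=bool)
    true_volume = 0.0
    r_lo, r_hi = params.tumor_radius_range_mm
    for _ in range(n_tumors):
        # log-uniform radius so cohort volumes span a wide range
        radius = float(np.exp(rng.uniform(np.log(r_lo), np.log(r_hi))))
        placed = False
        for _attempt in range(50):
            center = _place_center(rng, params, 0.0, _TUMOR_MAX_RHO, radius)
            comps = _draw_lesion(rng, radius, center,
                                 int(rng.integers(1, 4)))
            mask = _lesion_mask(comps, shape, spacing)
            if mask.any() and not (mask & gold).any():
                placed = True
                break
        if not placed:
            warnings.warn(f"{patient_id}: could not place a lesion of radius "
                          f"{radius:.1f} mm; skipping")
            continue
        gold |= mask
        true_volume += _lesion_volume_cm3(comps)
    ct[gold] = _CT_SOFT + _CT_TUMOR_CONTRAST   # sharp anatomic boundary

    # --- inflammation confounders (hot on PET, silent on CT) --------------
    n_inflam = int(rng.integers(params.inflammation_count_range[0],
                                params.inflammation_count_range[1] + 1))
    inflam = np.zeros(shape, dtype=bool)
    for _ in range(n_inflam):
        radius = rng.uniform(0.35, 0.6) * r_lo
        for _attempt in range(50):
            center = _place_center(rng, params, *_INFLAM_RHO,
                                   margin_z_mm=radius)
            mask = _lesion_mask([_Ellipsoid(center, [radius] * 3)],
                                shape, spacing)
            if mask.any() and not (mask & gold).any():
                inflam |= mask
                break
        else:
            warnings.warn(f"{patient_id}: could not place an inflammation "
                          "focus; skipping")

    # --- PET on the CT grid, then blur / downsample / noise ---------------
    uptake = np.zeros(shape)
    uptake[soft | rim] = _PET_SOFT_UPTAKE * (1.0 + 2.0 * texture[soft | rim])
    uptake[gold] = params.tumor_uptake_ratio * _PET_SOFT_UPTAKE
    uptake[inflam] = params.inflammation_uptake_ratio * _PET_SOFT_UPTAKE
    sigma_vox = [params.pet_blur_fwhm_mm / 2.35482 / s for s in spacing]
    pet_clean = gaussian_filter(uptake, sigma=sigma_vox)

    pet_native = _resample_to_grid(pet_clean, spacing,
                                   params.pet_shape, params.pet_spacing)
    pet_native = pet_native + rng.normal(0.0, params.pet_noise_sd,
                                         pet_native.shape)
    ct = ct + rng.normal(0.0, params.ct_noise_sd, shape)

    case = PatientCase(
        patient_id=patient_id,
        center_id=center_id,
        ct=ImageVolume(ct, spacing, "CT", patient_id),
        pet_native=ImageVolume(pet_native, params.pet_spacing, "PET",
                               patient_id),
        gold_mask=ImageVolume(gold.astype(np.uint8), spacing, "MASK",
                              patient_id),
        true_tumor_volume_cm3=true_volume,
        inflammation_mask=ImageVolume(inflam.astype(np.uint8), spacing,
                                      "MASK", patient_id),
        pet_clean_ct=pet_clean,
    )
    logger.info("%s: %d tumors (%.2f cm^3 true), %d inflammation foci",
                patient_id, n_tumors, true_volume, int(n_inflam))
    return case


def generate_cohort(n_patients: int,
                    params_per_center: dict[str, PhantomParams],
                    seed: int) -> list[PatientCase]:
    """Generate a multi-center cohort, patients round-robin across centers.

    Reproducible from ``seed``: each patient's generator seed is derived from
    a spawned child of the cohort seed sequence, so cases are independent and
    stable under re-runs.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not params_per_center:
        raise ValueError("need at least one center")
    centers = list(params_per_center)
    children = np.random.SeedSequence(seed).spawn(n_patients)
    cohort = []
    for i in range(n_patients):
        center = centers[i % len(centers)]
        child_seed = int(children[i].generate_state(1)[0] % (2 ** 31))
        params = replace(params_per_center[center], seed=child_seed)
        pid = f"P{i + 1:02d}"
        cohort.append(generate_patient(params, pid, center_id=center))
    return cohort


def desk_params(center: str = "A") -> PhantomParams:
    """Small-grid presets (64x64 in-plane) for CPU-scale experiments.

    Two pseudo-centers with distinct grids mirror the dual-center design:
    center A at 2.0x2.0x4.0 mm CT / 4 mm PET, center B at 2.5x2.5x5.0 mm CT
    / 5 mm PET; both yield 64x64 axial CT matrices.  Tumor radius ranges are
    chosen so lesion cross-sections occupy the same fraction of the image
    matrix as the clinical volume range (roughly 3.5-150 cm^3 on a 512 grid
    at half-millimetre pixels) does at full scale.
    """
    if center == "A":
        return PhantomParams()
    if center == "B":
        return PhantomParams(
            image_extent_mm=(160.0, 160.0, 50.0),
            ct_spacing=(2.5, 2.5, 5.0),
            pet_spacing=(5.0, 5.0, 5.0),
            n_slices=10,
            tumor_radius_range_mm=(6.0, 21.0),
        )
    raise ValueError("center must be 'A' or 'B'")


def center1_params() -> PhantomParams:
    """Full-scale grid emulating scanner 1: CT 0.49x0.49x2.5 mm, 512x512x63;
    PET 1.56x1.56x3.27 mm on the same field of view."""
    return PhantomParams(
        image_extent_mm=(250.88, 250.88, 157.5),
        ct_spacing=(0.49, 0.49, 2.5),
        pet_spacing=(1.56, 1.56, 3.27),
        n_slices=63,
        tumor_radius_range_mm=(9.5, 33.0),
        pet_blur_fwhm_mm=6.0,
    )


def center2_params() -> PhantomParams:
    """Full-scale grid emulating scanner 2: CT 0.59x0.59x3.27 mm, 512x512x47;
    PET 1.17x1.17x3.27 mm on the same field of view."""
    return PhantomParams(
        image_extent_mm=(302.08, 302.08, 153.69),
        ct_spacing=(0.59, 0.59, 3.27),
        pet_spacing=(1.17, 1.17, 3.27),
        n_slices=47,
        tumor_radius_range_mm=(9.5, 33.0),
        pet_blur_fwhm_mm=6.0,
    )
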