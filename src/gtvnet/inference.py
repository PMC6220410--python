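"""Scores-map binarization and per-patient volume assembly.

The dense non-negative scores map is thresholded at 0.5 (targets are {0,1});
no post-processing is applied by default, matching the bare pipeline.  An
optional largest-connected-component cleanup exists behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .dcnn import Network, ScoresMap, forward
from .metrics import (MetricsRecord, confusion_counts, dsc, msd, precision,
                      sensitivity)
from .phantom import PatientCase
from .preprocess import SamplePair, slice_area_cm2
from .training import FoldResult

logger = logging.getLogger(__name__)

__all__ = ["SegmentationResult", "predict_mask", "threshold_scores",
           "assemble_volume", "largest_component", "evaluate_fold",
           "evaluate_loocv"]

DEFAULT_THRESHOLD = 0.5


@dataclass
class SegmentationResult:
    """Per-slice binary masks on the CT grid plus the assembled volume."""

    patient_id: str
    masks: list = field(default_factory=list)
    slice_indices: list = field(default_factory=list)
    gtva_cm3: float = 0.0

    def __post_init__(self) -> None:
        if self.gtva_cm3 < 0:
            raise ValueError("volume cannot be negative")


def threshold_scores(scores, threshold: float = DEFAULT_THRESHOLD
                     ) -> np.ndarray:
    values = scores.values if isinstance(scores, ScoresMap) else scores
    return (np.asarray(values) >= threshold).astype(np.uint8)


def predict_mask(network: Network, sample: SamplePair,
                 threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary contour for one sample: scores >= threshold, full resolution.

    Requires the full-resolution (stage 3) network so the mask matches the
    input grid.
    """
    if network.stage != 3:
        raise ValueError("predict_mask requires a stage-3 network "
                         f"(got stage {network.stage})")
    return threshold_scores(forward(network, sample), threshold)


def assemble_volume(masks: Sequence[np.ndarray],
                    pixel_spacing_mm: tuple[float, float],
                    slice_thickness_mm: float) -> float:
    """Total segmented volume in cm^3: sum of pixel counts x voxel volume."""
    if min(pixel_spacing_mm) <= 0 or slice_thickness_mm <= 0:
        raise ValueError("spacings must be strictly positive")
    masks = list(masks)
    if not masks:
        return 0.0
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"masks must share dimensions; got {shapes}")
    count = sum(int(np.count_nonzero(m)) for m in masks)
    voxel_mm3 = (pixel_spacing_mm[0] * pixel_spacing_mm[1]
                 * slice_thickness_mm)
    return count * voxel_mm3 / 1000.0


def largest_component(masks: Sequence[np.ndarray]) -> list[np.ndarray]:
    """Keep only the largest 3-D connected component (optional cleanup)."""
    stack = np.stack(masks, axis=-1)
    labels, n = ndimage.label(stack)
    if n <= 1:
        return [m.copy() for m in masks]
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    cleaned = (labels == keep).astype(np.uint8)
    return [cleaned[..., k] for k in range(cleaned.shape[-1])]


def evaluate_fold(case: PatientCase, fold: FoldResult,
                  threshold: float = DEFAULT_THRESHOLD,
                  min_area_cm2: float = 0.5) -> tuple[MetricsRecord,
                                                      SegmentationResult]:
    """Score one held-out patient against its known mask.

    Evaluation slices are those whose gold cross-section is either zero or
    at least ``min_area_cm2`` (small-tumor slices are excluded, mirroring the
    training-side filter); metrics are pooled over those slices at the voxel
    level, and MSD is computed in 3-D mm coordinates.
    """
    spacing = case.ct.spacing_mm
    pixel_spacing = (spacing[0], spacing[1])
    pred_slices, gold_slices, kept = [], [], []
    for k, scores in zip(fold.slice_indices, fold.scores_maps):
        gold = case.gold_mask.voxels[:, :, k].astype(np.uint8)
        area = slice_area_cm2(gold, pixel_spacing)
        if 0.0 < area < min_area_cm2:
            continue
        pred_slices.append(threshold_scores(scores, threshold))
        gold_slices.append(gold)
        kept.append(k)
    pred_vol = np.stack(pred_slices, axis=-1)
    gold_vol = np.stack(gold_slices, axis=-1)
    c = confusion_counts(pred_vol, gold_vol)
    gtva = assemble_volume(pred_slices, pixel_spacing, spacing[2])
    gtvm = assemble_volume(gold_slices, pixel_spacing, spacing[2])
    record = MetricsRecord(
        patient_id=case.patient_id,
        gtvm_cm3=gtvm,
        gtva_cm3=gtva,
        sensitivity=sensitivity(c),
        precision=precision(c),
        dsc=dsc(c),
        msd_mm=msd(pred_vol, gold_vol, spacing),
        group=case.center_id,
    )
    seg = SegmentationResult(patient_id=case.patient_id, masks=pred_slices,
                             slice_indices=kept, gtva_cm3=gtva)
    return record, seg


def evaluate_loocv(cohort: Sequence[PatientCase],
                   folds: Sequence[FoldResult],
                   threshold: float = DEFAULT_THRESHOLD,
                   min_area_cm2: float = 0.5) -> list[MetricsRecord]:
    """Per-patient metrics rows for a completed LOOCV run."""
    by_id = {c.patient_id: c for c in cohort}
    records = []
    for fold in folds:
        case = by_id[fold.held_out_patient_id]
        record, _ = evaluate_fold(case, fold, threshold, min_area_cm2)
        records.append(record)
    return records
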