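"""Segmentation evaluation: overlap metrics, surface distance, volume agreement.

All overlap metrics are computed from voxel counts pooled over a patient's
evaluated slices (volume-level pooling), so that one ``ConfusionCounts`` per
patient yields one row of the per-patient report.  The mean surface distance
is the symmetric average of nearest-neighbour Euclidean distances between the
two boundaries, in millimetres, with boundary pixels extracted per slice
(4-neighbourhood) and embedded in 3-D physical coordinates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsRecord",
    "CohortReport",
    "confusion_counts",
    "dsc",
    "sensitivity",
    "precision",
    "boundary_points_mm",
    "msd",
    "volume_difference_pct",
    "pearson_r",
    "aggregate_cohort",
    "load_reference_cohort",
    "records_from_dataframe",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel-level confusion counts pooled over a patient's evaluated slices."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsRecord:
    """One per-patient evaluation row (volumes in cm^3, MSD in mm)."""

    patient_id: str
    gtvm_cm3: float
    gtva_cm3: float
    sensitivity: float
    precision: float
    dsc: float
    msd_mm: float
    volume_diff_pct: float = float("nan")
    group: str = ""


@dataclass
class CohortReport:
    """Aggregated cohort statistics per metric and group.

    ``stats`` maps (group, metric) -> dict with keys mean, sd, median, min,
    max, ci_low, ci_high; the 95% interval is mean +/- 1.96*SD of the metric
    distribution.  ``pearson_r`` is the product-moment correlation between the
    manual and automatic volumes over all records.
    """

    stats: dict = field(default_factory=dict)
    pearson_r: float = float("nan")
    groups: tuple = ()

    def get(self, group: str, metric: str, stat: str) -> float:
        return self.stats[(group, metric)][stat]


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1); found values {vals[:5]}")
    return a.astype(bool)


def confusion_counts(pred, gold) -> ConfusionCounts:
    """Pool exact TP/FP/FN/TN voxel counts over matching binary grids.

    ``pred`` and ``gold`` may be single slices, 3-D stacks, or sequences of
    slices; shapes must match element-wise.
    """
    if not isinstance(pred, np.ndarray):
        pred = np.stack([np.asarray(p) for p in pred])
        gold = np.stack([np.asarray(g) for g in gold])
    pred = _as_binary(pred, "pred")
    gold = _as_binary(gold, "gold")
    if pred.shape != gold.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gold {gold.shape}")
    tp = int(np.count_nonzero(pred & gold))
    fp = int(np.count_nonzero(pred & ~gold))
    fn = int(np.count_nonzero(~pred & gold))
    tn = int(np.count_nonzero(~pred & ~gold))
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP / (FP + 2TP + FN).

    Both masks empty is degenerate: returned as 1.0 with a warning (the two
    empty regions agree perfectly).
    """
    denom = c.fp + 2 * c.tp + c.fn
    if denom == 0:
        warnings.warn("DSC of two empty masks is degenerate; returning 1.0")
        return 1.0
    return 2.0 * c.tp / denom


def sensitivity(c: ConfusionCounts) -> float:
    """TP / (TP + FN); NaN with a warning when the gold region is empty."""
    if c.tp + c.fn == 0:
        warnings.warn("sensitivity undefined for empty gold mask; returning NaN")
        return float("nan")
    return c.tp / (c.tp + c.fn)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); NaN with a warning when the prediction is empty."""
    if c.tp + c.fp == 0:
        warnings.warn("precision undefined for empty prediction; returning NaN")
        return float("nan")
    return c.tp / (c.tp + c.fp)


def boundary_points_mm(mask: np.ndarray, spacing_mm: Sequence[float]) -> np.ndarray:
    """Extract boundary pixels of a (H, W[, S]) binary mask in mm coordinates.

    A positive pixel is a boundary pixel when at least one of its 4
    face-adjacent in-plane neighbours is background; pixels on the image edge
    count as boundary.  Coordinates are voxel-centre positions index*spacing.
    """
    m = _as_binary(mask, "mask")
    if m.ndim == 2:
        m = m[..., None]
    if m.ndim != 3:
        raise ValueError("mask must be 2-D or 3-D")
    interior = np.zeros_like(m)
    interior[1:-1, 1:-1, :] = (
        m[1:-1, 1:-1, :]
        & m[:-2, 1:-1, :]
        & m[2:, 1:-1, :]
        & m[1:-1, :-2, :]
        & m[1:-1, 2:, :]
    )
    boundary = m & ~interior
    idx = np.argwhere(boundary).astype(float)
    spacing = np.asarray(spacing_mm, dtype=float)
    if spacing.size == 2:
        spacing = np.append(spacing, 1.0)
    if spacing.size != 3 or np.any(spacing <= 0):
        raise ValueError("spacing must be 2 or 3 strictly positive values")
    return idx * spacing[None, :]


def msd(pred_mask: np.ndarray, gold_mask: np.ndarray,
        spacing_mm: Sequence[float]) -> float:
    """Symmetric mean surface distance between two masks, in mm.

    msd = 1/2 * [ mean_i min_j ||x_i - y_j|| + mean_j min_i ||x_i - y_j|| ]
    over the boundary point sets X (prediction) and Y (gold).  Undefined when
    either mask is empty (NaN with a warning).
    """
    x = boundary_points_mm(pred_mask, spacing_mm)
    y = boundary_points_mm(gold_mask, spacing_mm)
    if len(x) == 0 or len(y) == 0:
        warnings.warn("MSD undefined for an empty mask; returning NaN")
        return float("nan")
    d_xy = cKDTree(y).query(x)[0]
    d_yx = cKDTree(x).query(y)[0]
    return 0.5 * (d_xy.mean() + d_yx.mean())


def volume_difference_pct(gtva_cm3: float, gtvm_cm3: float) -> float:
    """Absolute volume difference |GTVa - GTVm| / GTVm * 100 (percent)."""
    if gtvm_cm3 <= 0:
        raise ValueError("manual volume must be positive")
    return abs(gtva_cm3 - gtvm_cm3) / gtvm_cm3 * 100.0


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation between two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


_METRICS = ("sensitivity", "precision", "dsc", "msd_mm",
            "gtvm_cm3", "gtva_cm3", "volume_diff_pct")


def aggregate_cohort(records: Sequence[MetricsRecord],
                     overall_label: str = "overall") -> CohortReport:
    """Aggregate per-patient rows into per-group and overall summary stats.

    For each metric and each group (plus the pooled cohort): mean, sample SD
    (n-1 denominator), median (midpoint of central order statistics for even
    n), min-max range, and the mean +/- 1.96*SD interval.  NaN entries (e.g.
    undefined MSD) are excluded per metric with a warning.
    """
    if not records:
        raise ValueError("no records to aggregate")
    for r in records:
        if np.isnan(r.volume_diff_pct) and r.gtvm_cm3 > 0:
            r.volume_diff_pct = volume_difference_pct(r.gtva_cm3, r.gtvm_cm3)
    groups = []
    for r in records:
        if r.group not in groups:
            groups.append(r.group)
    report = CohortReport(groups=tuple(groups) + (overall_label,))
    for group in report.groups:
        rows = [r for r in records
                if group == overall_label or r.group == group]
        if not rows:
            warnings.warn(f"empty group {group!r}; skipped")
            continue
        for metric in _METRICS:
            vals = np.array([getattr(r, metric) for r in rows], dtype=float)
            if np.isnan(vals).any():
                warnings.warn(f"{metric}: dropping NaN entries in {group!r}")
                vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
            report.stats[(group, metric)] = {
                "n": int(vals.size),
                "mean": mean,
                "sd": sd,
                "median": float(np.median(vals)),
                "min": float(vals.min()),
                "max": float(vals.max()),
                "ci_low": mean - 1.96 * sd,
                "ci_high": mean + 1.96 * sd,
            }
    gtvm = [r.gtvm_cm3 for r in records]
    gtva = [r.gtva_cm3 for r in records]
    if len(records) >= 3 and np.ptp(gtvm) > 0 and np.ptp(gtva) > 0:
        report.pearson_r = pearson_r(gtvm, gtva)
    logger.info("aggregated %d records into %d groups", len(records),
                len(report.groups))
    return report


def records_from_dataframe(df: pd.DataFrame) -> list[MetricsRecord]:
    records = []
    for _, row in df.iterrows():
        records.append(MetricsRecord(
            patient_id=str(row["patient_id"]),
            gtvm_cm3=float(row["gtvm_cm3"]),
            gtva_cm3=float(row["gtva_cm3"]),
            sensitivity=float(row["sensitivity"]),
            precision=float(row["precision"]),
            dsc=float(row["dsc"]),
            msd_mm=float(row["msd_mm"]),
            group=str(row.get("group", "")),
        ))
    return records


def load_reference_cohort() -> list[MetricsRecord]:
    """Load the packaged 22-patient dual-center reference results.

    Published per-patient head-and-neck PET-CT segmentation results (manual
    vs automatic volumes and overlap metrics from two centers), used as a
    regression fixture for the aggregation statistics.
    """
    with resources.files("gtvnet.data").joinpath(
            "reference_cohort_metrics.csv").open() as fh:
        df = pd.read_csv(fh)
    return records_from_dataframe(df)
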