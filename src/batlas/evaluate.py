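"""Overlap, volume and mean-value evaluation of paired segmentations.

The Dice similarity coefficient is computed from true-positive, false-
positive and false-negative voxel counts restricted to an evaluation
domain.  Target voxels outside the imaged volume of every atlas are
discarded (not counted as false negatives): a missing vote there reflects
subject positioning, not segmentation performance.  Volumes follow

    V_REF = (n_TP + n_FN) * voxel volume
    V_MAS = (n_TP + n_FP) * voxel volume

so that V_REF + V_MAS = (2 n_TP + n_FP + n_FN) * voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_io import BinaryMask, GridGeometry, GridMismatchError, QuantMap

__all__ = [
    "OverlapCounts",
    "EvaluationReport",
    "overlap_counts",
    "dice",
    "volumes",
    "region_means",
    "slice_selection",
    "evaluate_pair",
    "cohort_stats",
    "CohortStats",
]


@dataclass(frozen=True)
class OverlapCounts:
    """TP/FP/FN voxel counts of a test mask against a reference mask."""

    n_tp: int
    n_fp: int
    n_fn: int

    def __post_init__(self) -> None:
        if min(self.n_tp, self.n_fp, self.n_fn) < 0:
            raise ValueError("overlap counts must be non-negative")


@dataclass
class EvaluationReport:
    """Per-subject comparison of the MAS and REF segmentations."""

    subject_id: str
    dice: float
    v_ref_ml: float
    v_mas_ml: float
    mean_ff_ref: float
    mean_ff_mas: float
    mean_r2s_ref: float
    mean_r2s_mas: float
    domain_voxels: int
    counts: Optional[OverlapCounts] = None

    @property
    def delta_ff(self) -> float:
        return self.mean_ff_mas - self.mean_ff_ref

    @property
    def delta_r2s(self) -> float:
        return self.mean_r2s_mas - self.mean_r2s_ref

    @property
    def delta_volume_ml(self) -> float:
        return self.v_mas_ml - self.v_ref_ml

    def as_dict(self) -> dict:
        d = {
            "subject_id": self.subject_id,
            "dice": self.dice,
            "v_ref_ml": self.v_ref_ml,
            "v_mas_ml": self.v_mas_ml,
            "mean_ff_ref": self.mean_ff_ref,
            "mean_ff_mas": self.mean_ff_mas,
            "mean_r2s_ref": self.mean_r2s_ref,
            "mean_r2s_mas": self.mean_r2s_mas,
            "delta_ff": self.delta_ff,
            "delta_r2s": self.delta_r2s,
            "delta_volume_ml": self.delta_volume_ml,
            "domain_voxels": self.domain_voxels,
        }
        return d


def _require_compatible(*geoms: GridGeometry) -> None:
    ref = geoms[0]
    for g in geoms[1:]:
        if not ref.compatible_with(g):
            raise GridMismatchError("incompatible geometries in evaluation")


def overlap_counts(
    mas: BinaryMask, ref: BinaryMask, domain: Optional[BinaryMask] = None
) -> OverlapCounts:
    """TP/FP/FN counts within an evaluation domain.

    Reference voxels outside the domain are discarded, i.e. not counted as
    false negatives; likewise test voxels outside the domain are not false
    positives.
    """
    _require_compatible(mas.geometry, ref.geometry)
    if domain is None:
        dom = np.ones(mas.geometry.shape, dtype=bool)
    else:
        _require_compatible(mas.geometry, domain.geometry)
        dom = domain.values
    a = mas.values & dom
    b = ref.values & dom
    return OverlapCounts(
        n_tp=int((a & b).sum()),
        n_fp=int((a & ~b).sum()),
        n_fn=int((~a & b).sum()),
    )


def dice(counts: OverlapCounts) -> float:
    """Dice = 2 n_TP / (2 n_TP + n_FP + n_FN); undefined on all-zero counts."""
    denom = 2 * counts.n_tp + counts.n_fp + counts.n_fn
    if denom == 0:
        raise ValueError("Dice undefined: both masks empty within the domain")
    return 2.0 * counts.n_tp / denom


def volumes(counts: OverlapCounts, geometry: GridGeometry) -> tuple[float, float]:
    """(V_REF, V_MAS) in ml from overlap counts and voxel volume."""
    vox_ml = geometry.voxel_volume_mm3 / 1000.0
    return (
        (counts.n_tp + counts.n_fn) * vox_ml,
        (counts.n_tp + counts.n_fp) * vox_ml,
    )


def region_means(
    mask: BinaryMask, ff: QuantMap, r2s: QuantMap
) -> tuple[float, float]:
    """Arithmetic mean FF and R2* over the mask voxels."""
    _require_compatible(mask.geometry, ff.geometry, r2s.geometry)
    if not mask.values.any():
        raise ValueError("mean undefined over an empty mask")
    sel = mask.values
    return float(ff.values[sel].mean()), float(r2s.values[sel].mean())


def slice_selection(geometry: GridGeometry, rule: str = "all") -> BinaryMask:
    """Mask selecting axial slices by rule ('all', 'even', or 'odd').

    Slice numbering is 1-based (clinical convention), so 'even' on a
    25-slice stack selects slices 2, 4, ..., 24 — twelve slices.
    """
    if rule not in ("all", "even", "odd"):
        raise ValueError(f"unknown slice rule {rule!r}")
    mask = np.zeros(geometry.shape, dtype=bool)
    for k in range(geometry.shape[2]):
        number = k + 1
        if rule == "all" or (rule == "even") == (number % 2 == 0):
            mask[:, :, k] = True
    return BinaryMask(geometry, mask, label=f"slices:{rule}")


def evaluate_pair(
    subject_id: str,
    mas: BinaryMask,
    ref: BinaryMask,
    ff: QuantMap,
    r2s: QuantMap,
    fov: Optional[BinaryMask] = None,
    slices: str = "even",
) -> EvaluationReport:
    """Full per-subject evaluation: Dice, volumes, and mean FF/R2*.

    The evaluation domain is the intersection of the fusion FOV (if given)
    with the slice-selection mask.  Mean FF/R2* are computed over each
    segmentation restricted to the selected slices.
    """
    sel = slice_selection(mas.geometry, slices)
    dom = sel.values if fov is None else sel.values & fov.values
    domain = BinaryMask(mas.geometry, dom, "evaluation domain")
    counts = overlap_counts(mas, ref, domain)
    d = dice(counts)
    v_ref, v_mas = volumes(counts, mas.geometry)
    ref_sel = ref.with_values(ref.values & sel.values)
    mas_sel = mas.with_values(mas.values & sel.values)
    ff_ref, r2s_ref = region_means(ref_sel, ff, r2s)
    ff_mas, r2s_mas = region_means(mas_sel, ff, r2s)
    return EvaluationReport(
        subject_id=subject_id,
        dice=d,
        v_ref_ml=v_ref,
        v_mas_ml=v_mas,
        mean_ff_ref=ff_ref,
        mean_ff_mas=ff_mas,
        mean_r2s_ref=r2s_ref,
        mean_r2s_mas=r2s_mas,
        domain_voxels=int(domain.values.sum()),
        counts=counts,
    )


@dataclass
class CohortStats:
    """Paired-comparison statistics of one quantity across subjects."""

    pearson_r: float
    pearson_p: float
    t_statistic: float
    t_p: float
    delta_mean: float
    delta_sd: float
    n: int


def cohort_stats(
    reports: Sequence[EvaluationReport], x: str, y: str
) -> CohortStats:
    """Pearson r, two-tailed paired t-test, and delta mean +- SD of y - x.

    ``x`` and ``y`` name EvaluationReport fields (e.g. 'mean_ff_ref',
    'mean_ff_mas').
    """
    if len(reports) < 2:
        raise ValueError("at least 2 reports are required")
    xs = np.array([getattr(r, x) for r in reports], dtype=float)
    ys = np.array([getattr(r, y) for r in reports], dtype=float)
    if xs.std() == 0 or ys.std() == 0:
        raise ValueError("Pearson correlation undefined for zero-variance data")
    r, rp = stats.pearsonr(xs, ys)
    t, tp = stats.ttest_rel(ys, xs)
    deltas = ys - xs
    return CohortStats(
        pearson_r=float(r),
        pearson_p=float(rp),
        t_statistic=float(t),
        t_p=float(tp),
        delta_mean=float(deltas.mean()),
        delta_sd=float(deltas.std(ddof=1)),
        n=len(reports),
    )
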