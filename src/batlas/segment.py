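"""Fine adjustment, refinement, and the end-to-end segmentation pipelines.

The fine adjustment is shared by the reference (REF) and multi-atlas (MAS)
methods: inside a crude VOI it keeps adipose tissue by an FF threshold, an
in-plane erosion, and an R2* threshold.  The MAS pipeline additionally
refines the result by removing residual air/bone voxels (low total signal)
followed by per-slice dilation, hole filling and erosion, constrained so
refinement never adds voxels beyond the fine-adjusted region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask, GridMismatchError, QuantMap, SubjectStudy
from .fusion import CoverageMap, VotingParams, fuse_majority, fusion_fov, propagate_voi
from .preprocess import (
    SE_4N,
    BackgroundParams,
    SkinStripParams,
    preprocess_r2s,
    preprocess_support,
    preprocess_wf,
)
from .registration import (
    DeformationField,
    RegistrationBackend,
    RegistrationParams,
    SimpleITKBackend,
    SyntheticBackend,
)

__all__ = [
    "FineAdjustParams",
    "RefineParams",
    "Atlas",
    "SegmentationResult",
    "fine_adjust",
    "refine",
    "make_atlas",
    "run_mas",
    "run_ref",
]


@dataclass(frozen=True)
class FineAdjustParams:
    """Adipose-tissue extraction thresholds inside the crude VOI.

    Keep voxels with FF >= 40% (inclusive), erode one in-plane
    4-neighbourhood layer to trim probable border voxels, then keep voxels
    with R2* <= 50 s^-1.
    """

    ff_min: float = 0.40
    r2s_max: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ff_min <= 1.0:
            raise ValueError("ff_min must be a fraction in [0, 1]")
        if self.r2s_max < 0:
            raise ValueError("r2s_max must be >= 0")


@dataclass(frozen=True)
class RefineParams:
    """Residual air/bone removal after fine adjustment (MAS only)."""

    background: BackgroundParams = dc_field(default_factory=BackgroundParams)
    dilation_se: int = 3
    erosion_se: int = 3

    def __post_init__(self) -> None:
        for name in ("dilation_se", "erosion_se"):
            side = getattr(self, name)
            if side < 1 or side % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {side}")


@dataclass
class Atlas:
    """One preprocessed atlas: registration channels + crude VOI + FOV."""

    subject_id: str
    wf: QuantMap
    r2s: QuantMap
    voi: BinaryMask
    fov: BinaryMask

    def __post_init__(self) -> None:
        g = self.wf.geometry
        for name, member in (("r2s", self.r2s), ("voi", self.voi), ("fov", self.fov)):
            if not g.compatible_with(member.geometry):
                raise GridMismatchError(
                    f"atlas {self.subject_id!r}: {name} geometry incompatible"
                )


@dataclass
class SegmentationResult:
    """Final segmentation plus the evaluation FOV and per-stage provenance."""

    mask: BinaryMask
    fusion_fov: BinaryMask
    provenance: dict


def fine_adjust(
    voi: BinaryMask,
    ff: QuantMap,
    r2s: QuantMap,
    params: FineAdjustParams | None = None,
) -> BinaryMask:
    """Automated fine adjustment of a crude VOI (shared by REF and MAS).

    In order: (1) keep VOI voxels with FF >= ff_min; (2) one 2D
    4-neighbourhood erosion per axial slice; (3) keep voxels with
    R2* <= r2s_max.  Output is always a subset of the input VOI.
    """
    params = params or FineAdjustParams()
    for g in (ff.geometry, r2s.geometry):
        if not voi.geometry.compatible_with(g):
            raise GridMismatchError("fine_adjust: incompatible geometries")
    if not voi.values.any():
        warnings.warn("fine_adjust received an empty VOI", stacklevel=2)
        return voi.with_values(np.zeros_like(voi.values), "sBAT")
    mask = voi.values & (ff.values >= params.ff_min)
    eroded = np.zeros_like(mask)
    for k in range(mask.shape[2]):
        eroded[:, :, k] = ndimage.binary_erosion(mask[:, :, k], structure=SE_4N)
    mask = eroded & (r2s.values <= params.r2s_max)
    return voi.with_values(mask, "sBAT")


def refine(
    mask: BinaryMask,
    water: QuantMap,
    fat: QuantMap,
    params: RefineParams | None = None,
) -> BinaryMask:
    """Remove residual air/bone voxels from a fine-adjusted segmentation.

    Residual low-signal voxels inside the segmentation are found by
    thresholding the total water+fat signal, consolidated per slice by
    dilation, hole filling and erosion (so whole air/bone structures are
    captured together with their partial-volume borders), and removed.
    Refinement only ever removes voxels from the input mask.
    """
    params = params or RefineParams()
    for g in (water.geometry, fat.geometry):
        if not mask.geometry.compatible_with(g):
            raise GridMismatchError("refine: incompatible geometries")
    total = water.values + fat.values
    threshold = params.background.resolve(total)
    low = mask.values & (total <= threshold)
    dil_se = np.ones((params.dilation_se, params.dilation_se), dtype=bool)
    ero_se = np.ones((params.erosion_se, params.erosion_se), dtype=bool)
    airbone = np.zeros_like(low)
    for k in range(low.shape[2]):
        sl = ndimage.binary_dilation(low[:, :, k], structure=dil_se)
        sl = ndimage.binary_fill_holes(sl)
        airbone[:, :, k] = ndimage.binary_erosion(sl, structure=ero_se)
    return mask.with_values(mask.values & ~airbone, "sBAT refined")


def make_atlas(
    study: SubjectStudy,
    bg: BackgroundParams | None = None,
    skin: SkinStripParams | None = None,
) -> Atlas:
    """Preprocess an atlas subject's maps; the crude VOI must be present."""
    if study.voi is None:
        raise ValueError(f"atlas subject {study.subject_id!r} has no crude VOI")
    support = preprocess_support(study, bg, skin)
    return Atlas(
        subject_id=study.subject_id,
        wf=preprocess_wf(study, support=support),
        r2s=preprocess_r2s(study, support=support),
        voi=study.voi,
        fov=study.fov,
    )


def run_mas(
    target: SubjectStudy,
    atlases: Sequence[Atlas],
    backend: RegistrationBackend | None = None,
    registration: RegistrationParams | None = None,
    bg: BackgroundParams | None = None,
    skin: SkinStripParams | None = None,
    voting: VotingParams | None = None,
    fine: FineAdjustParams | None = None,
    refinement: RefineParams | None = None,
) -> SegmentationResult:
    """The full multi-atlas pipeline for one target subject.

    Preprocess the target, register every atlas to it, propagate the crude
    VOIs, fuse them by modified majority voting, fine-adjust, and refine.
    Deterministic given the backend and registration seed.
    """
    if not atlases:
        raise ValueError("at least one atlas is required")
    backend = backend or SimpleITKBackend()
    registration = registration or RegistrationParams()
    provenance: dict = {"stages": {}, "atlases": [a.subject_id for a in atlases]}

    support = preprocess_support(target, bg, skin)
    target_wf = preprocess_wf(target, support=support)
    target_r2s = preprocess_r2s(target, support=support)
    provenance["stages"]["support_voxels"] = int(support.values.sum())

    coverages: list[CoverageMap] = []
    for atlas in atlases:
        if isinstance(backend, SyntheticBackend):
            backend.select(atlas.subject_id)
        try:
            field = backend.register(
                atlas.wf, atlas.r2s, target_wf, target_r2s, registration
            )
        except Exception as exc:
            raise RuntimeError(
                f"registration of atlas {atlas.subject_id!r} failed: {exc}"
            ) from exc
        coverages.append(propagate_voi(atlas.voi, field, atlas_fov=atlas.fov))
        metrics = getattr(backend, "last_metrics", None)
        if metrics:
            provenance["stages"][f"metric_{atlas.subject_id}"] = dict(metrics)

    fused = fuse_majority(coverages, voting)
    fov = fusion_fov(coverages)
    provenance["stages"]["fused_voxels"] = int(fused.values.sum())

    adjusted = fine_adjust(fused, target.ff, target.r2s, fine)
    provenance["stages"]["fine_adjusted_voxels"] = int(adjusted.values.sum())
    final = refine(adjusted, target.water, target.fat, refinement)
    provenance["stages"]["refined_voxels"] = int(final.values.sum())
    return SegmentationResult(mask=final, fusion_fov=fov, provenance=provenance)


def run_ref(
    target: SubjectStudy,
    fine: FineAdjustParams | None = None,
) -> SegmentationResult:
    """The automated stage of the reference method.

    Fine adjustment applied directly to the manual crude VOI; no
    refinement, since air and bone are assumed to be avoided during manual
    delineation.
    """
    if target.voi is None:
        raise ValueError(f"subject {target.subject_id!r} has no manual crude VOI")
    mask = fine_adjust(target.voi, target.ff, target.r2s, fine)
    fov = target.fov
    return SegmentationResult(
        mask=mask,
        fusion_fov=fov,
        provenance={
            "stages": {"fine_adjusted_voxels": int(mask.values.sum())},
            "method": "REF",
        },
    )
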