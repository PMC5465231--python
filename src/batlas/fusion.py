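"""Label propagation and modified majority voting.

Each atlas's crude VOI is propagated through its deformation field with
linear interpolation, preserving fractional coverage values.  Because the
imaged volume only partially covers the depot and sits at slightly
different anatomical positions per subject, a voxel may map outside some
atlases' imaged volumes; the vote at that voxel is then taken only among
the atlases in which it is represented, and a voxel is labelled when more
than half of those atlases label it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core_io import BinaryMask, GridGeometry, GridMismatchError
from .registration import DeformationField, apply_field

__all__ = ["CoverageMap", "VotingParams", "propagate_voi", "fuse_majority", "fusion_fov"]


@dataclass
class CoverageMap:
    """Fractional label coverage of one propagated atlas VOI on the target grid.

    ``represented`` is true where the target voxel maps inside the atlas's
    imaged volume; coverage values where it is false are ignored by voting.
    """

    geometry: GridGeometry
    values: np.ndarray
    represented: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        represented = np.asarray(self.represented, dtype=bool)
        if values.shape != self.geometry.shape or represented.shape != self.geometry.shape:
            raise GridMismatchError("coverage arrays must match the geometry shape")
        if ((values < -1e-9) | (values > 1 + 1e-9)).any():
            raise ValueError("coverage values must lie in [0, 1]")
        self.values = np.clip(values, 0.0, 1.0)
        self.represented = represented


@dataclass(frozen=True)
class VotingParams:
    """Binarization threshold for a per-atlas vote and the majority rule.

    A propagated coverage >= ``binarize_at`` counts as one vote; a voxel is
    labelled when the yes-votes strictly exceed half of the representing
    atlases ("more than half", so an exact tie fails).
    """

    binarize_at: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.binarize_at <= 1.0:
            raise ValueError("binarize_at must be in (0, 1]")


def propagate_voi(
    voi: BinaryMask,
    field: DeformationField,
    atlas_fov: Optional[BinaryMask] = None,
) -> CoverageMap:
    """Propagate a crude atlas VOI to the target grid.

    Linear interpolation of the {0, 1} mask yields fractional coverage;
    ``represented`` is false where the mapped position exits the atlas grid
    or the atlas field of view.
    """
    values, represented = apply_field(
        field, voi, interpolation="linear", source_fov=atlas_fov
    )
    return CoverageMap(field.geometry, values, represented)


def _check_stack(coverages: Sequence[CoverageMap]) -> None:
    if not coverages:
        raise ValueError("at least one coverage map is required")
    ref = coverages[0].geometry
    for c in coverages[1:]:
        if not ref.compatible_with(c.geometry):
            raise GridMismatchError("coverage maps have incompatible geometries")


def fuse_majority(
    coverages: Sequence[CoverageMap], params: VotingParams | None = None
) -> BinaryMask:
    """Modified majority voting restricted to representing atlases.

    Per voxel, with m = number of atlases representing the voxel and
    v = number of those whose coverage >= binarize_at, the voxel is
    labelled iff m >= 1 and v > m/2.  Voxels with m = 0 are unlabelled
    (and excluded from evaluation via :func:`fusion_fov`).
    """
    params = params or VotingParams()
    _check_stack(coverages)
    rep = np.stack([c.represented for c in coverages])
    votes = np.stack(
        [(c.values >= params.binarize_at) & c.represented for c in coverages]
    )
    m = rep.sum(axis=0)
    v = votes.sum(axis=0)
    fused = (m >= 1) & (2 * v > m)
    return BinaryMask(coverages[0].geometry, fused, label="fused crude VOI")


def fusion_fov(coverages: Sequence[CoverageMap]) -> BinaryMask:
    """Mask of voxels represented in at least one atlas.

    Target voxels outside every atlas's imaged volume are discarded from
    the overlap evaluation rather than counted as errors.
    """
    _check_stack(coverages)
    any_rep = np.zeros(coverages[0].geometry.shape, dtype=bool)
    for c in coverages:
        any_rep |= c.represented
    return BinaryMask(coverages[0].geometry, any_rep, label="fusion FOV")
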