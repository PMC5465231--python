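"""Preprocessing of water-fat maps into registration inputs.

The water-fraction (WF = 1 - FF) map of a subject is reduced to an
"apparent lean tissue body": background (air, cortical bone) is removed by
thresholding the water+fat sum, and skin is stripped by an iterative
constrained 2D erosion that peels one voxel layer per iteration wherever
the layer looks like skin (low FF, high R2*).  Adipose tissue (high FF,
low R2*) and muscle (low FF, low R2*) fail the constraints and survive.
The same support also masks the R2* map, which is then median filtered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask, GridMismatchError, QuantMap, SubjectStudy

__all__ = [
    "SkinStripParams",
    "BackgroundParams",
    "compute_water_fraction",
    "remove_background",
    "strip_skin",
    "strip_skin_stages",
    "preprocess_wf",
    "preprocess_r2s",
    "preprocess_support",
]

#: In-plane 4-neighbourhood structuring element (edge-adjacent voxels).
SE_4N = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SkinStripParams:
    """Parameters of the iterative constrained skin stripping.

    Defaults follow the empirically determined skin properties: skin is the
    only boundary tissue with both FF <= 30% and R2* >= 80 s^-1.
    """

    ff_max: float = 0.30
    r2s_min: float = 80.0
    closing_se: int = 5
    final_erosion_se: int = 7
    max_iterations: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.ff_max <= 1.0:
            raise ValueError("ff_max must be a fraction in [0, 1]")
        if self.r2s_min < 0:
            raise ValueError("r2s_min must be >= 0")
        for name in ("closing_se", "final_erosion_se"):
            side = getattr(self, name)
            if side < 1 or side % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {side}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass(frozen=True)
class BackgroundParams:
    """Threshold on the water+fat sum separating tissue from air/bone.

    ``"auto"`` sets the threshold to ``auto_fraction`` of the 99th
    percentile of the sum signal — scale-free across signal-amplitude
    conventions.
    """

    sum_signal_threshold: Union[float, str] = "auto"
    auto_fraction: float = 0.05

    def __post_init__(self) -> None:
        t = self.sum_signal_threshold
        if isinstance(t, str):
            if t != "auto":
                raise ValueError(f"threshold must be numeric or 'auto', got {t!r}")
        elif t < 0:
            raise ValueError("sum_signal_threshold must be >= 0")

    def resolve(self, sum_signal: np.ndarray) -> float:
        if self.sum_signal_threshold == "auto":
            return float(self.auto_fraction * np.percentile(sum_signal, 99))
        return float(self.sum_signal_threshold)


def _check_compatible(*geoms) -> None:
    ref = geoms[0]
    for g in geoms[1:]:
        if not ref.compatible_with(g):
            raise GridMismatchError(f"incompatible geometries: {ref} vs {g}")


def compute_water_fraction(ff: QuantMap) -> QuantMap:
    """WF = 1 - FF voxelwise (an involution: applying it twice returns FF)."""
    if ff.quantity != "FF":
        raise ValueError(f"expected an FF map, got quantity {ff.quantity!r}")
    return QuantMap(ff.geometry, 1.0 - ff.values, "WF")


def remove_background(
    water: QuantMap, fat: QuantMap, params: BackgroundParams | None = None
) -> BinaryMask:
    """Body mask: true where water + fat exceeds the background threshold.

    Air and cortical bone carry near-zero water and fat signal and appear
    as noise in the quantitative maps; strict ``>`` excludes them.
    """
    params = params or BackgroundParams()
    _check_compatible(water.geometry, fat.geometry)
    total = water.values + fat.values
    threshold = params.resolve(total)
    body = total > threshold
    if not body.any():
        warnings.warn(
            "background removal produced an empty body mask; "
            "the sum-signal threshold is likely mis-set",
            stacklevel=2,
        )
    return BinaryMask(water.geometry, body, label="body")


def _boundary_layer_2d(mask: np.ndarray) -> np.ndarray:
    """Voxels removable by one in-plane 2D erosion with the 4-neighbourhood SE."""
    eroded = np.zeros_like(mask)
    for k in range(mask.shape[2]):
        eroded[:, :, k] = ndimage.binary_erosion(mask[:, :, k], structure=SE_4N)
    return mask & ~eroded


def _largest_component_3d(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n <= 1:
        return mask.copy()
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def _close_and_fill_2d(mask: np.ndarray, side: int) -> np.ndarray:
    se = np.ones((side, side), dtype=bool)
    out = np.zeros_like(mask)
    for k in range(mask.shape[2]):
        sl = ndimage.binary_closing(mask[:, :, k], structure=se)
        out[:, :, k] = ndimage.binary_fill_holes(sl)
    return out


def _erode_2d(mask: np.ndarray, se: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    for k in range(mask.shape[2]):
        out[:, :, k] = ndimage.binary_erosion(mask[:, :, k], structure=se)
    return out


def strip_skin_stages(
    body: BinaryMask,
    ff: QuantMap,
    r2s: QuantMap,
    params: SkinStripParams | None = None,
) -> dict[str, BinaryMask]:
    """Run skin stripping and return every intermediate stage.

    Stages, in order:

    ``constrained``
        Iterated constrained peeling: at each iteration the current in-plane
        boundary layer is computed from the mask state at iteration start
        and only boundary voxels with FF <= ff_max AND R2* >= r2s_min are
        removed — one voxel layer of skin at a time, simultaneously over the
        whole layer (so the result does not depend on voxel visit order).
        Stops at a fixpoint or after ``max_iterations``.
    ``largest``
        Largest 3D 26-connected component (drops residual clusters in skin
        or outside the body).
    ``closed``
        Per-slice 2D morphological closing (square SE) with filling of
        enclosed holes, correcting rare erosion underneath the skin.
    ``final``
        Per-slice unconstrained 2D erosion with the large square SE,
        trimming any residual skin voxels.
    """
    params = params or SkinStripParams()
    _check_compatible(body.geometry, ff.geometry, r2s.geometry)
    mask = body.values.copy()
    if not mask.any():
        warnings.warn("strip_skin received an empty body mask", stacklevel=2)
        empty = body.with_values(mask, "stripped")
        return {"constrained": empty, "largest": empty, "closed": empty, "final": empty}

    skin_like = (ff.values <= params.ff_max) & (r2s.values >= params.r2s_min)
    for _ in range(params.max_iterations):
        removable = _boundary_layer_2d(mask) & skin_like
        if not removable.any():
            break
        mask = mask & ~removable

    stages = {"constrained": body.with_values(mask, "constrained")}
    mask = _largest_component_3d(mask)
    stages["largest"] = body.with_values(mask, "largest-component")
    mask = _close_and_fill_2d(mask, params.closing_se)
    stages["closed"] = body.with_values(mask, "closed-filled")
    se = np.ones((params.final_erosion_se, params.final_erosion_se), dtype=bool)
    mask = _erode_2d(mask, se)
    stages["final"] = body.with_values(mask, "stripped")
    return stages


def strip_skin(
    body: BinaryMask,
    ff: QuantMap,
    r2s: QuantMap,
    params: SkinStripParams | None = None,
) -> BinaryMask:
    """Strip skin from a body mask; see :func:`strip_skin_stages`."""
    return strip_skin_stages(body, ff, r2s, params)["final"]


def preprocess_support(
    study: SubjectStudy,
    bg: BackgroundParams | None = None,
    skin: SkinStripParams | None = None,
) -> BinaryMask:
    """Support mask after background removal and skin stripping.

    The subject FOV is intersected first so never-imaged voxels cannot
    enter the body mask.
    """
    body = remove_background(study.water, study.fat, bg)
    body = body.with_values(body.values & study.fov.values, "body")
    return strip_skin(body, study.ff, study.r2s, skin)


def preprocess_wf(
    study: SubjectStudy,
    bg: BackgroundParams | None = None,
    skin: SkinStripParams | None = None,
    support: BinaryMask | None = None,
) -> QuantMap:
    """WF map zeroed outside the stripped body support.

    Adipose tissue has low WF, so the surviving high-intensity structure is
    the lean tissue body used as the registration's primary channel.
    """
    if support is None:
        support = preprocess_support(study, bg, skin)
    wf = compute_water_fraction(study.ff)
    return QuantMap(wf.geometry, np.where(support.values, wf.values, 0.0), "WF")


def preprocess_r2s(
    study: SubjectStudy,
    bg: BackgroundParams | None = None,
    skin: SkinStripParams | None = None,
    support: BinaryMask | None = None,
) -> QuantMap:
    """R2* masked by the same support as the WF map, then 3x3x3 median filtered.

    The filtered map keeps high intensities near bone and air-filled
    structures, guiding the matching of those anatomies during
    registration.
    """
    if support is None:
        support = preprocess_support(study, bg, skin)
    masked = np.where(support.values, study.r2s.values, 0.0)
    filtered = ndimage.median_filter(masked, size=(3, 3, 3), mode="constant", cval=0.0)
    return QuantMap(study.r2s.geometry, np.where(support.values, filtered, 0.0), "R2*")
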