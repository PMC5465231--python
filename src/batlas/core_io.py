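"""Core data model: quantitative maps, binary masks, grids, and NIfTI I/O.

All volumes live on a regular 3D grid indexed ``(x, y, z)`` with the third
axis running along the slice (axial) direction.  Fat-fraction (FF) and
water-fraction (WF) values are stored as dimensionless fractions in [0, 1];
R2* is stored in s^-1; water/fat channels are non-negative arbitrary signal
units.  Physical positions are ``index * spacing`` in mm (the origin and
orientation of the scanner frame carry no information for pairwise
registration of co-registered maps, so they are not modelled).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "GridGeometry",
    "QuantMap",
    "BinaryMask",
    "SubjectStudy",
    "QUANTITIES",
    "read_volume",
    "write_volume",
    "read_mask",
    "assert_compatible",
    "GridMismatchError",
    "MapFormatError",
]

#: Recognised map kinds.  FF/WF are fractions, R2* is a rate, water/fat and
#: sum-signal are raw magnitudes.
QUANTITIES = ("FF", "WF", "R2*", "water", "fat", "sum-signal")
_FRACTION_QUANTITIES = ("FF", "WF")


class GridMismatchError(ValueError):
    """Two volumes do not share shape and voxel spacing."""


class MapFormatError(ValueError):
    """A file is not a readable 3D NIfTI volume."""


@dataclass(frozen=True)
class GridGeometry:
    """Shape and voxel spacing of a regular 3D grid.

    Parameters
    ----------
    shape : tuple of int
        Grid size ``(nx, ny, nz)``; the third axis is the slice direction.
    spacing : tuple of float
        Voxel spacing in mm, default ``(1.0, 1.0, 2.0)`` matching a typical
        axial water-fat protocol (1 mm in-plane, 2 mm slices).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 2.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or len(spacing) != 3:
            raise ValueError("geometry must be 3D")
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"all spacings must be > 0, got {spacing}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_slices(self) -> int:
        return self.shape[2]

    def compatible_with(self, other: "GridGeometry") -> bool:
        return self.shape == other.shape and np.allclose(
            self.spacing, other.spacing, rtol=0.0, atol=1e-6
        )


def _clip_fraction(values: np.ndarray) -> np.ndarray:
    # Reconstruction noise can push FF/WF slightly outside [0, 1]; clip.
    return np.clip(values, 0.0, 1.0)


@dataclass
class QuantMap:
    """A 3D scalar quantitative map on a :class:`GridGeometry`."""

    geometry: GridGeometry
    values: np.ndarray
    quantity: str = "FF"

    def __post_init__(self) -> None:
        if self.quantity not in QUANTITIES:
            raise ValueError(
                f"unknown quantity {self.quantity!r}; expected one of {QUANTITIES}"
            )
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != self.geometry.shape:
            raise GridMismatchError(
                f"values shape {values.shape} != geometry shape {self.geometry.shape}"
            )
        if self.quantity in _FRACTION_QUANTITIES:
            values = _clip_fraction(values)
        elif self.quantity == "R2*":
            values = np.maximum(values, 0.0)
        self.values = values

    def with_values(self, values: np.ndarray, quantity: Optional[str] = None) -> "QuantMap":
        return QuantMap(self.geometry, values, quantity or self.quantity)


@dataclass
class BinaryMask:
    """A boolean 3D mask on a :class:`GridGeometry`."""

    geometry: GridGeometry
    values: np.ndarray
    label: str = "mask"

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.shape != self.geometry.shape:
            raise GridMismatchError(
                f"mask shape {values.shape} != geometry shape {self.geometry.shape}"
            )
        self.values = values.astype(bool)

    @property
    def count(self) -> int:
        return int(self.values.sum())

    def with_values(self, values: np.ndarray, label: Optional[str] = None) -> "BinaryMask":
        return BinaryMask(self.geometry, values, label or self.label)


@dataclass
class SubjectStudy:
    """Co-registered water-fat maps of one subject, plus optional crude VOI.

    ``fov`` marks where the subject was actually imaged; it defaults to
    all-true.  The field-of-view only partially covers the
    cervical-supraclavicular depot and sits at slightly different anatomical
    positions in different subjects, which is why it is carried explicitly.
    """

    subject_id: str
    water: QuantMap
    fat: QuantMap
    ff: QuantMap
    r2s: QuantMap
    voi: Optional[BinaryMask] = None
    fov: Optional[BinaryMask] = None

    def __post_init__(self) -> None:
        if self.fov is None:
            self.fov = BinaryMask(
                self.ff.geometry,
                np.ones(self.ff.geometry.shape, dtype=bool),
                label="FOV",
            )
        members = {
            "water": self.water.geometry,
            "fat": self.fat.geometry,
            "ff": self.ff.geometry,
            "r2s": self.r2s.geometry,
            "fov": self.fov.geometry,
        }
        if self.voi is not None:
            members["voi"] = self.voi.geometry
        ref_name, ref = next(iter(members.items()))
        for name, geom in members.items():
            if not ref.compatible_with(geom):
                raise GridMismatchError(
                    f"subject {self.subject_id!r}: field {name!r} geometry "
                    f"{geom} incompatible with {ref_name!r} geometry {ref}"
                )

    @property
    def geometry(self) -> GridGeometry:
        return self.ff.geometry


# ---------------------------------------------------------------------------
# NIfTI-1 I/O


def _affine_from_geometry(geometry: GridGeometry) -> np.ndarray:
    aff = np.diag(list(geometry.spacing) + [1.0])
    return aff


def _geometry_from_img(img: nib.Nifti1Image) -> GridGeometry:
    shape = img.shape
    zooms = img.header.get_zooms()[:3]
    return GridGeometry(tuple(shape), tuple(float(z) for z in zooms))


def read_volume(path: str | Path, quantity: str = "FF") -> QuantMap:
    """Read a 3D NIfTI-1 file as a :class:`QuantMap`.

    Spacing is taken from the header zooms; FF/WF values are clipped to
    [0, 1] on construction.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several flavours
        raise MapFormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise MapFormatError(
            f"{path}: expected a 3D image, got shape {tuple(img.shape)}"
        )
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    return QuantMap(_geometry_from_img(img), data, quantity)


def read_mask(path: str | Path, label: str = "mask") -> BinaryMask:
    """Read a 3D NIfTI-1 file as a :class:`BinaryMask` (nonzero = true)."""
    qmap = read_volume(path, quantity="sum-signal")
    return BinaryMask(qmap.geometry, qmap.values > 0.5, label)


def write_volume(volume: QuantMap | BinaryMask, path: str | Path) -> None:
    """Write a map (float32) or mask (uint8 {0,1}) as NIfTI-1.

    Re-reading reproduces masks bit-exactly and maps to float32 precision.
    """
    path = Path(path)
    if isinstance(volume, BinaryMask):
        data = volume.values.astype(np.uint8)
    else:
        data = volume.values.astype(np.float32)
    img = nib.Nifti1Image(data, _affine_from_geometry(volume.geometry))
    img.header.set_zooms(volume.geometry.spacing)
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise OSError(f"failed to write {path}: {exc}") from exc


def assert_compatible(studies: Sequence[SubjectStudy]) -> None:
    """Raise :class:`GridMismatchError` unless all study grids match."""
    if not studies:
        raise ValueError("empty study list")
    ref = studies[0]
    for other in studies[1:]:
        ga, gb = ref.geometry, other.geometry
        if ga.shape != gb.shape:
            raise GridMismatchError(
                f"subjects {ref.subject_id!r} and {other.subject_id!r} "
                f"differ in shape: {ga.shape} vs {gb.shape}"
            )
        if not np.allclose(ga.spacing, gb.spacing, rtol=0.0, atol=1e-6):
            raise GridMismatchError(
                f"subjects {ref.subject_id!r} and {other.subject_id!r} "
                f"differ in spacing: {ga.spacing} vs {gb.spacing}"
            )
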