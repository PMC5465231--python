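"""Synthetic water-fat phantoms with ground truth for every pipeline stage.

A phantom emulates the tissue structure the segmentation pipeline relies
on in the cervical-supraclavicular region: an elliptical body cross
section wrapped in skin (low FF, high R2*), a subcutaneous fat ring and a
deep adipose pocket (high FF, low R2*), lean tissue (low FF, moderate
R2*), two near-signal-free bone bars emulating clavicula and scapula, and
low-signal lung regions.  Water and fat channels are synthesized per
compartment with additive Gaussian noise before the FF map is recomputed,
so FF noise is signal-dependent as in real magnitude data.

A cohort is built by warping one base phantom with smooth random b-spline
deformations (plus translation jitter and field-of-view shifts), storing
the true deformation fields so registration and propagation can be tested
against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Optional

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask, GridGeometry, QuantMap, SubjectStudy
from .registration import (
    DeformationField,
    apply_field,
    compose_fields,
    identity_field,
    invert_field,
)

__all__ = [
    "LABELS",
    "TissueParams",
    "DeformationSpec",
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "derive_subject",
    "make_cohort",
    "true_pair_field",
]

#: Compartment label codes in the truth volume.
LABELS = {
    "air": 0,
    "lean": 1,
    "sat": 2,
    "sbat": 3,
    "skin": 4,
    "bone": 5,
    "lung": 6,
}


@dataclass(frozen=True)
class TissueParams:
    """Per-compartment signal model: FF mean, R2* mean (s^-1), amplitude."""

    ff: float
    r2s: float
    amplitude: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ff <= 1.0:
            raise ValueError("tissue FF mean must be in [0, 1]")
        if self.r2s < 0 or self.amplitude < 0:
            raise ValueError("tissue R2* and amplitude must be >= 0")


def _default_tissues() -> dict[str, TissueParams]:
    # Values sit clearly on the correct side of the pipeline thresholds
    # (FF 0.30/0.40; R2* 50/80 s^-1): the thresholds are the object under
    # test, not tissue realism.
    return {
        "air": TissueParams(ff=0.5, r2s=50.0, amplitude=0.0),
        "lean": TissueParams(ff=0.10, r2s=30.0, amplitude=1.0),
        "sat": TissueParams(ff=0.90, r2s=20.0, amplitude=1.0),
        "sbat": TissueParams(ff=0.90, r2s=20.0, amplitude=1.0),
        "skin": TissueParams(ff=0.10, r2s=100.0, amplitude=1.0),
        "bone": TissueParams(ff=0.5, r2s=120.0, amplitude=0.0),
        "lung": TissueParams(ff=0.5, r2s=60.0, amplitude=0.02),
    }


@dataclass(frozen=True)
class DeformationSpec:
    """Smooth random deformation for deriving subjects from the base phantom."""

    amplitude_mm: float = 6.0
    control_spacing_mm: float = 32.0
    translation_jitter_mm: float = 2.0
    fov_shift_slices: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_mm < 0 or self.control_spacing_mm <= 0:
            raise ValueError("invalid deformation spec")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, anatomy and signal model of the base phantom."""

    geometry: GridGeometry = dc_field(
        default_factory=lambda: GridGeometry((96, 64, 12), (1.0, 1.0, 2.0))
    )
    body_semi_axes: tuple[int, int] = (40, 24)
    skin_thickness: int = 2
    sat_thickness: int = 3
    bone_offset_y: int = 10
    bone_half_length: int = 26
    bone_half_thickness: int = 2
    sbat_semi_axes: tuple[int, int, int] = (16, 6, 4)
    lung_semi_axes: tuple[int, int] = (7, 5)
    noise_sd: float = 0.02
    r2s_noise_sd: float = 2.0
    #: R2* elevation (s^-1) in the two-voxel tissue halo around bone/air.
    r2s_halo: float = 40.0
    #: Smooth anatomy-anchored intensity texture (muscle groups, fascia,
    #: vasculature) superimposed on the compartment means.  Unlike the
    #: voxelwise noise it deforms with the subject, so it carries the
    #: information deformable registration exploits in real maps.  The
    #: amplitudes keep every compartment clearly on its side of the
    #: pipeline thresholds.
    texture_ff_sd: float = 0.04
    texture_r2s_sd: float = 4.0
    texture_smoothness_vox: float = 3.0
    tissues: Optional[dict[str, TissueParams]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.skin_thickness < 1:
            raise ValueError("skin thickness must be >= 1")
        if self.noise_sd < 0 or self.r2s_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if min(self.body_semi_axes) <= self.skin_thickness + self.sat_thickness:
            raise ValueError("body too small for the requested skin/SAT thickness")

    def tissue_table(self) -> dict[str, TissueParams]:
        return dict(self.tissues) if self.tissues else _default_tissues()


@dataclass
class PhantomTruth:
    """Ground truth of one phantom subject.

    ``sbat`` is the raw anatomical adipose pocket.  ``sbat_ref`` is the
    reference-standard segmentation of that pocket: the pocket after the
    ideal fine adjustment (FF/R2* thresholds pass everywhere inside it, so
    this is one in-plane erosion), which deliberately excludes the
    partial-volume border layer.  Segmentation outputs are judged against
    ``sbat_ref`` — the phantom analogue of a reference-method
    segmentation — since the protocol itself defines the target with
    border exclusion.
    """

    labels: np.ndarray
    sbat: BinaryMask
    sbat_ref: BinaryMask
    fov: BinaryMask
    field_to_base: Optional[DeformationField] = None
    #: Anatomy-anchored texture fields; deformed along with the labels.
    ff_texture: Optional[np.ndarray] = None
    r2s_texture: Optional[np.ndarray] = None

    def compartment_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


# ---------------------------------------------------------------------------
# Base phantom construction


def _label_volume(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.geometry.shape
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ax, ay = spec.body_semi_axes
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    body2d = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0

    # Peel rings with in-plane 4-neighbourhood erosion.
    se = ndimage.generate_binary_structure(2, 1)
    interior = ndimage.binary_erosion(body2d, se, iterations=spec.skin_thickness)
    skin2d = body2d & ~interior
    deep = ndimage.binary_erosion(interior, se, iterations=spec.sat_thickness)
    sat2d = interior & ~deep

    labels2d = np.zeros((nx, ny), dtype=np.uint8)
    labels2d[deep] = LABELS["lean"]
    labels2d[sat2d] = LABELS["sat"]
    labels2d[skin2d] = LABELS["skin"]

    # Two bone bars (clavicula/scapula analogues) inside the lean interior.
    for sign in (-1, 1):
        by = cy + sign * spec.bone_offset_y
        bone = (
            (np.abs(xx - cx) <= spec.bone_half_length)
            & (np.abs(yy - by) <= spec.bone_half_thickness)
            & deep
        )
        labels2d[bone] = LABELS["bone"]

    # Lungs: low-signal ellipses near the lateral body edges.
    for sign in (-1, 1):
        lx = cx + sign * (ax - spec.lung_semi_axes[0] - spec.skin_thickness
                          - spec.sat_thickness - 3)
        lung = (
            ((xx - lx) / spec.lung_semi_axes[0]) ** 2
            + ((yy - cy) / spec.lung_semi_axes[1]) ** 2
            <= 1.0
        ) & deep
        labels2d[lung & (labels2d == LABELS["lean"])] = LABELS["lung"]

    labels = np.repeat(labels2d[:, :, None], nz, axis=2)

    # sBAT pocket: ellipsoid between the two bone bars, carved from lean.
    sx, sy, sz = spec.sbat_semi_axes
    cz = (nz - 1) / 2.0
    zz = np.arange(nz)
    pocket = (
        ((xx[..., None] - cx) / sx) ** 2
        + ((yy[..., None] - cy) / sy) ** 2
        + ((zz[None, None, :] - cz) / sz) ** 2
        <= 1.0
    )
    labels[pocket & (labels == LABELS["lean"])] = LABELS["sbat"]
    return labels


def _anatomy_texture(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Smooth zero-mean texture fields for FF and R2*.

    Clipped at 2.5 SD so every compartment stays on its side of the
    pipeline thresholds.
    """
    shape = spec.geometry.shape

    def one(sd: float) -> np.ndarray:
        if sd <= 0:
            return np.zeros(shape)
        raw = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, shape), spec.texture_smoothness_vox
        )
        std = raw.std()
        if std == 0:
            return np.zeros(shape)
        raw *= sd / std
        return np.clip(raw, -2.5 * sd, 2.5 * sd)

    return one(spec.texture_ff_sd), one(spec.texture_r2s_sd)


def _synthesize_signals(
    labels: np.ndarray,
    fov: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
    ff_texture: Optional[np.ndarray] = None,
    r2s_texture: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Water, fat, FF and R2* volumes from a label volume."""
    tissues = spec.tissue_table()
    shape = labels.shape
    amp = np.zeros(shape)
    ff_mean = np.zeros(shape)
    r2s_mean = np.zeros(shape)
    for name, code in LABELS.items():
        t = tissues[name]
        sel = labels == code
        amp[sel] = t.amplitude
        ff_mean[sel] = t.ff
        r2s_mean[sel] = t.r2s

    # Anatomy-anchored texture rides on the compartment means within
    # signal-bearing tissue only.
    in_tissue = amp > 0
    if ff_texture is not None:
        ff_mean = np.where(
            in_tissue, np.clip(ff_mean + ff_texture, 0.01, 0.99), ff_mean
        )
    if r2s_texture is not None:
        r2s_mean = np.where(
            in_tissue, np.maximum(r2s_mean + r2s_texture, 0.0), r2s_mean
        )

    # Susceptibility effects elevate R2* in tissue near bone and air-filled
    # structures; this halo is what lets the preprocessed R2* map guide the
    # matching of those anatomies during registration.
    near_src = (
        (labels == LABELS["bone"])
        | (labels == LABELS["lung"])
        | (labels == LABELS["air"])
    )
    # Restricted to lean tissue: adipose compartments keep their nominal
    # R2* so the pipeline's thresholds stay unambiguous on phantoms.
    halo = (
        ndimage.binary_dilation(
            near_src, structure=ndimage.generate_binary_structure(3, 1), iterations=2
        )
        & ~near_src
        & (labels == LABELS["lean"])
    )
    r2s_mean = np.where(halo, r2s_mean + spec.r2s_halo, r2s_mean)

    water = amp * (1.0 - ff_mean) + rng.normal(0.0, spec.noise_sd, shape)
    fat = amp * ff_mean + rng.normal(0.0, spec.noise_sd, shape)
    water = np.maximum(water, 0.0)
    fat = np.maximum(fat, 0.0)
    total = water + fat
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = np.where(total > 0, fat / np.maximum(total, 1e-12), 0.0)
    r2s = np.maximum(r2s_mean + rng.normal(0.0, spec.r2s_noise_sd, shape), 0.0)
    # Outside the imaged volume nothing was acquired.
    water[~fov] = 0.0
    fat[~fov] = 0.0
    ff[~fov] = 0.0
    r2s[~fov] = 0.0
    return water, fat, ff, r2s


def _study_from_labels(
    subject_id: str,
    labels: np.ndarray,
    fov: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
    field_to_base: Optional[DeformationField] = None,
    ff_texture: Optional[np.ndarray] = None,
    r2s_texture: Optional[np.ndarray] = None,
) -> tuple[SubjectStudy, PhantomTruth]:
    geom = spec.geometry
    water, fat, ff, r2s = _synthesize_signals(
        labels, fov, spec, rng, ff_texture, r2s_texture
    )
    fov_mask = BinaryMask(geom, fov, "FOV")
    pocket = (labels == LABELS["sbat"]) & fov
    sbat = BinaryMask(geom, pocket, "true sBAT")
    se = ndimage.generate_binary_structure(2, 1)
    eroded = np.zeros_like(pocket)
    for k in range(pocket.shape[2]):
        eroded[:, :, k] = ndimage.binary_erosion(pocket[:, :, k], structure=se)
    sbat_ref = BinaryMask(geom, eroded, "reference sBAT")
    study = SubjectStudy(
        subject_id=subject_id,
        water=QuantMap(geom, water, "water"),
        fat=QuantMap(geom, fat, "fat"),
        ff=QuantMap(geom, ff, "FF"),
        r2s=QuantMap(geom, r2s, "R2*"),
        fov=fov_mask,
    )
    truth = PhantomTruth(
        labels=labels,
        sbat=sbat,
        sbat_ref=sbat_ref,
        fov=fov_mask,
        field_to_base=field_to_base,
        ff_texture=ff_texture,
        r2s_texture=r2s_texture,
    )
    return study, truth


def make_phantom(
    spec: PhantomSpec | None = None, seed: Optional[int] = None
) -> tuple[SubjectStudy, PhantomTruth]:
    """Build the base phantom; deterministic given the seed."""
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    labels = _label_volume(spec)
    ff_texture, r2s_texture = _anatomy_texture(spec, rng)
    fov = np.ones(spec.geometry.shape, dtype=bool)
    return _study_from_labels(
        "base", labels, fov, spec, rng,
        ff_texture=ff_texture, r2s_texture=r2s_texture,
    )


# ---------------------------------------------------------------------------
# Derived subjects


def _random_bspline_field(
    geometry: GridGeometry, dspec: DeformationSpec, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random displacement (mm) with max amplitude ``amplitude_mm``."""
    shape = np.asarray(geometry.shape)
    spacing = np.asarray(geometry.spacing)
    phys = shape * spacing
    ctrl = np.maximum(2, np.ceil(phys / dspec.control_spacing_mm).astype(int) + 1)
    disp = np.zeros(tuple(shape) + (3,))
    for c in range(3):
        coarse = rng.normal(0.0, 1.0, tuple(ctrl))
        zoom = shape / ctrl
        fine = ndimage.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
        disp[..., c] = fine
    mags = np.linalg.norm(disp, axis=-1)
    peak = mags.max()
    if peak > 0:
        disp *= dspec.amplitude_mm / peak
    return disp


def _jacobian_ok(disp: np.ndarray, spacing) -> bool:
    """True if the map x -> x + d(x) has positive Jacobian determinant."""
    grads = np.empty(disp.shape[:-1] + (3, 3))
    for c in range(3):
        for d in range(3):
            grads[..., c, d] = np.gradient(disp[..., c], spacing[d], axis=d)
    jac = np.eye(3) + grads
    det = np.linalg.det(jac)
    return bool((det > 0).all())


def derive_subject(
    base: tuple[SubjectStudy, PhantomTruth],
    spec: PhantomSpec | None = None,
    deformation: DeformationSpec | None = None,
    seed: int = 1,
    subject_id: Optional[str] = None,
) -> tuple[SubjectStudy, PhantomTruth]:
    """Warp the base phantom into a new subject with its own noise and FOV.

    The stored ``field_to_base`` maps each derived-subject voxel position to
    the corresponding base position; labels are pulled through it with
    nearest-neighbour sampling and signals are re-synthesized with fresh
    noise, so truth masks transform exactly consistently with the field.
    The deformation is regenerated at reduced amplitude if it folds
    (negative Jacobian), and fails after 5 attempts.
    """
    spec = spec or PhantomSpec()
    deformation = deformation or DeformationSpec()
    base_study, base_truth = base
    geom = base_study.geometry
    rng = np.random.default_rng(seed)

    amplitude = deformation.amplitude_mm
    disp = None
    for _ in range(5):
        trial = replace(deformation, amplitude_mm=amplitude)
        cand = _random_bspline_field(geom, trial, rng)
        if deformation.translation_jitter_mm > 0:
            cand = cand + rng.uniform(
                -deformation.translation_jitter_mm,
                deformation.translation_jitter_mm,
                size=3,
            )
        if _jacobian_ok(cand, geom.spacing):
            disp = cand
            break
        amplitude *= 0.7
    if disp is None:
        raise RuntimeError("could not generate a fold-free deformation in 5 attempts")

    field = DeformationField(geom, disp)
    label_map = QuantMap(geom, base_truth.labels.astype(float), "sum-signal")
    warped, _inside = apply_field(field, label_map, interpolation="nearest")
    labels = warped.astype(np.uint8)

    def _warp_texture(tex: Optional[np.ndarray]) -> Optional[np.ndarray]:
        if tex is None:
            return None
        out, _ = apply_field(
            field, QuantMap(geom, tex + 1000.0, "sum-signal"), interpolation="linear"
        )  # offset separates real values from the out-of-grid zero fill
        return np.where(out > 0, out - 1000.0, 0.0)

    fov = np.ones(geom.shape, dtype=bool)
    shift = deformation.fov_shift_slices
    if shift > 0:
        fov[:, :, :shift] = False
    elif shift < 0:
        fov[:, :, shift:] = False

    return _study_from_labels(
        subject_id or f"derived-{seed}",
        labels,
        fov,
        spec,
        rng,
        field_to_base=field,
        ff_texture=_warp_texture(base_truth.ff_texture),
        r2s_texture=_warp_texture(base_truth.r2s_texture),
    )


def true_pair_field(
    atlas_truth: PhantomTruth, target_truth: PhantomTruth
) -> DeformationField:
    """Ground-truth target→atlas field composed through the base phantom.

    The target's stored field maps target space to base space; the inverse
    of the atlas's stored field maps base space to atlas space.  Their
    composition is what a perfect registration of the atlas to the target
    would return.
    """
    f_target = target_truth.field_to_base
    f_atlas = atlas_truth.field_to_base
    geom = target_truth.fov.geometry
    if f_target is None:
        f_target = identity_field(geom)
    if f_atlas is None or not np.any(f_atlas.displacement):
        return f_target
    f_atlas_inv = invert_field(f_atlas)
    return compose_fields(f_target, f_atlas_inv, f_atlas_inv.geometry)


def _crude_voi(truth: PhantomTruth, dilation_iterations: int = 3) -> BinaryMask:
    """Crude VOI emulating manual delineation: the true pocket generously
    dilated, keeping adjacent lean tissue but avoiding skin, bone and air."""
    struct = ndimage.generate_binary_structure(3, 1)
    dil = ndimage.binary_dilation(
        truth.sbat.values, structure=struct, iterations=dilation_iterations
    )
    allowed = (truth.labels == LABELS["sbat"]) | (truth.labels == LABELS["lean"])
    voi = dil & allowed & truth.fov.values
    return BinaryMask(truth.fov.geometry, voi, "crude sBAT VOI")


def make_cohort(
    n_atlases: int = 9,
    n_targets: int = 4,
    spec: PhantomSpec | None = None,
    deformation: DeformationSpec | None = None,
    seed: int = 0,
    fov_jitter_slices: int = 1,
    voi_dilation: int = 3,
) -> tuple[
    list[tuple[SubjectStudy, PhantomTruth]],
    list[tuple[SubjectStudy, PhantomTruth]],
]:
    """Independent derived subjects from one base phantom.

    Every subject receives a crude VOI (the dilated true pocket including
    adjacent lean tissue); for atlases it plays the atlas delineation, for
    targets the reference method's manual delineation.  Field-of-view
    shifts of up to ``fov_jitter_slices`` slices emulate inter-subject
    differences in imaged-volume placement.
    """
    if n_atlases < 1 or n_targets < 1:
        raise ValueError("cohort sizes must be >= 1")
    spec = spec or PhantomSpec()
    deformation = deformation or DeformationSpec()
    base = make_phantom(spec, seed=seed)
    rng = np.random.default_rng(seed + 1)

    def _one(tag: str, i: int) -> tuple[SubjectStudy, PhantomTruth]:
        shift = (
            int(rng.integers(-fov_jitter_slices, fov_jitter_slices + 1))
            if fov_jitter_slices > 0
            else 0
        )
        dspec = replace(deformation, fov_shift_slices=shift)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        study, truth = derive_subject(
            base, spec, dspec, seed=sub_seed, subject_id=f"{tag}-{i}"
        )
        study.voi = _crude_voi(truth, voi_dilation)
        return study, truth

    atlases = [_one("atlas", i) for i in range(n_atlases)]
    targets = [_one("target", i) for i in range(n_targets)]
    return atlases, targets
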