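"""Pairwise atlas-to-target registration and deformation-field resampling.

Registration is two-step: an affine alignment of the preprocessed WF maps
(normalized-correlation metric), then a b-spline elastic refinement driven
by both the WF and R2* channels with equal weight.  The result is a dense
:class:`DeformationField` on the target grid mapping each target voxel's
physical position (mm) to a position in atlas physical space; label
propagation and map resampling sample the atlas volume there.

Two backends implement the optimization:

* :class:`SimpleITKBackend` — the production engine, built on SimpleITK's
  ITK registration framework (multiresolution pyramids; seeded stochastic
  gradient descent for the affine stage; dense-sampled L-BFGS-B with
  multi-start for the b-spline stage at the configured final control-grid
  spacing).
* :class:`SyntheticBackend` — returns externally supplied ground-truth
  fields; used in tests and phantom experiments so downstream stages are
  bit-reproducible and independent of optimizer stochasticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Protocol

import numpy as np
from scipy import ndimage

from .core_io import BinaryMask, GridGeometry, GridMismatchError, QuantMap

__all__ = [
    "AffineStageParams",
    "ElasticStageParams",
    "RegistrationParams",
    "DeformationField",
    "RegistrationError",
    "normalized_correlation",
    "two_channel_correlation",
    "identity_field",
    "translation_field",
    "compose_fields",
    "invert_field",
    "apply_field",
    "register_pair",
    "RegistrationBackend",
    "SyntheticBackend",
    "SimpleITKBackend",
    "get_backend",
]


class RegistrationError(RuntimeError):
    """Registration failure, carrying the stage (affine/elastic) that failed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class AffineStageParams:
    resolutions: int = 4
    max_iterations: int = 3000
    interpolation_order: int = 1
    sampling_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.resolutions < 1:
            raise ValueError("resolutions must be >= 1")


@dataclass(frozen=True)
class ElasticStageParams:
    resolutions: int = 4
    max_iterations: int = 7000
    interpolation_order: int = 1
    final_grid_spacing_mm: float = 20.0
    #: WF:R2* channel weights, normalized to sum to 1.
    channel_weights: tuple[float, float] = (0.5, 0.5)
    sampling_fraction: float = 0.25
    #: 'lbfgsb' (dense in-mask sampling, default) or 'gradient_descent'
    #: (random sampling with estimated step length).
    optimizer: str = "lbfgsb"
    #: Also try the b-spline refinement from the identity initialization
    #: and keep the better metric (guards against a misleading affine).
    multistart: bool = True

    def __post_init__(self) -> None:
        if self.resolutions < 1:
            raise ValueError("resolutions must be >= 1")
        if self.final_grid_spacing_mm <= 0:
            raise ValueError("final grid spacing must be > 0")
        w = np.asarray(self.channel_weights, dtype=float)
        if w.sum() <= 0:
            raise ValueError("channel weights must have positive sum")
        object.__setattr__(self, "channel_weights", tuple(w / w.sum()))


@dataclass(frozen=True)
class RegistrationParams:
    """Both registration stages plus the stochastic-optimizer seed."""

    affine: AffineStageParams = dc_field(default_factory=AffineStageParams)
    elastic: ElasticStageParams = dc_field(default_factory=ElasticStageParams)
    seed: int = 20170608


@dataclass
class DeformationField:
    """Dense displacement field on the target grid, in mm.

    ``displacement[i, j, k]`` is the mm vector added to the physical
    position of target voxel ``(i, j, k)`` to obtain the corresponding
    position in atlas physical space.  The identity field has zero
    displacement everywhere.
    """

    geometry: GridGeometry
    displacement: np.ndarray

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacement, dtype=np.float64)
        if disp.shape != self.geometry.shape + (3,):
            raise GridMismatchError(
                f"displacement shape {disp.shape} != {self.geometry.shape + (3,)}"
            )
        if not np.isfinite(disp).all():
            raise ValueError("displacement field contains non-finite values")
        self.displacement = disp

    def mapped_voxel_coords(self, source_geometry: GridGeometry) -> np.ndarray:
        """Fractional voxel coordinates in the source (atlas) grid.

        Returns an array of shape ``shape + (3,)``.
        """
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.geometry.shape], indexing="ij"),
            axis=-1,
        ).astype(np.float64)
        pos_mm = idx * np.asarray(self.geometry.spacing) + self.displacement
        return pos_mm / np.asarray(source_geometry.spacing)


def identity_field(geometry: GridGeometry) -> DeformationField:
    return DeformationField(geometry, np.zeros(geometry.shape + (3,)))


def translation_field(geometry: GridGeometry, shift_mm) -> DeformationField:
    """Field mapping every target position to position + shift (mm)."""
    disp = np.broadcast_to(
        np.asarray(shift_mm, dtype=np.float64), geometry.shape + (3,)
    ).copy()
    return DeformationField(geometry, disp)


def _sample_vector_field(
    disp: np.ndarray, coords: np.ndarray, order: int = 1
) -> np.ndarray:
    """Linearly sample a vector field at fractional voxel coords."""
    out = np.empty(coords.shape[:-1] + (3,), dtype=np.float64)
    pts = [coords[..., d] for d in range(3)]
    for c in range(3):
        out[..., c] = ndimage.map_coordinates(
            disp[..., c], pts, order=order, mode="nearest"
        )
    return out


def compose_fields(
    first: DeformationField, second: DeformationField, source_geometry: GridGeometry
) -> DeformationField:
    """Field applying ``first`` (target -> mid) then ``second`` (mid -> source).

    ``second`` lives on the mid-space grid (``source_geometry``); for a
    target position x the composed map is x + d1(x) + d2(x + d1(x)).
    """
    mid_coords = first.mapped_voxel_coords(second.geometry)
    d2 = _sample_vector_field(second.displacement, mid_coords)
    return DeformationField(first.geometry, first.displacement + d2)


def invert_field(field: DeformationField, iterations: int = 30) -> DeformationField:
    """Fixed-point inversion of a (small, smooth) displacement field.

    Solves d_inv(x) = -d(x + d_inv(x)) by iteration; accurate for fields
    without folding, as produced by the phantom generator.
    """
    spacing = np.asarray(field.geometry.spacing)
    idx = np.stack(
        np.meshgrid(*[np.arange(n) for n in field.geometry.shape], indexing="ij"),
        axis=-1,
    ).astype(np.float64)
    d_inv = np.zeros_like(field.displacement)
    for _ in range(iterations):
        coords = (idx * spacing + d_inv) / spacing
        d_inv = -_sample_vector_field(field.displacement, coords)
    return DeformationField(field.geometry, d_inv)


def normalized_correlation(
    a: QuantMap, b: QuantMap, support: Optional[BinaryMask] = None
) -> float:
    """Mean-subtracted normalized cross-correlation over a support mask.

    Returns a score in [-1, 1]; raises on a constant image where the
    metric is undefined.
    """
    if not a.geometry.compatible_with(b.geometry):
        raise GridMismatchError("normalized_correlation: incompatible geometries")
    if support is not None:
        if not support.geometry.compatible_with(a.geometry):
            raise GridMismatchError("support geometry incompatible")
        x = a.values[support.values]
        y = b.values[support.values]
    else:
        x = a.values.ravel()
        y = b.values.ravel()
    if x.size < 2:
        raise ValueError("support must contain at least 2 voxels")
    x = x - x.mean()
    y = y - y.mean()
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        raise ValueError("normalized correlation undefined for constant image")
    return float(np.dot(x, y) / (nx * ny))


def two_channel_correlation(
    a_wf: QuantMap,
    a_r2s: QuantMap,
    b_wf: QuantMap,
    b_r2s: QuantMap,
    support: Optional[BinaryMask] = None,
    weights: tuple[float, float] = (0.5, 0.5),
) -> float:
    """Weighted sum of per-channel normalized correlations (WF, R2*)."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return float(
        w[0] * normalized_correlation(a_wf, b_wf, support)
        + w[1] * normalized_correlation(a_r2s, b_r2s, support)
    )


def apply_field(
    field: DeformationField,
    source: QuantMap | BinaryMask,
    interpolation: str = "linear",
    source_fov: Optional[BinaryMask] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Resample an atlas-space volume onto the target grid through a field.

    Returns ``(values, represented)``: linearly interpolated values on the
    target grid, and a boolean array that is false wherever the mapped
    position leaves the atlas grid (or the atlas FOV, if given) — the
    out-of-FOV marker consumed by the voting stage.
    """
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unsupported interpolation {interpolation!r}")
    order = 1 if interpolation == "linear" else 0
    src_geom = source.geometry
    coords = field.mapped_voxel_coords(src_geom)
    pts = [coords[..., d] for d in range(3)]
    inside = np.ones(field.geometry.shape, dtype=bool)
    for d in range(3):
        inside &= (coords[..., d] >= 0.0) & (coords[..., d] <= src_geom.shape[d] - 1)
    src_values = source.values.astype(np.float64)
    values = ndimage.map_coordinates(
        src_values, pts, order=order, mode="constant", cval=0.0
    )
    values[~inside] = 0.0
    represented = inside
    if source_fov is not None:
        fov_cov = ndimage.map_coordinates(
            source_fov.values.astype(np.float64), pts, order=1, mode="constant", cval=0.0
        )
        represented = inside & (fov_cov >= 0.5)
    return values, represented


# ---------------------------------------------------------------------------
# Backends


class RegistrationBackend(Protocol):
    """Maps a preprocessed (wf, r2s) atlas/target pair to a deformation field."""

    def register(
        self,
        atlas_wf: QuantMap,
        atlas_r2s: QuantMap,
        target_wf: QuantMap,
        target_r2s: QuantMap,
        params: RegistrationParams,
    ) -> DeformationField: ...


class SyntheticBackend:
    """Backend returning supplied ground-truth deformation fields.

    ``fields`` maps an arbitrary key to a precomputed field; the key for
    the next ``register`` call is set via :meth:`select` (the pipeline sets
    it to the atlas subject id).  With no fields configured, the identity
    field is returned — convenient for self-registration tests.
    """

    name = "synthetic"

    def __init__(self, fields: Optional[dict[str, DeformationField]] = None):
        self.fields = fields or {}
        self._key: Optional[str] = None

    def select(self, key: str) -> "SyntheticBackend":
        self._key = key
        return self

    def register(self, atlas_wf, atlas_r2s, target_wf, target_r2s, params):
        if self._key is not None and self._key in self.fields:
            return self.fields[self._key]
        return identity_field(target_wf.geometry)


def _to_sitk(qmap: QuantMap):
    import SimpleITK as sitk

    # SimpleITK's GetImageFromArray expects (z, y, x) ordering.
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(qmap.values.transpose(2, 1, 0).astype(np.float64))
    )
    img.SetSpacing(tuple(float(s) for s in qmap.geometry.spacing))
    return img


def _zscore_on_support(values: np.ndarray, support: np.ndarray) -> np.ndarray:
    inside = values[support]
    if inside.size < 2 or inside.std() == 0:
        return np.zeros_like(values)
    return np.where(support, (values - inside.mean()) / inside.std(), 0.0)


class SimpleITKBackend:
    """Affine + b-spline registration through SimpleITK's ITK engine.

    The affine stage matches the atlas WF map (moving) to the target WF map
    (fixed) under the correlation metric, using gradient descent with
    estimated step length and seeded random sampling.  The elastic stage
    refines the result with a multiresolution b-spline transform at the
    configured final control-grid spacing, driven by an equal-weight sum
    of the per-channel z-scored WF and R2* maps fused into a single scalar
    image (the engine evaluates one image pair per metric); it is
    optimized by L-BFGS-B over a dense in-mask sample, started from both
    the affine result and the identity, keeping the better metric.

    Runs single-threaded so results are bit-reproducible across machines.
    """

    name = "sitk"

    def __init__(self, verbose: bool = False):
        self.verbose = verbose
        #: Final metric value per stage of the last run (diagnostics).
        self.last_metrics: dict[str, float] = {}

    # -- helpers ------------------------------------------------------------

    def _shrink_and_sigma(self, levels: int, shape) -> tuple[list[int], list[float]]:
        shrink = [2 ** (levels - 1 - i) for i in range(levels)]
        min_dim = min(shape)
        shrink = [min(s, max(1, min_dim // 4)) if s > 1 else 1 for s in shrink]
        sigmas = [max(0.0, (s - 1) * 0.5) for s in shrink]
        return shrink, sigmas

    def _elastic_schedule(self, levels: int) -> tuple[list[int], list[float]]:
        # Gentle pyramid for the quasi-Newton refinement: deep shrinking
        # adds nothing once the affine stage has handled gross alignment,
        # and it degrades the thin slice axis.
        shrink = [2] * (levels - 1) + [1] if levels > 1 else [1]
        sigmas = [1.0] * max(0, levels - 2) + ([0.5] if levels > 1 else []) + [0.0]
        return shrink, sigmas

    def _run_stage(
        self,
        stage: str,
        fixed,
        moving,
        reg,
    ):
        import SimpleITK as sitk

        try:
            return reg.Execute(fixed, moving)
        except RuntimeError as exc:
            raise RegistrationError(stage, str(exc)) from exc

    # -- main entry ---------------------------------------------------------

    def register(
        self,
        atlas_wf: QuantMap,
        atlas_r2s: QuantMap,
        target_wf: QuantMap,
        target_r2s: QuantMap,
        params: RegistrationParams,
    ) -> DeformationField:
        import SimpleITK as sitk

        geom = target_wf.geometry
        fixed_wf = _to_sitk(target_wf)
        moving_wf = _to_sitk(atlas_wf)

        # ---- affine stage on the WF channel
        ap = params.affine
        reg = sitk.ImageRegistrationMethod()
        reg.SetNumberOfWorkUnits(1)
        reg.SetMetricAsCorrelation()
        reg.SetMetricSamplingStrategy(reg.RANDOM)
        reg.SetMetricSamplingPercentage(ap.sampling_fraction, int(params.seed) % (2**31))
        reg.SetInterpolator(sitk.sitkLinear)
        reg.SetOptimizerAsGradientDescent(
            learningRate=1.0,
            numberOfIterations=ap.max_iterations,
            convergenceMinimumValue=1e-7,
            convergenceWindowSize=20,
            estimateLearningRate=reg.EachIteration,
        )
        reg.SetOptimizerScalesFromPhysicalShift()
        shrink, sigmas = self._shrink_and_sigma(ap.resolutions, geom.shape)
        reg.SetShrinkFactorsPerLevel(shrink)
        reg.SetSmoothingSigmasPerLevel(sigmas)
        reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
        initial = sitk.CenteredTransformInitializer(
            fixed_wf,
            moving_wf,
            sitk.AffineTransform(3),
            sitk.CenteredTransformInitializerFilter.GEOMETRY,
        )
        reg.SetInitialTransform(initial, inPlace=False)
        affine_tx = self._run_stage("affine", fixed_wf, moving_wf, reg)
        self.last_metrics["affine"] = float(reg.GetMetricValue())
        if not np.isfinite(self.last_metrics["affine"]):
            raise RegistrationError("affine", "non-finite metric value")
        if self.verbose:
            print(f"[affine] metric={self.last_metrics['affine']:.5f}")

        # ---- elastic stage on the fused two-channel image
        ep = params.elastic
        w = np.asarray(ep.channel_weights)
        support_t = (target_wf.values > 0) | (target_r2s.values > 0)
        support_a = (atlas_wf.values > 0) | (atlas_r2s.values > 0)
        fused_target = w[0] * _zscore_on_support(
            target_wf.values, support_t
        ) + w[1] * _zscore_on_support(target_r2s.values, support_t)
        fused_atlas = w[0] * _zscore_on_support(
            atlas_wf.values, support_a
        ) + w[1] * _zscore_on_support(atlas_r2s.values, support_a)
        fixed = _to_sitk(QuantMap(geom, fused_target, "sum-signal"))
        moving = _to_sitk(QuantMap(atlas_wf.geometry, fused_atlas, "sum-signal"))

        phys_size = [
            (n - 1) * s for n, s in zip(atlas_wf.geometry.shape, geom.spacing)
        ]
        levels = ep.resolutions
        # Control-point mesh with the configured final grid spacing; coarse
        # levels double the spacing where the mesh allows it.
        final_mesh = [
            max(1, int(round(sz / ep.final_grid_spacing_mm))) for sz in phys_size
        ]
        halvings = max(0, min(int(np.log2(max(m, 1))) for m in final_mesh))
        halvings = min(halvings, levels - 1)
        coarse_mesh = [max(1, m >> halvings) for m in final_mesh]
        scale_factors = [1] * (levels - halvings) + [
            2**i for i in range(1, halvings + 1)
        ]

        # Metric domain: the target support with its enclosed holes filled
        # (adipose regions appear as dark holes in the support and their
        # shape is informative), slightly dilated to keep boundary voxels.
        from scipy import ndimage as _ndi

        fixed_mask_arr = _ndi.binary_dilation(support_t, iterations=3)
        for k in range(fixed_mask_arr.shape[2]):
            fixed_mask_arr[:, :, k] = _ndi.binary_fill_holes(fixed_mask_arr[:, :, k])
        fixed_mask = sitk.GetImageFromArray(
            np.ascontiguousarray(fixed_mask_arr.transpose(2, 1, 0).astype(np.uint8))
        )
        fixed_mask.CopyInformation(fixed)

        def _run_elastic(moving_initial):
            bspline = sitk.BSplineTransformInitializer(fixed, coarse_mesh, order=3)
            reg = sitk.ImageRegistrationMethod()
            reg.SetNumberOfWorkUnits(1)
            reg.SetMetricAsCorrelation()
            reg.SetInterpolator(sitk.sitkLinear)
            if ep.optimizer == "lbfgsb":
                # Dense in-mask sampling with a quasi-Newton optimizer: on
                # the smooth low-dimensional b-spline problem this reaches
                # the correlation optimum far more reliably than ITK's
                # generic gradient descent.
                reg.SetMetricSamplingStrategy(reg.NONE)
                reg.SetOptimizerAsLBFGSB(
                    gradientConvergenceTolerance=1e-9,
                    numberOfIterations=min(ep.max_iterations, 500),
                    maximumNumberOfCorrections=10,
                    maximumNumberOfFunctionEvaluations=5000,
                    costFunctionConvergenceFactor=1e5,
                )
            elif ep.optimizer == "gradient_descent":
                reg.SetMetricSamplingStrategy(reg.RANDOM)
                reg.SetMetricSamplingPercentage(
                    ep.sampling_fraction, (int(params.seed) + 1) % (2**31)
                )
                reg.SetOptimizerAsGradientDescent(
                    learningRate=1.0,
                    numberOfIterations=ep.max_iterations,
                    convergenceMinimumValue=1e-7,
                    convergenceWindowSize=20,
                    estimateLearningRate=reg.EachIteration,
                )
                reg.SetOptimizerScalesFromPhysicalShift()
            else:
                raise RegistrationError(
                    "elastic", f"unknown optimizer {ep.optimizer!r}"
                )
            shrink, sigmas = self._elastic_schedule(levels)
            reg.SetShrinkFactorsPerLevel(shrink)
            reg.SetSmoothingSigmasPerLevel(sigmas)
            reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
            reg.SetMetricFixedMask(fixed_mask)
            if moving_initial is not None:
                reg.SetMovingInitialTransform(moving_initial)
            reg.SetInitialTransformAsBSpline(
                bspline, inPlace=True, scaleFactors=scale_factors
            )
            tx = self._run_stage("elastic", fixed, moving, reg)
            metric = float(reg.GetMetricValue())
            if not np.isfinite(metric):
                raise RegistrationError("elastic", "non-finite metric value")
            parts = [moving_initial, tx] if moving_initial is not None else [tx]
            return sitk.CompositeTransform(parts), metric

        # Multi-start: the affine stage is the right initialization for
        # genuine inter-subject pose/size differences but can trap the
        # b-spline refinement in a poorer basin when the pair differs by a
        # pure elastic deformation; the better metric decides.
        composite, metric = _run_elastic(affine_tx)
        start = "affine"
        if ep.multistart:
            composite_id, metric_id = _run_elastic(None)
            if metric_id < metric:
                composite, metric, start = composite_id, metric_id, "identity"
        self.last_metrics["elastic"] = metric
        self.last_metrics["elastic_start"] = start
        if self.verbose:
            print(f"[elastic] metric={metric:.5f} start={start}")

        # ---- densify: displacement at each target voxel, in mm
        to_disp = sitk.TransformToDisplacementFieldFilter()
        to_disp.SetReferenceImage(fixed_wf)
        disp_img = to_disp.Execute(composite)
        disp = sitk.GetArrayFromImage(disp_img)  # (z, y, x, 3) with (x,y,z) vectors
        disp = disp.transpose(2, 1, 0, 3)
        return DeformationField(geom, disp)


def write_parameter_files(
    params: RegistrationParams, directory
) -> list:
    """Emit Elastix-style parameter text files describing both stages.

    Written next to registration outputs so a run's configuration can be
    reproduced with external ITK/Elastix tooling.  Returns the two paths.
    """
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = directory / "parameters_affine.txt"
    affine.write_text(
        "// Stage 1: affine alignment of the preprocessed WF maps\n"
        '(Transform "AffineTransform")\n'
        '(Metric "AdvancedNormalizedCorrelation")\n'
        '(Optimizer "AdaptiveStochasticGradientDescent")\n'
        f"(NumberOfResolutions {params.affine.resolutions})\n"
        f"(MaximumNumberOfIterations {params.affine.max_iterations})\n"
        f"(BSplineInterpolationOrder {params.affine.interpolation_order})\n"
        f"(RandomSeed {params.seed})\n"
    )
    elastic = directory / "parameters_elastic.txt"
    w = params.elastic.channel_weights
    elastic.write_text(
        "// Stage 2: b-spline refinement on the WF and R2* channels\n"
        '(Transform "BSplineTransform")\n'
        '(Metric "AdvancedNormalizedCorrelation" "AdvancedNormalizedCorrelation")\n'
        f"(MetricWeights {w[0]:g} {w[1]:g})\n"
        '(Optimizer "AdaptiveStochasticGradientDescent")\n'
        f"(NumberOfResolutions {params.elastic.resolutions})\n"
        f"(MaximumNumberOfIterations {params.elastic.max_iterations})\n"
        f"(BSplineInterpolationOrder {params.elastic.interpolation_order})\n"
        f"(FinalGridSpacingInPhysicalUnits {params.elastic.final_grid_spacing_mm:g})\n"
        f"(RandomSeed {params.seed + 1})\n"
    )
    return [affine, elastic]


def get_backend(name: str, **kwargs) -> RegistrationBackend:
    """Look up a registration backend by name ('sitk' or 'synthetic')."""
    if name in ("sitk", "itk", "elastix"):
        return SimpleITKBackend(**kwargs)
    if name == "synthetic":
        return SyntheticBackend(**kwargs)
    raise ValueError(f"unknown registration backend {name!r}")


def register_pair(
    atlas_wf: QuantMap,
    atlas_r2s: QuantMap,
    target_wf: QuantMap,
    target_r2s: QuantMap,
    params: RegistrationParams | None = None,
    backend: RegistrationBackend | None = None,
) -> DeformationField:
    """Register one atlas to one target; see module docstring.

    The affine stage uses the WF channel only; the elastic stage uses both
    channels with the configured weights and starts from the affine result.
    """
    params = params or RegistrationParams()
    backend = backend or SimpleITKBackend()
    for m in (atlas_r2s, target_wf, target_r2s):
        if not atlas_wf.geometry.spacing == m.geometry.spacing:
            raise GridMismatchError("registration inputs must share voxel spacing")
    return backend.register(atlas_wf, atlas_r2s, target_wf, target_r2s, params)
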