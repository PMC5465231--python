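import numpy as np
import pytest

from batlas import (
    BackgroundParams,
    BinaryMask,
    GridGeometry,
    QuantMap,
    SkinStripParams,
    compute_water_fraction,
    preprocess_r2s,
    preprocess_wf,
    remove_background,
    strip_skin,
)
from batlas.phantom import LABELS
from batlas.preprocess import preprocess_support, strip_skin_stages

from .oracles import strip_skin_oracle


def _maps(geometry, ff, r2s):
    return (
        QuantMap(geometry, ff, "FF"),
        QuantMap(geometry, r2s, "R2*"),
    )


class TestWaterFraction:
    def test_complement_and_involution(self):
        geom = GridGeometry((3, 3, 1))
        ff = QuantMap(geom, np.full(geom.shape, 0.84), "FF")
        wf = compute_water_fraction(ff)
        assert wf.quantity == "WF"
        assert wf.values[0, 0, 0] == pytest.approx(0.16)
        # applying the complement twice recovers FF
        back = compute_water_fraction(QuantMap(geom, wf.values, "FF"))
        np.testing.assert_allclose(back.values, ff.values)

    def test_wrong_quantity_rejected(self):
        geom = GridGeometry((2, 2, 1))
        with pytest.raises(ValueError, match="FF"):
            compute_water_fraction(QuantMap(geom, np.zeros(geom.shape), "R2*"))


class TestRemoveBackground:
    def test_zero_signal_warns_and_is_empty(self):
        geom = GridGeometry((4, 4, 2))
        zero = QuantMap(geom, np.zeros(geom.shape), "water")
        with pytest.warns(UserWarning, match="empty body mask"):
            body = remove_background(zero, zero.with_values(zero.values, "fat"))
        assert body.count == 0

    def test_threshold_is_strictly_greater_than(self):
        geom = GridGeometry((3, 1, 1))
        water = QuantMap(geom, np.array([[[5.0]], [[10.0]], [[15.0]]]) / 2, "water")
        fat = QuantMap(geom, np.array([[[5.0]], [[10.0]], [[15.0]]]) / 2, "fat")
        body = remove_background(water, fat, BackgroundParams(10.0))
        np.testing.assert_array_equal(body.values.ravel(), [False, False, True])

    def test_noise_free_phantom_body_support_exact(self):
        from batlas import PhantomSpec, make_phantom

        spec = PhantomSpec(noise_sd=0.0, r2s_noise_sd=0.0)
        study, truth = make_phantom(spec, seed=0)
        body = remove_background(study.water, study.fat)
        # the body mask is exactly the full-amplitude compartments
        expected = np.isin(
            truth.labels,
            [LABELS["lean"], LABELS["sat"], LABELS["sbat"], LABELS["skin"]],
        )
        np.testing.assert_array_equal(body.values, expected)


def _toy_rim(rim_thickness=1, n=20, rim_ff=0.10, rim_r2s=100.0,
             core_ff=0.10, core_r2s=30.0):
    """Single-slice square body with a skin-like rim around a core."""
    geom = GridGeometry((n, n, 1))
    body = np.zeros(geom.shape, dtype=bool)
    body[3 : n - 3, 3 : n - 3, 0] = True
    core = np.zeros_like(body)
    t = rim_thickness
    core[3 + t : n - 3 - t, 3 + t : n - 3 - t, 0] = True
    ff = np.where(core, core_ff, rim_ff)
    r2s = np.where(core, core_r2s, rim_r2s)
    return geom, BinaryMask(geom, body), core, *_maps(geom, ff, r2s)


class TestStripSkin:
    def test_single_layer_rim_removed_in_one_iteration(self):
        geom, body, core, ff, r2s = _toy_rim(rim_thickness=1)
        stages = strip_skin_stages(body, ff, r2s, SkinStripParams(max_iterations=1))
        np.testing.assert_array_equal(stages["constrained"].values, core)

    def test_thick_rim_peeled_one_layer_per_iteration(self):
        geom, body, core, ff, r2s = _toy_rim(rim_thickness=3)
        for n_iter in (1, 2, 3):
            stages = strip_skin_stages(
                body, ff, r2s, SkinStripParams(max_iterations=n_iter)
            )
            remaining = stages["constrained"].values
            expected = np.zeros_like(body.values)
            expected[3 + n_iter : 17 - n_iter, 3 + n_iter : 17 - n_iter, 0] = True
            np.testing.assert_array_equal(remaining, expected)
        # a fourth iteration removes nothing more: core fails the constraints
        full = strip_skin_stages(body, ff, r2s, SkinStripParams(max_iterations=50))
        np.testing.assert_array_equal(full["constrained"].values, core)

    def test_adipose_boundary_untouched_by_constraints(self):
        # AT fails both constraints (high FF, low R2*): nothing is removed
        geom, body, _, _, _ = _toy_rim()
        ff = QuantMap(geom, np.full(geom.shape, 0.90), "FF")
        r2s = QuantMap(geom, np.full(geom.shape, 20.0), "R2*")
        stages = strip_skin_stages(body, ff, r2s)
        np.testing.assert_array_equal(stages["constrained"].values, body.values)

    def test_output_subset_of_body_and_empty_body_warns(self):
        geom, body, _, ff, r2s = _toy_rim()
        out = strip_skin(body, ff, r2s)
        assert not (out.values & ~body.values).any()
        empty = BinaryMask(geom, np.zeros(geom.shape, dtype=bool))
        with pytest.warns(UserWarning, match="empty body"):
            assert strip_skin(empty, ff, r2s).count == 0

    def test_constrained_stage_idempotent_on_own_output(self):
        geom, body, _, ff, r2s = _toy_rim(rim_thickness=2)
        first = strip_skin_stages(body, ff, r2s)["constrained"]
        second = strip_skin_stages(first, ff, r2s)["constrained"]
        np.testing.assert_array_equal(second.values, first.values)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_oracle_on_random_grids(self, trial):
        rng = np.random.default_rng(100 + trial)
        shape = (
            int(rng.integers(8, 20)),
            int(rng.integers(8, 20)),
            int(rng.integers(1, 4)),
        )
        geom = GridGeometry(shape)
        body = BinaryMask(geom, rng.random(shape) > 0.3)
        ff = QuantMap(geom, rng.uniform(0, 1, shape), "FF")
        r2s = QuantMap(geom, rng.uniform(0, 160, shape), "R2*")
        params = SkinStripParams(closing_se=3, final_erosion_se=3, max_iterations=10)
        ours = strip_skin(body, ff, r2s, params)
        expected = strip_skin_oracle(
            body.values, ff.values, r2s.values,
            params.ff_max, params.r2s_min,
            params.closing_se, params.final_erosion_se, params.max_iterations,
        )
        np.testing.assert_array_equal(ours.values, expected)


class TestPreprocessMaps:
    def test_phantom_skin_zeroed_and_interior_lean_kept(self, base_phantom):
        study, truth = base_phantom
        support = preprocess_support(study)
        wf = preprocess_wf(study, support=support)
        skin = truth.compartment_mask("skin")
        assert np.all(wf.values[skin] == 0.0)
        # interior lean voxels (beyond the final erosion reach) keep WF
        from scipy import ndimage

        lean = truth.compartment_mask("lean")
        se = np.ones((15, 15), dtype=bool)  # 2 x final_erosion_se + 1
        interior = np.zeros_like(lean)
        tissue = np.isin(
            truth.labels,
            [LABELS["lean"], LABELS["sat"], LABELS["sbat"], LABELS["skin"]],
        )
        for k in range(lean.shape[2]):
            interior[:, :, k] = ndimage.binary_erosion(tissue[:, :, k], structure=se)
        deep_lean = lean & interior
        kept = (wf.values > 0)[deep_lean]
        assert kept.mean() >= 0.99

    def test_all_air_input_gives_zero_map(self):
        geom = GridGeometry((8, 8, 2))
        from batlas import SubjectStudy

        z = np.zeros(geom.shape)
        study = SubjectStudy(
            "air",
            water=QuantMap(geom, z, "water"),
            fat=QuantMap(geom, z, "fat"),
            ff=QuantMap(geom, z, "FF"),
            r2s=QuantMap(geom, z, "R2*"),
        )
        with pytest.warns(UserWarning):
            wf = preprocess_wf(study)
        assert np.all(wf.values == 0.0)

    def test_r2s_median_filter_replaces_impulse(self):
        geom = GridGeometry((9, 9, 3))
        from batlas import SubjectStudy

        ones = np.ones(geom.shape)
        r2s_vals = np.full(geom.shape, 25.0)
        r2s_vals[4, 4, 1] = 500.0
        study = SubjectStudy(
            "s",
            water=QuantMap(geom, ones, "water"),
            fat=QuantMap(geom, ones * 0.1, "fat"),
            ff=QuantMap(geom, np.full(geom.shape, 0.09), "FF"),
            r2s=QuantMap(geom, r2s_vals, "R2*"),
        )
        support = BinaryMask(geom, np.ones(geom.shape, dtype=bool))
        out = preprocess_r2s(study, support=support)
        assert out.values[4, 4, 1] == pytest.approx(25.0)

    def test_masked_out_voxels_are_zero(self, base_phantom):
        study, _ = base_phantom
        support = preprocess_support(study)
        r2s = preprocess_r2s(study, support=support)
        assert np.all(r2s.values[~support.values] == 0.0)
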