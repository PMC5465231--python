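import numpy as np
import pytest

from batlas import (
    BinaryMask,
    FineAdjustParams,
    GridGeometry,
    QuantMap,
    RefineParams,
    SyntheticBackend,
    fine_adjust,
    make_atlas,
    refine,
    run_mas,
    run_ref,
)
from batlas.phantom import make_cohort, true_pair_field
from batlas.preprocess import BackgroundParams

from .conftest import small_spec
from .oracles import fine_adjust_oracle, refine_oracle


def _toy_voi():
    """Single-slice 7x7 VOI: 5x5 adipose block with a low-FF rim."""
    geom = GridGeometry((7, 7, 1))
    voi = np.ones(geom.shape, dtype=bool)
    ff = np.full(geom.shape, 0.3)
    ff[1:6, 1:6, 0] = 0.9
    r2s = np.full(geom.shape, 20.0)
    return geom, BinaryMask(geom, voi), QuantMap(geom, ff, "FF"), QuantMap(geom, r2s, "R2*")


class TestFineAdjust:
    def test_toy_grid_nine_voxels_survive(self):
        geom, voi, ff, r2s = _toy_voi()
        out = fine_adjust(voi, ff, r2s)
        # FF threshold keeps the 5x5 block; erosion leaves its 3x3 interior
        expected = np.zeros(geom.shape, dtype=bool)
        expected[2:5, 2:5, 0] = True
        np.testing.assert_array_equal(out.values, expected)
        assert out.count == 9

    def test_ff_threshold_is_inclusive(self):
        geom = GridGeometry((5, 5, 1))
        voi = BinaryMask(geom, np.ones(geom.shape, dtype=bool))
        ff = QuantMap(geom, np.full(geom.shape, 0.40), "FF")
        r2s = QuantMap(geom, np.zeros(geom.shape), "R2*")
        out = fine_adjust(voi, ff, r2s)
        assert out.values[2, 2, 0]  # interior survives erosion

    def test_high_r2s_excludes_everything(self):
        geom, voi, ff, _ = _toy_voi()
        r2s = QuantMap(geom, np.full(geom.shape, 60.0), "R2*")
        assert fine_adjust(voi, ff, r2s).count == 0

    def test_empty_voi_warns(self):
        geom, _, ff, r2s = _toy_voi()
        empty = BinaryMask(geom, np.zeros(geom.shape, dtype=bool))
        with pytest.warns(UserWarning, match="empty VOI"):
            assert fine_adjust(empty, ff, r2s).count == 0

    @pytest.mark.parametrize("trial", range(15))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(400 + trial)
        shape = (int(rng.integers(5, 16)), int(rng.integers(5, 16)), int(rng.integers(1, 4)))
        geom = GridGeometry(shape)
        voi = BinaryMask(geom, rng.random(shape) > 0.3)
        ff = QuantMap(geom, rng.uniform(0, 1, shape), "FF")
        r2s = QuantMap(geom, rng.uniform(0, 100, shape), "R2*")
        ours = fine_adjust(voi, ff, r2s)
        expected = fine_adjust_oracle(voi.values, ff.values, r2s.values, 0.40, 50.0)
        np.testing.assert_array_equal(ours.values, expected)

    def test_output_subset_of_input(self):
        rng = np.random.default_rng(9)
        geom = GridGeometry((12, 12, 3))
        voi = BinaryMask(geom, rng.random(geom.shape) > 0.4)
        ff = QuantMap(geom, rng.uniform(0, 1, geom.shape), "FF")
        r2s = QuantMap(geom, rng.uniform(0, 100, geom.shape), "R2*")
        out = fine_adjust(voi, ff, r2s)
        assert not (out.values & ~voi.values).any()


class TestRefine:
    def _signals(self, geom, total):
        half = total / 2.0
        return (
            QuantMap(geom, half, "water"),
            QuantMap(geom, half, "fat"),
        )

    def test_air_pocket_removed(self):
        geom = GridGeometry((9, 9, 1))
        mask = np.zeros(geom.shape, dtype=bool)
        mask[1:8, 1:8, 0] = True
        total = np.where(mask, 1.0, 0.0)
        total[4, 4, 0] = 0.0
        total[4, 5, 0] = 0.0  # 2-voxel air pocket, zero signal
        water, fat = self._signals(geom, total)
        out = refine(BinaryMask(geom, mask), water, fat, RefineParams(BackgroundParams(0.1)))
        assert not out.values[4, 4, 0] and not out.values[4, 5, 0]

    def test_no_low_signal_voxels_is_identity(self):
        geom = GridGeometry((9, 9, 2))
        rng = np.random.default_rng(5)
        mask = np.zeros(geom.shape, dtype=bool)
        mask[2:7, 2:7, :] = True
        water, fat = self._signals(geom, np.ones(geom.shape))
        out = refine(BinaryMask(geom, mask), water, fat, RefineParams(BackgroundParams(0.1)))
        np.testing.assert_array_equal(out.values, mask)

    def test_empty_mask_stays_empty(self):
        geom = GridGeometry((5, 5, 1))
        water, fat = self._signals(geom, np.ones(geom.shape))
        empty = BinaryMask(geom, np.zeros(geom.shape, dtype=bool))
        assert refine(empty, water, fat).count == 0

    @pytest.mark.parametrize("trial", range(15))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(500 + trial)
        shape = (int(rng.integers(5, 16)), int(rng.integers(5, 16)), int(rng.integers(1, 4)))
        geom = GridGeometry(shape)
        mask = BinaryMask(geom, rng.random(shape) > 0.4)
        total = rng.uniform(0, 1, shape)
        water, fat = self._signals(geom, total)
        params = RefineParams(BackgroundParams(0.3))
        ours = refine(mask, water, fat, params)
        expected = refine_oracle(mask.values, water.values, fat.values, 0.3, 3, 3)
        np.testing.assert_array_equal(ours.values, expected)


class TestPipelines:
    @pytest.fixture(scope="class")
    def small_cohort(self):
        return make_cohort(n_atlases=3, n_targets=1, spec=small_spec(), seed=11)

    def test_identity_pipeline_equals_reference(self, small_cohort):
        """Atlases identical to the target + identity fields: the MAS crude
        VOI is the target's own VOI, so MAS and REF coincide bit-exactly."""
        _, targets = small_cohort
        t_study, _ = targets[0]
        atlas = make_atlas(t_study)
        mas = run_mas(t_study, [atlas] * 3, backend=SyntheticBackend())
        ref = run_ref(t_study)
        np.testing.assert_array_equal(mas.mask.values, ref.mask.values)

    def test_synthetic_true_fields_recover_reference_truth(self, small_cohort):
        atlases, targets = small_cohort
        t_study, t_truth = targets[0]
        atlas_objs = [make_atlas(s) for s, _ in atlases]
        fields = {s.subject_id: true_pair_field(tr, t_truth) for s, tr in atlases}
        res = run_mas(t_study, atlas_objs, backend=SyntheticBackend(fields))
        from batlas.evaluate import dice, overlap_counts

        d = dice(overlap_counts(res.mask, t_truth.sbat_ref, res.fusion_fov))
        assert d >= 0.95

    def test_run_mas_bit_reproducible_under_synthetic_backend(self, small_cohort):
        atlases, targets = small_cohort
        t_study, t_truth = targets[0]
        atlas_objs = [make_atlas(s) for s, _ in atlases]
        fields = {s.subject_id: true_pair_field(tr, t_truth) for s, tr in atlases}
        a = run_mas(t_study, atlas_objs, backend=SyntheticBackend(fields))
        b = run_mas(t_study, atlas_objs, backend=SyntheticBackend(fields))
        np.testing.assert_array_equal(a.mask.values, b.mask.values)
        np.testing.assert_array_equal(a.fusion_fov.values, b.fusion_fov.values)

    def test_run_ref_requires_voi_and_is_deterministic(self, small_cohort):
        _, targets = small_cohort
        t_study, _ = targets[0]
        a = run_ref(t_study)
        b = run_ref(t_study)
        np.testing.assert_array_equal(a.mask.values, b.mask.values)
        t_no_voi = type(t_study)(
            "bare", t_study.water, t_study.fat, t_study.ff, t_study.r2s
        )
        with pytest.raises(ValueError, match="VOI"):
            run_ref(t_no_voi)

    def test_provenance_counts_recorded(self, small_cohort):
        atlases, targets = small_cohort
        t_study, _ = targets[0]
        atlas_objs = [make_atlas(s) for s, _ in atlases]
        res = run_mas(t_study, atlas_objs, backend=SyntheticBackend())
        stages = res.provenance["stages"]
        for key in ("support_voxels", "fused_voxels", "fine_adjusted_voxels", "refined_voxels"):
            assert key in stages
        assert stages["refined_voxels"] <= stages["fine_adjusted_voxels"]
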