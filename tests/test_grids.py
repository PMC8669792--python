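"""Voxel grid, NIfTI IO, hemisphere folding, smoothing, streamline masking."""

import numpy as np
import pytest

import lesioncov as lc
from lesioncov import synth as sy
from lesioncov.grids import fold_average, fwhm_to_sigma

from conftest import line_map


@pytest.fixture(scope="module")
def grid():
    return sy.make_grid()


def lesion_from_indices(grid, idx):
    vol = np.zeros(grid.shape, np.uint8)
    for i in idx:
        vol[i] = 1
    vol &= grid.mask("brain").astype(np.uint8)
    return lc.LesionMask("s", grid, vol[grid.mask("brain")], "bilateral")


class TestNiftiIO:
    def test_mask_roundtrip_preserves_count(self, grid, tmp_path):
        vol = np.zeros(grid.shape)
        brain = np.argwhere(grid.mask("brain"))
        for i in brain[:10]:
            vol[tuple(i)] = 1.0
        import nibabel as nib

        nib.save(nib.Nifti1Image(vol, grid.default_affine()), tmp_path / "m.nii.gz")
        mask = lc.read_mask(tmp_path / "m.nii.gz", grid)
        assert mask.values.sum() == 10

    def test_nonbinary_values_rounded(self, grid, tmp_path, caplog):
        vol = np.zeros(grid.shape)
        brain = np.argwhere(grid.mask("brain"))
        for i in brain[:5]:
            vol[tuple(i)] = 0.999
        import nibabel as nib

        nib.save(nib.Nifti1Image(vol, grid.default_affine()), tmp_path / "m.nii.gz")
        with caplog.at_level("WARNING", logger="lesioncov.grids"):
            mask = lc.read_mask(tmp_path / "m.nii.gz", grid)
        assert mask.values.sum() == 5
        assert any("rounded" in r.message for r in caplog.records)

    def test_empty_mask_rejected(self, grid, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros(grid.shape), grid.default_affine()),
                 tmp_path / "z.nii.gz")
        with pytest.raises(lc.ValidationError):
            lc.read_mask(tmp_path / "z.nii.gz", grid)

    def test_shape_mismatch_rejected(self, grid, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.ones((8, 8, 8)), np.eye(4)), tmp_path / "b.nii.gz")
        with pytest.raises(lc.GridError):
            lc.read_mask(tmp_path / "b.nii.gz", grid)

    def test_map_roundtrip_to_1e6(self, grid, tmp_path):
        rng = np.random.default_rng(0)
        m = lc.BrainMap(grid, "brain", rng.standard_normal(grid.n_voxels("brain")))
        lc.write_map(m, tmp_path / "v.nii.gz")
        back = lc.read_map(tmp_path / "v.nii.gz", grid, "brain")
        assert np.allclose(back.values, m.values, atol=1e-6)


class TestFolding:
    def test_left_lesion_unchanged(self, grid):
        brain_left = np.argwhere(grid.mask("brain") & grid.left_hemisphere())
        m = lesion_from_indices(grid, [tuple(i) for i in brain_left[:20]])
        out = lc.fold_to_left(m)
        assert np.array_equal(out.values, m.values)
        assert out.hemisphere == "left"

    def test_mirror_image_folds_to_original(self, grid):
        brain_left = np.argwhere(grid.mask("brain") & grid.left_hemisphere())
        left = lesion_from_indices(grid, [tuple(i) for i in brain_left[:20]])
        vol = left.to_volume()
        right = lc.LesionMask("s", grid, grid.mirror(vol)[grid.mask("brain")], "right")
        assert np.array_equal(lc.fold_to_left(right).values,
                              lc.fold_to_left(left).values)

    def test_idempotent(self, grid):
        local = sy.make_truth(seed=1)
        masks = sy.sample_lesions(local, n=12, seed=9)
        for m in masks:
            once = lc.fold_to_left(m)
            twice = lc.fold_to_left(once)
            assert np.array_equal(once.values, twice.values)

    def test_bilateral_minority_united(self, grid):
        """A butterfly lesion keeps its majority side and gains the mirrored
        minority voxels (voxelwise max keeps values binary)."""
        left_vox = np.argwhere(grid.mask("brain") & grid.left_hemisphere())
        pick = [tuple(i) for i in left_vox[:6]]
        mirrored = [tuple(np.array([grid.shape[0] - 1 - i, j, k])) for i, j, k in pick[:2]]
        m = lesion_from_indices(grid, pick + mirrored)
        out = lc.fold_to_left(m)
        assert out.hemisphere == "left"
        assert set(np.flatnonzero(out.values)) == set(
            np.flatnonzero(lesion_from_indices(grid, pick).values))

    def test_symmetric_map_average_equals_left_half(self, grid):
        rng = np.random.default_rng(1)
        vol = rng.standard_normal(grid.shape)
        vol = 0.5 * (vol + grid.mirror(vol))  # symmetric input
        m = lc.BrainMap.from_volume(grid, "brain", vol)
        out = fold_average(m)
        left = grid.left_hemisphere()[grid.mask("brain")]
        assert np.allclose(out.values[left], m.values[left])


class TestStack:
    def test_identical_masks_identical_rows(self, grid):
        brain_left = np.argwhere(grid.mask("brain") & grid.left_hemisphere())
        m = lesion_from_indices(grid, [tuple(i) for i in brain_left[:5]])
        m.hemisphere = "left"
        st = lc.stack([lc.LesionMask(f"s{i}", grid, m.values.copy(), "left")
                       for i in range(3)])
        assert (st.matrix == st.matrix[0]).all()

    def test_disjoint_masks_column_sums(self, grid):
        brain_left = np.argwhere(grid.mask("brain") & grid.left_hemisphere())
        a = lesion_from_indices(grid, [tuple(i) for i in brain_left[:5]])
        b = lesion_from_indices(grid, [tuple(i) for i in brain_left[5:9]])
        st = lc.stack([lc.LesionMask("a", grid, a.values, "left"),
                       lc.LesionMask("b", grid, b.values, "left")])
        assert set(np.unique(st.frequency_map().values)) <= {0.0, 1.0}

    def test_duplicate_ids_rejected(self, grid):
        brain_left = np.argwhere(grid.mask("brain") & grid.left_hemisphere())
        m = lesion_from_indices(grid, [tuple(i) for i in brain_left[:5]])
        with pytest.raises(lc.ValidationError):
            lc.stack([lc.LesionMask("x", grid, m.values, "left"),
                      lc.LesionMask("x", grid, m.values, "left")])

    def test_cohort_dimensions(self, stack240, truth):
        assert stack240.matrix.shape == (240, truth.grid.n_voxels("brain"))
        assert (stack240.matrix.sum(axis=0) == stack240.frequency_map().values).all()


class TestSmoothing:
    def test_fwhm_sigma_closed_form(self):
        assert fwhm_to_sigma(5.0) == pytest.approx(2.1233, abs=1e-4)

    def test_constant_map_fixed_point(self, grid):
        m = lc.BrainMap(grid, "brain", np.full(grid.n_voxels("brain"), 3.7))
        assert np.allclose(lc.smooth(m, 6.0).values, 3.7, atol=1e-9)

    def test_interior_impulse_mass_preserved(self, grid):
        centre = tuple(s // 2 for s in grid.shape)
        vol = np.zeros(grid.shape)
        vol[centre] = 1.0
        m = lc.BrainMap.from_volume(grid, "brain", vol)
        out = lc.smooth(m, 5.0)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-6)

    def test_values_stay_in_convex_hull(self, grid):
        rng = np.random.default_rng(3)
        m = lc.BrainMap(grid, "brain", rng.uniform(-2, 5, grid.n_voxels("brain")))
        out = lc.smooth(m, 8.0)
        assert out.values.min() >= m.values.min() - 1e-9
        assert out.values.max() <= m.values.max() + 1e-9


class TestStreamlineMask:
    def test_dominant_voxel_only(self):
        m = line_map([100.0, 1.0, 1.0])
        assert lc.streamline_mask(m, 0.01).tolist() == [0]

    def test_zero_fraction_keeps_all_nonzero(self):
        m = line_map([3.0, 0.0, 2.0, 1.0])
        assert lc.streamline_mask(m, 0.0).tolist() == [0, 2, 3]

    @pytest.mark.parametrize("v, expect_all", [(50, True), (200, False)])
    def test_uniform_density_threshold(self, v, expect_all):
        m = line_map(np.ones(v))
        kept = lc.streamline_mask(m, 0.01)
        assert (len(kept) == v) == expect_all
        if not expect_all:
            assert len(kept) == 0

    def test_all_zero_density_empty(self):
        assert lc.streamline_mask(line_map(np.zeros(5))).size == 0
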