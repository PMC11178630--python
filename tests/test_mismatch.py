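"""Registration-error draws and Gaussian-spline free-form deformation."""

import numpy as np
import pytest

from biopsyplan.mismatch import (
    CONTROL_SHAPE,
    DeformationField,
    TREConfig,
    densify,
    sample_deformation,
    sample_tre,
    translate_mask,
    warp_mask,
)
from biopsyplan.phantoms_io import MaskVolume

SHAPE = (40, 40, 32)
SPACING = (1.0, 1.0, 1.0)
EXTENT = tuple((s - 1) * sp for s, sp in zip(SHAPE, SPACING))


class TestSampleTre:
    def test_level_zero_is_exact_zero(self):
        t = sample_tre(TREConfig(level_mm=0.0, seed=0))
        assert not t["gland"].any() and not t["lesion"].any()

    def test_rms_magnitude_calibration(self):
        """10^4 draws at level 10 mm: E[|d|^2] must be 100 +/- 3 mm^2."""
        rng = np.random.default_rng(0)
        cfg = TREConfig(level_mm=10.0)
        sq = [np.sum(sample_tre(cfg, rng)["gland"] ** 2) for _ in range(10_000)]
        assert np.mean(sq) == pytest.approx(100.0, abs=3.0)

    def test_same_seed_identical(self):
        a = sample_tre(TREConfig(level_mm=5.0, seed=42))
        b = sample_tre(TREConfig(level_mm=5.0, seed=42))
        np.testing.assert_array_equal(a["gland"], b["gland"])
        np.testing.assert_array_equal(a["lesion"], b["lesion"])

    def test_shared_translation_when_not_per_structure(self):
        t = sample_tre(TREConfig(level_mm=5.0, per_structure=False, seed=1))
        np.testing.assert_array_equal(t["gland"], t["lesion"])

    def test_negative_level_rejected(self):
        with pytest.raises(ValueError):
            TREConfig(level_mm=-1.0)


class TestSampleDeformation:
    def test_zero_rate_or_scale_gives_zero_field(self):
        for rate, scale in [(0.0, 1.0), (0.5, 0.0)]:
            f = sample_deformation(rate, scale, None, EXTENT, seed=0)
            assert not f.displacements.any()

    def test_rate_controls_displaced_count(self):
        f = sample_deformation(0.25, 0.1, None, EXTENT, seed=0)
        assert f.n_displaced() == 250

    def test_full_rate_full_scale(self):
        f = sample_deformation(1.0, 1.0, None, EXTENT, seed=0)
        assert f.n_displaced() == 1000
        assert np.abs(f.displacements).max() <= 1.0

    def test_components_bounded_by_scale(self):
        f = sample_deformation(0.5, 2.5, None, EXTENT, seed=3)
        assert np.abs(f.displacements).max() <= 2.5


def _single_point_field(index, vec, sigma=4.0):
    disp = np.zeros(CONTROL_SHAPE + (3,))
    disp[index] = vec
    return DeformationField(
        displacements=disp, image_extent_mm=EXTENT, kernel_sigma_mm=sigma
    )


def _direct_convolution_oracle(field, shape, spacing):
    """Evaluate the Gaussian-spline sum point by point (no separability)."""
    coords = [np.arange(shape[d]) * spacing[d] for d in range(3)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    out = np.zeros(shape + (3,))
    cps = [field.control_coords(d) for d in range(3)]
    idx = np.argwhere(np.any(field.displacements != 0, axis=-1))
    for a, b, c in idx:
        d2 = (
            (xx - cps[0][a]) ** 2 + (yy - cps[1][b]) ** 2 + (zz - cps[2][c]) ** 2
        )
        w = np.exp(-d2 / (2 * field.kernel_sigma_mm**2))
        out += w[..., None] * field.displacements[a, b, c]
    return out


class TestDensify:
    def test_zero_field_zero_volume(self):
        f = _single_point_field((4, 4, 4), (0, 0, 0))
        dense = densify(f, SHAPE, SPACING)
        assert not dense.any()

    def test_single_point_matches_direct_convolution(self):
        f = _single_point_field((3, 5, 4), (5.0, -2.0, 1.0))
        dense = densify(f, SHAPE, SPACING)
        oracle = _direct_convolution_oracle(f, SHAPE, SPACING)
        np.testing.assert_allclose(dense, oracle, rtol=1e-6, atol=1e-9)

    def test_peak_at_control_point(self):
        f = _single_point_field((4, 4, 4), (5.0, 0.0, 0.0))
        dense = densify(f, SHAPE, SPACING)
        peak = np.unravel_index(np.argmax(dense[..., 0]), SHAPE)
        cp_vox = tuple(
            int(round(f.control_coords(d)[4] / SPACING[d])) for d in range(3)
        )
        assert np.linalg.norm(np.subtract(peak, cp_vox)) <= 1.0
        assert dense[..., 0].max() <= 5.0 + 1e-9

    def test_linearity_superposition(self):
        fa = _single_point_field((1, 1, 1), (3.0, 0.0, 0.0))
        fb = _single_point_field((8, 8, 8), (0.0, -4.0, 2.0))
        fsum = DeformationField(
            displacements=fa.displacements + fb.displacements,
            image_extent_mm=EXTENT, kernel_sigma_mm=fa.kernel_sigma_mm,
        )
        np.testing.assert_allclose(
            densify(fsum, SHAPE, SPACING),
            densify(fa, SHAPE, SPACING) + densify(fb, SHAPE, SPACING),
            rtol=1e-12, atol=1e-12,
        )

    def test_dense_bounded_by_kernel_sum(self):
        f = sample_deformation(1.0, 1.0, None, EXTENT, seed=5)
        dense = densify(f, SHAPE, SPACING)
        bounds = []
        for d in range(3):
            x = np.arange(SHAPE[d]) * SPACING[d]
            c = f.control_coords(d)
            g = np.exp(-((x[:, None] - c) ** 2) / (2 * f.kernel_sigma_mm**2))
            bounds.append(g.sum(axis=1).max())
        assert np.abs(dense).max() <= np.prod(bounds) * 1.0 + 1e-9


def _ball_mask(radius=8.0, shape=SHAPE):
    c = [(s - 1) / 2 for s in shape]
    g = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g[d] - c[d]) ** 2 for d in range(3))
    return MaskVolume((d2 <= radius**2).astype(np.uint8))


class TestWarpMask:
    def test_identity_field_returns_input(self):
        m = _ball_mask()
        dense = np.zeros(SHAPE + (3,))
        out = warp_mask(m, dense)
        np.testing.assert_array_equal(out.voxels, m.voxels)

    def test_uniform_field_translates(self):
        m = _ball_mask(6.0)
        dense = np.zeros(SHAPE + (3,))
        dense[..., 0] = 3.0  # +3 mm = +3 voxels along x
        out = warp_mask(m, dense)
        np.testing.assert_array_equal(out.voxels, np.roll(m.voxels, 3, axis=0))

    def test_small_field_volume_stable(self):
        """Monte-Carlo: small fields (scale 1 mm, rate 0.25) perturb lesion
        volume by < 15% on average."""
        m = _ball_mask(8.0)
        rels = []
        for seed in range(10):
            f = sample_deformation(0.25, 1.0, None, EXTENT, seed=seed)
            dense = densify(f, SHAPE, SPACING)
            out = warp_mask(m, dense)
            rels.append(
                abs(int(out.voxels.sum()) - int(m.voxels.sum())) / m.voxels.sum()
            )
        assert np.mean(rels) < 0.15

    def test_binarity_and_shape_preserved(self):
        m = _ball_mask()
        f = sample_deformation(1.0, 3.0, None, EXTENT, seed=9)
        out = warp_mask(m, densify(f, SHAPE, SPACING))
        assert out.shape == m.shape
        assert set(np.unique(out.voxels)) <= {0, 1}

    def test_non_finite_field_rejected(self):
        m = _ball_mask()
        dense = np.zeros(SHAPE + (3,))
        dense[0, 0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            warp_mask(m, dense)

    def test_field_export_as_4d_nifti(self, tmp_path):
        import nibabel as nib

        from biopsyplan.mismatch import write_field

        f = sample_deformation(0.25, 1.0, None, EXTENT, seed=0)
        p = tmp_path / "field.nii.gz"
        write_field(f, SHAPE, SPACING, p)
        img = nib.load(p)
        assert img.shape == SHAPE + (3,)
        np.testing.assert_allclose(
            np.asarray(img.dataobj), densify(f, SHAPE, SPACING), atol=1e-6
        )

    def test_integral_translation_composes_with_warp(self):
        """Backward-warp composition: warping a t-translated mask with field u
        equals warping the original with u + t, for integral-voxel t."""
        m = _ball_mask(6.0)
        t = np.array([2.0, -3.0, 1.0])
        f = sample_deformation(0.3, 1.5, None, EXTENT, seed=2)
        dense = densify(f, SHAPE, SPACING)
        lhs = warp_mask(translate_mask(m, t), dense)
        rhs = warp_mask(m, dense + t)
        # linear resampling of the two paths differs only at crossing voxels
        mismatch = np.mean(lhs.voxels != rhs.voxels)
        assert mismatch < 0.005
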