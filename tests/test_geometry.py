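"""Template grid, action quantization, needle rasterization, core lengths."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biopsyplan.geometry import (
    APEX,
    BASE,
    DEFAULT_CORE_LENGTH_MM,
    GRID_SIZE,
    Action,
    build_template_grid,
    depth_planes,
    intersection_length,
    quantize_action,
    rasterize_needle,
)
from biopsyplan.phantoms_io import NEEDLE_AXIS, MaskVolume, PatientCase, generate_phantom

from conftest import SMALL_SHAPE


class TestTemplateGrid:
    def test_node_count_and_span(self, centred_case):
        grid = build_template_grid(centred_case)
        nodes = grid.all_nodes()
        assert nodes.shape == (169, 2)
        cx, cy = grid.centre_mm
        # 6 steps of 5 mm on each side of the centre
        np.testing.assert_allclose(nodes[:, 0].min(), cx - 30.0)
        np.testing.assert_allclose(nodes[:, 0].max(), cx + 30.0)
        np.testing.assert_allclose(nodes[:, 1].min(), cy - 30.0)
        np.testing.assert_allclose(nodes[:, 1].max(), cy + 30.0)

    def test_centre_node_is_grid_centre(self, centred_case):
        grid = build_template_grid(centred_case)
        assert grid.node(6, 6) == pytest.approx(grid.centre_mm)

    def test_adjacent_nodes_5mm_apart(self, centred_case):
        grid = build_template_grid(centred_case)
        x0, y0 = grid.node(3, 4)
        x1, y1 = grid.node(4, 4)
        x2, y2 = grid.node(3, 5)
        assert (x1 - x0, y1 - y0) == pytest.approx((5.0, 0.0))
        assert (x2 - x0, y2 - y0) == pytest.approx((0.0, 5.0))

    def test_grid_centred_on_gland_centroid(self, offset_case):
        grid = build_template_grid(offset_case)
        c = offset_case.gland.centroid_mm()
        assert grid.centre_mm == pytest.approx((c[0], c[1]))


def _oracle_quantize(dx, dy, node):
    """Brute-force reference: round half away from zero then clamp."""
    def r(v):
        return int(np.sign(v) * np.floor(abs(v) + 0.5))

    i = min(max(node[0] + r(dx), 0), GRID_SIZE - 1)
    j = min(max(node[1] + r(dy), 0), GRID_SIZE - 1)
    return (i, j)


class TestQuantizeAction:
    def test_identity_at_centre(self):
        node, fire, depth = quantize_action(Action(0, 0, 0), (6, 6))
        assert node == (6, 6) and fire and depth == APEX

    @pytest.mark.parametrize(
        "dx,expected", [(3.4, 3), (-3.5, -4), (3.5, 4), (-3.4, -3), (0.49, 0)]
    )
    def test_half_away_from_zero_rounding(self, dx, expected):
        node, _, _ = quantize_action(Action(dx, 0, 0), (6, 6))
        assert node[0] - 6 == expected

    def test_clamps_at_grid_edge(self):
        node, _, _ = quantize_action(Action(9.9, 0, 0), (10, 6))
        assert node == (12, 6)

    def test_exhaustive_integer_displacements_match_oracle(self):
        for start in [(0, 0), (6, 6), (12, 12), (2, 10)]:
            for dx in range(-10, 11):
                for dy in range(-10, 11):
                    node, _, _ = quantize_action(Action(dx, dy, 0.5), start)
                    assert node == _oracle_quantize(dx, dy, start)

    @pytest.mark.parametrize(
        "dz,fire,depth",
        [(-1.0, False, "no_fire"), (-0.34, False, "no_fire"),
         (-0.33, True, APEX), (0.0, True, APEX), (0.33, True, APEX),
         (0.34, True, BASE), (1.0, True, BASE)],
    )
    def test_dz_three_way_threshold(self, dz, fire, depth):
        _, f, d = quantize_action(Action(0, 0, dz), (6, 6))
        assert (f, d) == (fire, depth)

    def test_non_finite_raises(self):
        with pytest.raises(ValueError):
            quantize_action(Action(np.nan, 0, 0), (6, 6))

    @settings(max_examples=200, deadline=None)
    @given(
        dx=st.floats(-50, 50), dy=st.floats(-50, 50), dz=st.floats(-1, 1),
        i=st.integers(0, 12), j=st.integers(0, 12),
    )
    def test_never_leaves_grid(self, dx, dy, dz, i, j):
        node, _, _ = quantize_action(Action(dx, dy, dz), (i, j))
        assert 0 <= node[0] < GRID_SIZE and 0 <= node[1] < GRID_SIZE


class TestDepthPlanes:
    def test_quartiles_of_axial_extent(self, centred_case):
        apex, base = depth_planes(centred_case)
        z = np.argwhere(centred_case.gland.voxels)[:, NEEDLE_AXIS].astype(float)
        zmin, zmax = z.min(), z.max()  # spacing 1, origin 0
        assert apex == pytest.approx(zmin + 0.25 * (zmax - zmin))
        assert base == pytest.approx(zmin + 0.75 * (zmax - zmin))

    def test_symmetric_about_centroid(self, centred_case):
        apex, base = depth_planes(centred_case)
        cz = centred_case.gland.centroid_mm()[NEEDLE_AXIS]
        assert (apex + base) / 2 == pytest.approx(cz, abs=0.6)

    def test_translation_equivariance(self, centred_case):
        shifted = PatientCase(
            "t",
            MaskVolume(centred_case.gland.voxels, origin=(0, 0, 7.0)),
            MaskVolume(centred_case.lesion.voxels, origin=(0, 0, 7.0)),
        )
        a0, b0 = depth_planes(centred_case)
        a1, b1 = depth_planes(shifted)
        assert (a1 - a0, b1 - b0) == pytest.approx((7.0, 7.0))


class TestRasterizeNeedle:
    def test_interior_core_voxel_count(self, centred_case):
        traj = rasterize_needle((6, 6), APEX, 20.0, centred_case)
        assert traj.voxels.sum() == 20

    def test_column_at_single_xy(self, centred_case):
        traj = rasterize_needle((8, 5), BASE, 20.0, centred_case)
        idx = np.argwhere(traj.voxels)
        in_plane = [d for d in range(3) if d != NEEDLE_AXIS]
        assert len(np.unique(idx[:, in_plane[0]])) == 1
        assert len(np.unique(idx[:, in_plane[1]])) == 1

    def test_clipped_at_image_boundary(self, centred_case):
        # oracle: overlap of [centre - L/2, centre + L/2) with the axial
        # voxel-centre range, in whole voxels
        apex, base = depth_planes(centred_case)
        n_axial = centred_case.gland.shape[NEEDLE_AXIS]
        long = 3.0 * n_axial  # far longer than the image -> full column
        traj = rasterize_needle((6, 6), APEX, long, centred_case)
        assert traj.voxels.sum() == n_axial

    def test_node_outside_image_raises(self):
        # a tiny image where outer grid nodes fall beyond the field of view
        case = generate_phantom(
            seed=0, gland_radii_mm=(14, 14, 12), lesion_radius_mm=4.0,
            shape=(32, 32, 32),
        )
        with pytest.raises(ValueError, match="field of view"):
            rasterize_needle((0, 0), APEX, 20.0, case)


class TestIntersectionLength:
    def test_disjoint_masks_zero(self, centred_case):
        traj = rasterize_needle((0, 6), APEX, 20.0, centred_case)
        assert intersection_length(traj, centred_case.lesion) == 0.0

    @pytest.mark.parametrize("offset_mm,radius", [(0.0, 5.0), (3.0, 5.0), (4.0, 5.0)])
    def test_chord_through_sphere(self, offset_mm, radius):
        case = generate_phantom(
            seed=0, gland_radii_mm=(26, 24, 21), lesion_radius_mm=radius,
            lesion_offset_mm=(offset_mm, 0.0, 0.0), shape=SMALL_SHAPE,
        )
        grid = build_template_grid(case)
        lc = case.lesion.centroid_mm()
        # column exactly through the lesion-centre (x offset back to the
        # gland-centred grid line), long enough to traverse the lesion
        nodes = grid.all_nodes()
        d = np.hypot(nodes[:, 0] - grid.centre_mm[0], nodes[:, 1] - lc[1])
        k = int(np.argmin(d))
        node = (k // 13, k % 13)
        traj = rasterize_needle(node, APEX, 200.0, case)
        # analytic chord at the needle's actual in-plane distance from the
        # lesion centre (the raster snaps the column to a voxel centre)
        tv = np.argwhere(traj.voxels)[0]
        in_plane = [d for d in range(3) if d != 2]
        dist = np.hypot(tv[in_plane[0]] - lc[0], tv[in_plane[1]] - lc[1])
        chord = 2.0 * np.sqrt(max(radius**2 - dist**2, 0.0))
        assert abs(dist - offset_mm) <= 0.75  # node snaps within a half-voxel
        assert intersection_length(traj, case.lesion) == pytest.approx(
            chord, abs=1.0
        )

    def test_bounded_by_core_and_lesion_extent(self, offset_case):
        traj = rasterize_needle((6, 6), APEX, DEFAULT_CORE_LENGTH_MM, offset_case)
        lesion_z = np.argwhere(offset_case.lesion.voxels)[:, NEEDLE_AXIS]
        extent = float(np.ptp(lesion_z)) + 1.0
        got = intersection_length(traj, offset_case.lesion)
        assert got <= min(DEFAULT_CORE_LENGTH_MM, extent) + 1.0

    def test_shape_mismatch_raises(self, centred_case):
        other = MaskVolume(np.zeros((8, 8, 8), dtype=np.uint8))
        with pytest.raises(ValueError):
            intersection_length(other, centred_case.lesion)
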