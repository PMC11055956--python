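"""Distance fields, supply index, cell distances, Col IV association."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from vtscope import (
    CellSet,
    cell_distances,
    colIV_association,
    complementary_cell_distances,
    distance_histogram,
    pv_distance_field,
    supply_index,
)
from conftest import sphere_mask, tube_mask, SPACING


class TestDistanceField:
    def test_face_adjacent_voxel_along_z(self):
        cd31 = np.zeros((8, 8, 8), bool)
        cd31[3, 4, 4] = True
        vts = np.ones((8, 8, 8), bool)
        field = pv_distance_field(cd31, vts, SPACING)
        assert field.values[4, 4, 4] == pytest.approx(1.0)  # dz = 1 um
        assert field.values[3, 4, 5] == pytest.approx(0.5)  # dx = 0.5 um

    def test_pv_voxels_excluded_from_domain(self):
        cd31 = np.zeros((6, 6, 6), bool)
        cd31[2, 2, 2] = True
        field = pv_distance_field(cd31, np.ones((6, 6, 6), bool), SPACING)
        assert np.isnan(field.values[2, 2, 2])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        cd31 = rng.random((16, 16, 16)) < 0.02
        vts = rng.random((16, 16, 16)) < 0.7
        if not cd31.any():
            cd31[0, 0, 0] = True
        field = pv_distance_field(cd31, vts, SPACING)
        coords_um = np.argwhere(np.ones((16,) * 3)).reshape(16, 16, 16, 3) * SPACING
        pv_um = np.argwhere(cd31) * SPACING
        domain = vts & ~cd31
        brute = cdist(coords_um[domain], pv_um).min(axis=1)
        np.testing.assert_allclose(field.values[domain], brute, rtol=1e-9)

    def test_empty_pv_all_sentinel_with_warning(self):
        with pytest.warns(UserWarning, match="empty CD31"):
            field = pv_distance_field(
                np.zeros((6, 6, 6), bool), np.ones((6, 6, 6), bool), SPACING
            )
        assert not field.has_vessels
        assert np.isnan(field.values).all()
        hist = distance_histogram(field)
        assert len(hist) == 0 and np.isnan(hist.attrs["median_um"])

    def test_lipschitz_and_monotone_contraction(self):
        rng = np.random.default_rng(1)
        cd31 = rng.random((12, 12, 12)) < 0.03
        cd31[5, 5, 5] = True
        vts = np.ones((12, 12, 12), bool)
        field = pv_distance_field(cd31, vts, (1.0, 1.0, 1.0))
        v = field.values
        # 1-Lipschitz along voxel steps (isotropic 1 um grid)
        for axis in range(3):
            diff = np.abs(np.diff(np.nan_to_num(v, nan=0.0), axis=axis))
            finite = ~np.isnan(np.diff(v, axis=axis))
            assert np.all(diff[finite] <= 1.0 + 1e-9)
        # adding PV voxels never increases any distance
        more = cd31.copy()
        more[2, 9, 9] = True
        field2 = pv_distance_field(more, vts, (1.0, 1.0, 1.0))
        both = np.isfinite(field.values) & np.isfinite(field2.values)
        assert np.all(field2.values[both] <= field.values[both] + 1e-9)

    def test_uint8_export_quantization(self):
        cd31 = np.zeros((8, 8, 8), bool)
        cd31[4, 4, 4] = True
        vts = sphere_mask((8, 8, 8), (4, 2, 2), 3.0)
        field = pv_distance_field(cd31, vts, SPACING)
        enc = field.to_uint8(max_distance=10.0)
        assert np.all(enc[~field.domain] == 255)
        step = 10.0 / 254.0
        dec = enc[field.domain] * step
        np.testing.assert_allclose(dec, field.values[field.domain], atol=step)


class TestHistogramAndSupply:
    def test_bin_counts_conserved(self):
        rng = np.random.default_rng(2)
        cd31 = rng.random((14, 14, 14)) < 0.05
        cd31[0, 0, 0] = True
        vts = sphere_mask((14, 14, 14), (7, 3.5, 3.5), 3.0)
        field = pv_distance_field(cd31, vts, SPACING)
        hist = distance_histogram(field, bin_width=1.0)
        assert hist["count"].sum() == vts.sum() - (vts & cd31).sum()

    def test_cylinder_axis_median_analytic(self):
        # VTS = flat-ended cylinder of radius R along x, PV = its axis row of
        # voxels: median distance-to-axis over a disk is R/sqrt(2)
        R = 20.0
        shape = (44, 88, 120)
        z0, y0 = 21, 43
        zz = (np.arange(shape[0]) * SPACING[0])[:, None]
        yy = (np.arange(shape[1]) * SPACING[1])[None, :]
        radial = np.sqrt((zz - z0 * SPACING[0]) ** 2 + (yy - y0 * SPACING[1]) ** 2)
        vts = np.broadcast_to((radial <= R)[:, :, None], shape).copy()
        cd31 = np.zeros(shape, bool)
        cd31[z0, y0, :] = True
        field = pv_distance_field(cd31, vts, SPACING)
        assert field.median() == pytest.approx(R / np.sqrt(2), abs=1.0)

    def test_supply_index_definition_and_proportionality(self):
        assert supply_index(10.0, 10.0) == pytest.approx(1.0)
        assert supply_index(10.0, 20.0) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            supply_index(10.0, 0.0)
        with pytest.raises(ValueError):
            supply_index(0.0, 10.0)

    def test_supply_index_end_to_end_oracle(self):
        # cylinder-in-sphere phantom recomputed from raw voxel counts
        shape = (40, 80, 80)
        center = (19.5, 19.75, 19.75)
        vts = sphere_mask(shape, center, 18.0)
        cd31 = tube_mask(shape, (19.5, 19.75, 4), (19.5, 19.75, 36), 2.0) & vts
        field = pv_distance_field(cd31, vts, SPACING)
        rel_pct = 100.0 * cd31.sum() / vts.sum()
        si = supply_index(rel_pct, field.median())
        # independent: brute-force distances
        coords = np.argwhere(vts & ~cd31) * SPACING
        pv = np.argwhere(cd31) * SPACING
        brute_median = np.median(cdist(coords, pv).min(axis=1))
        assert si == pytest.approx(rel_pct / brute_median, rel=1e-9)


class TestCellDistances:
    def test_cell_on_pv_voxel_zero(self):
        cd31 = np.zeros((8, 8, 8), bool)
        cd31[4, 4, 4] = True
        cells = CellSet(role="tumor", centroids=np.array([[4.0, 2.0, 2.0]]))
        table = cell_distances(cells, cd31, SPACING, mode="mask")
        assert table["distance_um"].iloc[0] == pytest.approx(0.0)

    def test_center_of_sphere_surface_mode(self):
        shape = (60, 120, 120)
        center = (29.5, 29.75, 29.75)
        mask = sphere_mask(shape, center, 20.0)
        cells = CellSet(role="cd11b", centroids=np.array([center]))
        table = cell_distances(cells, mask, SPACING, mode="surface")
        assert table["distance_um"].iloc[0] == pytest.approx(20.0, abs=1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_config_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        target = rng.random((16, 16, 16)) < 0.05
        target[8, 8, 8] = True
        pts = rng.uniform(0, 7.5, size=(8, 3)) * (2, 1, 1)
        cells = CellSet(role="tumor", centroids=pts)
        table = cell_distances(cells, target, SPACING, mode="mask")
        tgt_um = np.argwhere(target) * SPACING
        snapped = np.round(pts / SPACING) * SPACING
        brute = cdist(snapped, tgt_um).min(axis=1)
        np.testing.assert_allclose(table["distance_um"].to_numpy(), brute, rtol=1e-9)

    def test_empty_target_sentinel(self):
        cells = CellSet(role="tumor", centroids=np.array([[1.0, 1.0, 1.0]]))
        table = cell_distances(cells, np.zeros((4, 4, 4), bool), SPACING)
        assert np.isnan(table["distance_um"]).all()

    def test_complementary_distances(self):
        a = CellSet(role="tumor", centroids=np.array([[0.0, 0, 0], [0, 0, 10.0]]))
        b = CellSet(role="fibroblast", centroids=np.array([[0.0, 0, 4.0]]))
        table = complementary_cell_distances(a, b)
        np.testing.assert_allclose(table["distance_um"], [4.0, 6.0])


class TestColIVAssociation:
    def test_dilated_cd31_fully_associated(self):
        from scipy import ndimage

        cd31 = np.zeros((16, 16, 16), bool)
        cd31[8, 6:10, 6:10] = True
        colIV = ndimage.binary_dilation(cd31)  # within 1 voxel <= 3 um
        vts = np.ones((16, 16, 16), bool)
        out = colIV_association(colIV, cd31, vts, d_assoc=3.0, spacing=SPACING)
        assert out["associated_fraction"] == pytest.approx(1.0)

    def test_distant_blob_not_associated(self):
        cd31 = np.zeros((20, 20, 40), bool)
        cd31[10, 10, 2:6] = True
        colIV = np.zeros_like(cd31)
        colIV[10, 10, 30:34] = True  # ~12 um away
        vts = np.ones_like(cd31)
        out = colIV_association(colIV, cd31, vts, d_assoc=3.0, spacing=SPACING)
        assert out["associated_fraction"] == 0.0
        assert out["in_vts_nonassociated_fraction"] == pytest.approx(1.0)

    def test_shell_fraction_matches_voxel_oracle(self):
        cd31 = tube_mask((24, 60, 120), (12, 15, 10), (12, 15, 50), 3.0)
        colIV = tube_mask((24, 60, 120), (12, 15, 10), (12, 15, 50), 6.0) & ~cd31
        vts = tube_mask((24, 60, 120), (12, 15, 10), (12, 15, 50), 14.0)
        d_assoc = 2.0
        out = colIV_association(colIV, cd31, vts, d_assoc=d_assoc, spacing=SPACING)
        col_um = np.argwhere(colIV) * SPACING
        pv_um = np.argwhere(cd31) * SPACING
        near = cdist(col_um, pv_um).min(axis=1) <= d_assoc
        assert out["associated_fraction"] == pytest.approx(near.mean(), rel=1e-9)
        assert out["associated_over_cd31"] == pytest.approx(
            near.sum() / cd31.sum(), rel=1e-9
        )

    def test_empty_cd31_warns_zero(self):
        colIV = np.zeros((8, 8, 8), bool)
        colIV[2, 2, 2] = True
        with pytest.warns(UserWarning, match="empty CD31"):
            out = colIV_association(
                colIV, np.zeros((8, 8, 8), bool), np.ones((8, 8, 8), bool)
            )
        assert out["associated_fraction"] == 0.0
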