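"""ROI grid construction, weighted statistics, SPI/SHI, percentages."""

import numpy as np
import pytest

from lungstrain import (
    BinaryMask,
    axis_partition,
    build_roi_grid,
    make_roi_grid,
    percentage_significant,
    roi_weighted_stats,
    shi,
    spi,
    tetrahedralize_mask,
    volumetric_strain,
)
from lungstrain.core import AB, DV
from lungstrain.mesh import StrainField
from lungstrain.roi import cell_strain_samples


def _field_from_mask(mask_arr, spacing=0.1, strain_fn=None):
    mesh = tetrahedralize_mask(BinaryMask(mask_arr, spacing))
    ref = mesh.nodes / 1.1
    s = volumetric_strain(mesh, ref)
    if strain_fn is not None:
        s.strain = strain_fn(s.centroid)
    return s


@pytest.fixture(scope="module")
def box_field():
    m = np.zeros((24, 24, 24), bool)
    m[2:22, 2:22, 2:22] = True
    return _field_from_mask(m)


@pytest.fixture(scope="module")
def ellipsoid_field(graded_ground_truth):
    spec, mask, gt = graded_ground_truth
    mesh = tetrahedralize_mask(mask)
    u = gt.displacement(mesh.nodes)
    return volumetric_strain(mesh, mesh.nodes + u)


class TestAxisPartition:
    def test_uniform_box_boundaries_near_deciles(self, box_field):
        bounds = axis_partition(box_field, AB, 10)
        extent = box_field.centroid[:, AB]
        lo, hi = extent.min(), extent.max()
        expected = np.linspace(lo, hi, 11)
        # centroid coordinates are quantised to quarter-voxels; allow one voxel
        assert np.allclose(bounds, expected, atol=0.1)

    def test_slab_volumes_balanced(self, ellipsoid_field):
        bounds = axis_partition(ellipsoid_field, DV, 10)
        idx = np.clip(
            np.searchsorted(bounds[1:-1], ellipsoid_field.centroid[:, DV], side="left"), 0, 9
        )
        vols = np.bincount(idx, weights=ellipsoid_field.ei_volume, minlength=10)
        total = ellipsoid_field.ei_volume.sum()
        # balance up to the largest tied-centroid-coordinate group
        coord = ellipsoid_field.centroid[:, DV]
        _, counts = np.unique(np.round(coord, 9), return_counts=True)
        granule = counts.max() * ellipsoid_field.ei_volume.max()
        assert np.abs(vols - total / 10).max() <= granule

    def test_too_few_slabs_rejected(self, box_field):
        with pytest.raises(ValueError):
            axis_partition(box_field, AB, 1)


class TestGridConstruction:
    def test_box_occupies_all_cells(self, box_field):
        grid = make_roi_grid(box_field, 10)
        assert grid.n_occupied == 100

    def test_oblique_lung_has_void_corner_cells(self, ellipsoid_field):
        # the apical end sits dorsally, so the (apical, ventral-most) and
        # (basal, dorsal-most) corner cells never intersect the lung
        grid = make_roi_grid(ellipsoid_field, 10)
        assert grid.n_occupied < 100
        occ = grid.occupied
        assert not occ[0, -1] and not occ[-1, 0]

    def test_binning_matches_bruteforce_oracle(self, ellipsoid_field):
        grid = make_roi_grid(ellipsoid_field, 10)
        ab, dv = grid.ab_bounds, grid.dv_bounds
        # independent per-tet loop using explicit interval comparisons
        rng = np.random.default_rng(3)
        pick = rng.integers(0, len(ellipsoid_field.strain), 500)
        for t in pick:
            ca, cd = ellipsoid_field.centroid[t, AB], ellipsoid_field.centroid[t, DV]
            # ties go to the lower slab: count boundaries strictly below
            i = int(np.clip(sum(b < ca for b in ab[1:-1]), 0, 9))
            j = int(np.clip(sum(b < cd for b in dv[1:-1]), 0, 9))
            assert grid.cell_of_tet[t] == i * 10 + j

    def test_boundary_past_centroids_empties_row(self, box_field):
        bounds = axis_partition(box_field, AB, 10)
        dv_bounds = axis_partition(box_field, DV, 10)
        shifted = bounds.copy()
        shifted[1] = box_field.centroid[:, AB].max() + 1.0  # row 0 swallows all
        grid = build_roi_grid(box_field, shifted, dv_bounds, 10)
        assert not grid.occupied[1].any()


class TestWeightedStats:
    def test_hand_arithmetic_two_tets(self):
        f = StrainField(
            strain=np.array([0.1, 0.3]),
            ref_volume=np.array([1.0, 3.0]),
            ei_volume=np.array([1.0, 3.0]),
            centroid=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
            spacing=1.0,
        )
        grid = build_roi_grid(f, np.array([-1.0, 2.0]), np.array([-1.0, 2.0]), n=2)
        stats = roi_weighted_stats(f, grid)
        assert stats.mean[0, 0] == pytest.approx(0.25)

    def test_constant_strain_zero_sd(self, box_field):
        f = box_field
        f2 = StrainField(np.full_like(f.strain, 0.2), f.ref_volume, f.ei_volume, f.centroid, f.spacing)
        grid = make_roi_grid(f2, 4)
        stats = roi_weighted_stats(f2, grid)
        occ = grid.occupied
        assert np.allclose(stats.mean[occ], 0.2)
        assert np.allclose(stats.sd[occ], 0.0, atol=1e-9)

    def test_random_cell_matches_bruteforce(self, ellipsoid_field):
        grid = make_roi_grid(ellipsoid_field, 10)
        stats = roi_weighted_stats(ellipsoid_field, grid)
        occupied_cells = np.argwhere(grid.occupied)
        rng = np.random.default_rng(0)
        for i, j in occupied_cells[rng.integers(0, len(occupied_cells), 5)]:
            sel = grid.cell_of_tet == i * 10 + j
            w = ellipsoid_field.ei_volume[sel]
            e = ellipsoid_field.strain[sel]
            mean = (w * e).sum() / w.sum()
            sd = np.sqrt((w * (e - mean) ** 2).sum() / w.sum())
            assert stats.mean[i, j] == pytest.approx(mean, rel=1e-12)
            assert stats.sd[i, j] == pytest.approx(sd, rel=1e-9, abs=1e-12)

    def test_void_cells_are_nan_not_zero(self, ellipsoid_field):
        grid = make_roi_grid(ellipsoid_field, 10)
        stats = roi_weighted_stats(ellipsoid_field, grid)
        assert np.isnan(stats.mean[~grid.occupied]).all()

    def test_grand_mean_and_volume_conservation(self, ellipsoid_field):
        grid = make_roi_grid(ellipsoid_field, 10)
        stats = roi_weighted_stats(ellipsoid_field, grid)
        occ = grid.occupied
        grand = np.nansum(stats.mean[occ] * stats.volume[occ]) / np.nansum(stats.volume[occ])
        direct = np.average(ellipsoid_field.strain, weights=ellipsoid_field.ei_volume)
        assert grand == pytest.approx(direct, rel=1e-12)
        assert stats.volume[occ].sum() == pytest.approx(ellipsoid_field.ei_volume.sum(), rel=1e-12)

    def test_cell_samples_partition_the_mesh(self, ellipsoid_field):
        grid = make_roi_grid(ellipsoid_field, 10)
        samples = cell_strain_samples(ellipsoid_field, grid)
        assert sum(len(v) for v in samples.values()) == len(ellipsoid_field.strain)


class TestIndices:
    def test_spi_identity_and_hand_value(self):
        assert spi(0.3, 0.3) == pytest.approx(1.0)
        assert spi(0.2, 0.5) == pytest.approx(1.25)
        assert spi(0.5, 0.2) < 1.0

    def test_spi_invalid_mean_rejected(self):
        with pytest.raises(ValueError):
            spi(-1.2, 0.1)

    def test_shi_identities_and_hand_value(self):
        assert shi(0.0, 0.0) == pytest.approx(1.0)
        assert shi(0.25, 0.10) == pytest.approx(1.10 / 1.25)
        for m in (0.1, 0.4, 2.0):
            assert shi(m, m) == pytest.approx(1.0)

    def test_shi_shift_consistency(self):
        # adding a constant to all strains: mean -> mean + c, sd unchanged
        rng = np.random.default_rng(2)
        e = rng.normal(0.3, 0.05, 200)
        w = rng.uniform(0.5, 1.5, 200)
        c = 0.07
        mean0 = np.average(e, weights=w)
        sd0 = np.sqrt(np.average((e - mean0) ** 2, weights=w))
        mean1 = np.average(e + c, weights=w)
        sd1 = np.sqrt(np.average((e + c - mean1) ** 2, weights=w))
        assert shi(mean1, sd1) == pytest.approx((1 + sd0) / (1 + mean0 + c), rel=1e-12)


class TestPercentage:
    @pytest.mark.parametrize(
        "k,occ,expected", [(38, 87, 43.7), (1, 84, 1.2), (0, 100, 0.0), (24, 91, 26.4)]
    )
    def test_reported_arithmetic(self, k, occ, expected):
        flags = np.zeros(occ, bool)
        flags[:k] = True
        assert percentage_significant(flags, occ) == expected

    def test_zero_occupied_rejected(self):
        with pytest.raises(ValueError):
            percentage_significant(np.zeros(0, bool), 0)
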