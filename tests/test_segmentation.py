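"""Probability-map post-processing rules and the three cell-expansion modes."""

import numpy as np
import pytest
from scipy import ndimage

from cytotile.segmentation import (
    LabelImage,
    ProbabilityMap,
    ProbabilityMapError,
    cells_fixed_radius,
    cells_propagation,
    cells_watershed,
    default_probability_map,
    dilate_labels_one_pixel,
    nuclei_from_probabilities,
    remove_border_cells,
)
from conftest import disc_labels


def map_from_interior(interior_mask: np.ndarray) -> ProbabilityMap:
    """Hard probability map with the given interior support."""
    p = np.where(interior_mask, 0.9, 0.05)
    b = np.where(interior_mask, 0.05, 0.9)
    rest = 1.0 - p - b
    return ProbabilityMap(background=b, interior=p, boundary=rest)


class TestProbabilityMap:
    def test_per_pixel_sum_enforced(self):
        ones = np.ones((4, 4))
        with pytest.raises(ProbabilityMapError):
            ProbabilityMap(background=ones, interior=ones, boundary=ones)

    def test_blank_image_all_background(self):
        pm = default_probability_map(np.zeros((32, 32)))
        assert np.all(pm.background > 0.5)
        assert np.allclose(pm.background + pm.interior + pm.boundary, 1.0)

    def test_single_disc_one_interior_component_with_boundary_ring(self):
        yy, xx = np.mgrid[0:64, 0:64]
        img = np.exp(-((yy - 32.0) ** 2 + (xx - 32.0) ** 2) / 60.0)
        pm = default_probability_map(img, smoothing_sigma=1.0)
        interior = np.argmax(pm.stacked(), axis=0) == 1
        _, n = ndimage.label(interior)
        assert n == 1
        boundary = np.argmax(pm.stacked(), axis=0) == 2
        # the boundary ring touches the interior component
        grown = ndimage.binary_dilation(interior)
        assert np.any(boundary & grown)
        assert not np.any(boundary & interior)

    def test_always_a_distribution(self):
        rng = np.random.default_rng(0)
        pm = default_probability_map(rng.random((40, 40)), 2.0)
        total = pm.background + pm.interior + pm.boundary
        assert np.allclose(total, 1.0, atol=1e-9)


class TestNucleiFromProbabilities:
    def test_all_background_yields_no_labels(self):
        pm = map_from_interior(np.zeros((32, 32), dtype=bool))
        assert nuclei_from_probabilities(pm, 50).label_set == set()

    def test_two_discs_survive_size_filter(self):
        discs = disc_labels((64, 64), [(20, 20, 8), (44, 44, 8)])  # ~200 px each
        pm = map_from_interior(discs > 0)
        nuclei = nuclei_from_probabilities(pm, min_size=50)
        assert nuclei.label_set == {1, 2}
        for k in (1, 2):
            assert (nuclei.labels == k).sum() >= (discs == k).sum()

    def test_small_component_removed(self):
        big = disc_labels((64, 64), [(20, 20, 8)]) > 0      # ~200 px
        small = disc_labels((64, 64), [(50, 50, 3)]) > 0    # ~30 px
        pm = map_from_interior(big | small)
        nuclei = nuclei_from_probabilities(pm, min_size=50)
        assert len(nuclei.label_set) == 1
        assert nuclei.labels[50, 50] == 0

    def test_dilation_is_one_pixel_and_label_preserving(self):
        # two interior blobs two pixels apart: dilation must not merge them
        interior = np.zeros((16, 24), dtype=bool)
        interior[6:10, 4:10] = True
        interior[6:10, 12:18] = True
        pm = map_from_interior(interior)
        nuclei = nuclei_from_probabilities(pm, 0)
        assert nuclei.label_set == {1, 2}
        # labels stay 4-connected components
        for k in (1, 2):
            _, n = ndimage.label(nuclei.labels == k)
            assert n == 1
        # grown by exactly one pixel: column 10 goes to label 1, column 11 to 2
        assert np.all(nuclei.labels[6:10, 10] == 1)
        assert np.all(nuclei.labels[6:10, 11] == 2)

    def test_contested_tie_goes_to_smaller_label(self):
        # single background column equidistant (distance 1) to both labels
        interior = np.zeros((8, 11), dtype=bool)
        interior[2:6, 0:5] = True
        interior[2:6, 6:11] = True
        pm = map_from_interior(interior)
        nuclei = nuclei_from_probabilities(pm, 0)
        assert np.all(nuclei.labels[2:6, 5] == 1)

    def test_argmax_invariance_under_monotone_rescale(self):
        rng = np.random.default_rng(4)
        raw = rng.dirichlet((1, 1, 1), size=(32, 32))
        pm1 = ProbabilityMap(raw[..., 0], raw[..., 1], raw[..., 2])
        # strictly monotone per-pixel rescale of all three classes together
        powered = raw ** 0.5
        powered /= powered.sum(axis=-1, keepdims=True)
        pm2 = ProbabilityMap(powered[..., 0], powered[..., 1], powered[..., 2])
        a = nuclei_from_probabilities(pm1, 3)
        b = nuclei_from_probabilities(pm2, 3)
        assert np.array_equal(a.labels, b.labels)


def brute_force_nearest_seed(labels: np.ndarray, radius: float) -> np.ndarray:
    """Per-pixel nearest-nucleus scan with the tie -> smaller label rule."""
    out = labels.copy()
    ids = sorted(set(np.unique(labels)) - {0})
    yy, xx = np.mgrid[0:labels.shape[0], 0:labels.shape[1]]
    dists = []
    for k in ids:
        ys, xs = np.nonzero(labels == k)
        d = np.sqrt((yy[..., None] - ys) ** 2 + (xx[..., None] - xs) ** 2).min(-1)
        dists.append(d)
    dists = np.stack(dists)  # (K, H, W)
    best = dists.min(axis=0)
    # smallest label among those achieving the minimum
    winner = np.zeros_like(labels)
    for i in reversed(range(len(ids))):
        winner = np.where(np.isclose(dists[i], best, atol=1e-9), ids[i], winner)
    sel = (labels == 0) & (best <= radius + 1e-9)
    out[sel] = winner[sel]
    return out


class TestCellsFixedRadius:
    def test_radius_zero_identity(self):
        nuc = LabelImage(disc_labels((32, 32), [(16, 16, 5)]))
        cells = cells_fixed_radius(nuc, 0.0)
        assert np.array_equal(cells.labels, nuc.labels)
        assert cells.kind == "cell"

    def test_disc_area_close_to_analytic(self):
        nuc = LabelImage(disc_labels((64, 64), [(32, 32, 10)]))
        cells = cells_fixed_radius(nuc, 5.0)
        area = (cells.labels == 1).sum()
        assert abs(area - np.pi * 15**2) / (np.pi * 15**2) < 0.05

    def test_boundary_matches_brute_force_bisector(self):
        nuc_arr = disc_labels((60, 60), [(30, 20, 4), (30, 30, 4)])  # 10 px apart
        cells = cells_fixed_radius(LabelImage(nuc_arr), 20.0)
        expect = brute_force_nearest_seed(nuc_arr, 20.0)
        assert np.array_equal(cells.labels, expect)

    def test_invariants(self):
        nuc = LabelImage(disc_labels((64, 64), [(20, 20, 6), (40, 45, 5)]))
        cells = cells_fixed_radius(nuc, 8.0)
        assert cells.label_set == nuc.label_set
        keep = nuc.labels > 0
        assert np.array_equal(cells.labels[keep], nuc.labels[keep])


class TestCellsWatershed:
    def test_mask_equal_to_nuclei_gives_nuclei(self):
        nuc = LabelImage(disc_labels((48, 48), [(24, 24, 6)]))
        cells = cells_watershed(nuc, np.zeros((48, 48)),
                                precomputed_mask=nuc.labels > 0)
        assert np.array_equal(cells.labels, nuc.labels)

    def test_single_nucleus_fills_membrane_blob(self):
        nuc_arr = disc_labels((64, 64), [(32, 32, 5)])
        blob = disc_labels((64, 64), [(32, 32, 14)]) > 0
        cells = cells_watershed(LabelImage(nuc_arr), np.zeros((64, 64)),
                                precomputed_mask=blob)
        assert np.array_equal(cells.labels > 0, blob | (nuc_arr > 0))
        assert set(np.unique(cells.labels)) == {0, 1}

    def test_two_nuclei_partition_one_blob(self):
        nuc_arr = disc_labels((64, 64), [(32, 22, 4), (32, 42, 4)])
        yy, xx = np.mgrid[0:64, 0:64]
        blob = ((yy - 32) ** 2 / 120 + (xx - 32) ** 2 / 320) <= 1.0
        cells = cells_watershed(LabelImage(nuc_arr), np.zeros((64, 64)),
                                precomputed_mask=blob)
        allowed = blob | (nuc_arr > 0)
        assert set(np.unique(cells.labels)) == {0, 1, 2}
        # pixel conservation over the seeded mask
        assert (cells.labels > 0).sum() == allowed.sum()

    def test_unseeded_mask_islands_dropped(self):
        nuc_arr = disc_labels((64, 64), [(16, 16, 4)])
        mask = (disc_labels((64, 64), [(16, 16, 8)]) > 0) | \
               (disc_labels((64, 64), [(48, 48, 6)]) > 0)
        cells = cells_watershed(LabelImage(nuc_arr), np.zeros((64, 64)),
                                precomputed_mask=mask)
        assert cells.labels[48, 48] == 0
        assert (cells.labels > 0).sum() == (disc_labels((64, 64), [(16, 16, 8)]) > 0).sum()


class TestCellsPropagation:
    def test_empty_mask_outside_nuclei_identity(self):
        nuc = LabelImage(disc_labels((32, 32), [(16, 16, 5)]))
        cells = cells_propagation(nuc, np.zeros((32, 32)),
                                  mask=np.zeros((32, 32), dtype=bool), lam=1.0)
        assert np.array_equal(cells.labels, nuc.labels)

    def test_large_lambda_matches_nearest_seed_on_axis_pair(self):
        # seeds separated along x: L1 and L2 nearest-seed partitions agree
        seeds = np.zeros((64, 64), dtype=np.int32)
        seeds[32, 16] = 1
        seeds[32, 48] = 2
        mask = np.ones((64, 64), dtype=bool)
        cells = cells_propagation(LabelImage(seeds), np.ones((64, 64)),
                                  mask=mask, lam=1000.0)
        expect = brute_force_nearest_seed(seeds, np.inf)
        assert np.array_equal(cells.labels, expect)

    def test_lambda_zero_boundary_follows_ridge(self):
        # bright vertical ridge at x=20, seeds on either side; with lam=0 the
        # boundary must sit on the ridge crest, not the midline (x=32)
        h, w = 33, 65
        img = np.zeros((h, w))
        img[:, 20] = 1.0
        seeds = np.zeros((h, w), dtype=np.int32)
        seeds[16, 4] = 1
        seeds[16, 60] = 2
        cells = cells_propagation(LabelImage(seeds), img,
                                  mask=np.ones((h, w), bool), lam=0.0)
        assert np.all(cells.labels[:, :20] == 1)
        assert np.all(cells.labels[:, 21:] == 2)

    def test_pixel_conservation_and_containment(self):
        rng = np.random.default_rng(7)
        nuc = LabelImage(disc_labels((48, 48), [(14, 14, 4), (30, 32, 5)]))
        img = rng.random((48, 48))
        mask = np.ones((48, 48), bool)
        cells = cells_propagation(nuc, img, mask=mask, lam=0.5)
        assert (cells.labels > 0).sum() == mask.sum()
        keep = nuc.labels > 0
        assert np.array_equal(cells.labels[keep], nuc.labels[keep])
        assert cells.label_set == nuc.label_set


class TestBorderRemoval:
    def test_border_touching_cells_dropped_in_pairs(self):
        nuc = LabelImage(disc_labels((40, 40), [(3, 20, 3), (20, 20, 4)]))
        cells = cells_fixed_radius(nuc, 4.0)
        cells2, nuc2 = remove_border_cells(cells, nuc)
        assert 1 not in cells2.label_set
        assert cells2.label_set == nuc2.label_set == {2}


class TestDilateLabels:
    def test_grows_by_at_most_one_pixel(self):
        lab = disc_labels((32, 32), [(16, 16, 5)])
        grown = dilate_labels_one_pixel(lab)
        dist = ndimage.distance_transform_edt(lab == 0)
        added = (grown > 0) & (lab == 0)
        assert np.all(dist[added] <= np.sqrt(2) + 1e-9)
        # every background pixel within distance 1 was claimed
        assert np.all(grown[(dist <= 1.0) & (lab == 0)] > 0)
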