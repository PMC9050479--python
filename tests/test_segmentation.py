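"""Spectral PCA, difference-image masking, watershed, patch extraction."""

import numpy as np
import pytest
from sklearn.decomposition import PCA as SKPCA
from sklearn.metrics import roc_auc_score

from hsinuclei.cube_io import HyperCube, calibrate_transmittance
from hsinuclei.segmentation import (
    NucleiMask,
    difference_image,
    extract_patches,
    mask_nuclei,
    normalize_pc,
    orient_components,
    pca_spectral,
    segment_cube,
    split_touching,
)
from tests.conftest import make_two_region_cube


class TestPCASpectral:
    def test_rank_one_cube_pc1_explains_everything(self, rng):
        spectrum = rng.random(6) + 0.5
        coeff = rng.random((10, 10, 1)) * 2
        cube = HyperCube(coeff * spectrum, np.linspace(470, 720, 6), "transmittance")
        res = pca_spectral(cube)
        ratio = res.explained_variance / res.explained_variance.sum()
        assert ratio[0] > 1 - 1e-9

    def test_matches_covariance_eigendecomposition_oracle(self, small_cube):
        """Scores agree with an independent PCA (sklearn) to 1e-8, per-PC sign aside."""
        res = pca_spectral(small_cube, n_components=3)
        x = small_cube.data.reshape(-1, 5)
        ref = SKPCA(n_components=3, svd_solver="full").fit(x)
        ref_scores = ref.transform(x)
        for k in range(3):
            ours = res.scores.reshape(-1, 3)[:, k]
            sign = np.sign(np.dot(ours, ref_scores[:, k])) or 1.0
            np.testing.assert_allclose(ours, sign * ref_scores[:, k], atol=1e-8)
        np.testing.assert_allclose(res.explained_variance,
                                   ref.explained_variance_, rtol=1e-10)

    def test_two_region_cube_pc1_separates_regions(self):
        cube, truth = make_two_region_cube(seed=5)
        res = pca_spectral(cube)
        score = res.pc(1).ravel()
        auc = roc_auc_score(truth.ravel(), score)
        assert max(auc, 1 - auc) > 0.99

    def test_too_few_pixels_raise(self, rng):
        cube = HyperCube(rng.random((1, 2, 5)), [1, 2, 3, 4, 5])
        with pytest.raises(ValueError):
            pca_spectral(cube, n_components=3)


class TestNormalizePC:
    def test_linear_map(self):
        out = normalize_pc(np.array([[0.0, 5.0, 10.0]]))
        np.testing.assert_allclose(out.image, [[0.0, 0.5, 1.0]])
        assert not out.degenerate

    def test_constant_flags_degenerate(self):
        out = normalize_pc(np.full((4, 4), 3.3))
        np.testing.assert_array_equal(out.image, 0.0)
        assert out.degenerate

    def test_idempotent_on_normalized_input(self, rng):
        img = rng.random((6, 6))
        img.flat[0], img.flat[-1] = 0.0, 1.0
        np.testing.assert_allclose(normalize_pc(img).image, img)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            normalize_pc(np.array([[np.nan, 1.0]]))


def _oriented_diff(pca):
    o = orient_components(pca)
    return difference_image(normalize_pc(o.pc(1)), normalize_pc(o.pc(2)))


@pytest.fixture(scope="module")
def scene_pca(nuclei_scene):
    cal = calibrate_transmittance(nuclei_scene.raw, nuclei_scene.references)
    return pca_spectral(cal), nuclei_scene.truth_labels > 0


class TestOrientation:

    def test_nuclei_positive_in_difference(self, scene_pca):
        pca, nuc = scene_pca
        diff = _oriented_diff(pca)
        assert diff[nuc].mean() > 0
        frac = (diff > 0).mean()
        assert 0 < frac <= 0.5

    @pytest.mark.parametrize("flip", [(0,), (1,), (0, 1)])
    def test_sign_flips_restored(self, scene_pca, flip):
        pca, _ = scene_pca
        flipped_scores = pca.scores.copy()
        flipped_comps = pca.components.copy()
        for k in flip:
            flipped_scores[:, :, k] *= -1
            flipped_comps[k] *= -1
        from hsinuclei.segmentation import PCAResult

        pca_flipped = PCAResult(flipped_scores, pca.explained_variance.copy(),
                                flipped_comps, pca.mean.copy())
        base = mask_nuclei(_oriented_diff(pca))
        redo = mask_nuclei(_oriented_diff(pca_flipped))
        np.testing.assert_array_equal(base.binary, redo.binary)

    def test_all_background_cube_degenerate(self):
        lam = np.linspace(470, 720, 6)
        cube = HyperCube(np.full((16, 16, 6), 1.0)
                         + np.random.default_rng(0).normal(0, 1e-12, (16, 16, 6)),
                         lam, "transmittance")
        mask, diff, pca = segment_cube(cube)
        assert pca.degenerate or mask.n_nuclei == 0
        assert mask.n_nuclei == 0


class TestDifferenceImage:
    def test_equal_inputs_zero(self, rng):
        img = rng.random((5, 5))
        n = normalize_pc(img)
        np.testing.assert_array_equal(difference_image(n, n), 0.0)

    def test_extremes_give_ones(self):
        from hsinuclei.segmentation import NormalizedPC

        ones = NormalizedPC(np.ones((3, 3)))
        zeros = NormalizedPC(np.zeros((3, 3)))
        np.testing.assert_array_equal(difference_image(zeros, ones), 1.0)

    def test_two_region_fixture_signs(self):
        """Nucleus-like pixels positive, cytoplasm-like negative."""
        cube, truth = make_two_region_cube(seed=6)
        mask, diff, _ = segment_cube(cube, min_area=1, split=False)
        # one region strictly positive, the other strictly negative on average
        assert diff[truth].mean() * diff[~truth].mean() < 0

    def test_shape_mismatch_raises(self):
        a = normalize_pc(np.random.default_rng(0).random((4, 4)))
        b = normalize_pc(np.random.default_rng(0).random((5, 5)))
        with pytest.raises(ValueError):
            difference_image(a, b)


class TestMaskNuclei:
    def test_small_component_removed(self):
        diff = -np.ones((30, 60))
        diff[2:4, 2:5] = 1.0  # area 6
        diff[10:22, 10:22] = 1.0  # area 144
        mask = mask_nuclei(diff, min_area=50)
        assert mask.n_nuclei == 1
        assert mask.labels.max() == 1

    def test_all_negative_diff_empty(self):
        mask = mask_nuclei(-np.ones((10, 10)), min_area=5)
        assert mask.n_nuclei == 0
        assert not mask.binary.any()

    def test_disjoint_nuclei_centroids_recovered(self):
        rng = np.random.default_rng(3)
        diff = -np.ones((220, 220))
        centers = [(r * 52 + 30, c * 52 + 30) for r in range(4) for c in range(3)]
        yy, xx = np.mgrid[0:220, 0:220]
        for (r, c) in centers:
            diff[(yy - r) ** 2 + (xx - c) ** 2 <= 81] = 1.0
        mask = mask_nuclei(diff, min_area=50)
        assert mask.n_nuclei == len(centers)
        got = sorted(map(tuple, np.rint(mask.centroids).astype(int).tolist()))
        for (gr, gc), (tr, tc) in zip(got, sorted(centers)):
            assert abs(gr - tr) <= 2 and abs(gc - tc) <= 2

    def test_strictly_greater_threshold(self):
        diff = np.zeros((20, 20))
        diff[5:15, 5:15] = 0.0  # exactly at threshold -> excluded
        assert mask_nuclei(diff, threshold=0.0, min_area=1).n_nuclei == 0


def disc_diff(centers, radius, shape=(120, 160)):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    diff = -np.ones(shape)
    for (r, c) in centers:
        diff[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = 0.5
    return diff


class TestSplitTouching:
    def test_two_overlapping_discs_split(self):
        r = 14
        diff = disc_diff([(60, 60), (60, 60 + int(1.2 * r))], r)
        mask = mask_nuclei(diff, min_area=100)
        assert mask.n_nuclei == 1  # merged before splitting
        out = split_touching(mask, diff, min_area=100)
        assert out.n_nuclei == 2

    def test_isolated_disc_unchanged(self):
        diff = disc_diff([(60, 80)], 14)
        mask = mask_nuclei(diff, min_area=100)
        out = split_touching(mask, diff, min_area=100)
        assert out.n_nuclei == 1
        np.testing.assert_array_equal(out.binary, mask.binary)

    def test_three_lobed_blob_split_into_three(self):
        r = 13
        sep = int(1.6 * r)  # three clearly lobed, pairwise-touching discs
        diff = disc_diff([(60, 40), (60, 40 + sep), (60, 40 + 2 * sep)], r)
        mask = mask_nuclei(diff, min_area=100)
        assert mask.n_nuclei == 1
        out = split_touching(mask, diff, min_area=100)
        assert out.n_nuclei == 3

    def test_empty_mask_passthrough(self):
        mask = mask_nuclei(-np.ones((20, 20)))
        out = split_touching(mask, min_area=10)
        assert out.n_nuclei == 0


class TestExtractPatches:
    @staticmethod
    def _mask_at(centroids, shape):
        labels = np.zeros(shape, dtype=int)
        for i, (r, c) in enumerate(centroids, start=1):
            labels[int(r) - 2:int(r) + 3, int(c) - 2:int(c) + 3] = i
        return NucleiMask(labels > 0, labels, np.array(centroids, dtype=float))

    def test_boundary_touching_window(self, rng):
        cube = HyperCube(rng.random((200, 200, 5)), [1, 2, 3, 4, 5], "transmittance")
        rgb = rng.random((200, 200, 3))
        mask = self._mask_at([(50.0, 50.0)], (200, 200))
        recs = extract_patches(cube, rgb, mask, size=101)
        assert len(recs) == 1
        np.testing.assert_array_equal(recs[0].hsi_patch, cube.data[0:101, 0:101, :])

    def test_near_edge_centroid_dropped(self, rng):
        cube = HyperCube(rng.random((200, 200, 5)), [1, 2, 3, 4, 5], "transmittance")
        rgb = rng.random((200, 200, 3))
        mask = self._mask_at([(10.0, 100.0)], (200, 200))
        assert extract_patches(cube, rgb, mask, size=101) == []

    def test_margin_overlap_dropped(self, rng):
        cube = HyperCube(rng.random((200, 200, 5)), [1, 2, 3, 4, 5], "transmittance")
        rgb = rng.random((200, 200, 3))
        margin = np.zeros((200, 200), dtype=bool)
        margin[:, 0:55] = True  # registration fill at the left edge
        mask = self._mask_at([(100.0, 100.0), (100.0, 140.0)], (200, 200))
        recs = extract_patches(cube, rgb, mask, margin_mask=margin, size=101)
        assert [r.centroid for r in recs] == [(100.0, 140.0)]

    def test_even_size_rejected(self, rng):
        cube = HyperCube(rng.random((50, 50, 5)), [1, 2, 3, 4, 5], "transmittance")
        with pytest.raises(ValueError):
            extract_patches(cube, rng.random((50, 50, 3)),
                            self._mask_at([(25.0, 25.0)], (50, 50)), size=100)

    def test_mask_patch_isolates_single_nucleus(self, rng):
        cube = HyperCube(rng.random((200, 200, 5)), [1, 2, 3, 4, 5], "transmittance")
        rgb = rng.random((200, 200, 3))
        mask = self._mask_at([(90.0, 90.0), (90.0, 120.0)], (200, 200))
        recs = extract_patches(cube, rgb, mask, size=101)
        for rec in recs:
            assert rec.mask_patch.sum() == 25  # only its own 5x5 blob


def test_focus_filter_drops_blurred_records(rng):
    """Sharp nucleus patches pass the Laplacian-variance filter; heavily
    defocused copies of the same patches do not."""
    from scipy import ndimage as ndi

    from hsinuclei.segmentation import NucleusRecord, focus_filter

    sharp = np.zeros((31, 31, 4))
    sharp[10:20, 10:20, :] = 1.0
    sharp += rng.normal(0, 0.01, sharp.shape)
    blurred = ndi.gaussian_filter(sharp, sigma=(6, 6, 0))

    def rec(patch):
        return NucleusRecord(centroid=(15.0, 15.0), hsi_patch=patch,
                             rgb_patch=patch[:, :, :3],
                             mask_patch=np.ones((31, 31), bool))

    kept = focus_filter([rec(sharp), rec(blurred)], min_sharpness=1e-3)
    assert len(kept) == 1
    np.testing.assert_array_equal(kept[0].hsi_patch, sharp)


def test_lymphocyte_scale_objects_never_masked(nuclei_scene):
    """Distractors below the area floor are absent from the final mask."""
    cal = calibrate_transmittance(nuclei_scene.raw, nuclei_scene.references)
    mask, _, _ = segment_cube(cal)
    if len(nuclei_scene.lymphocyte_centroids) == 0 or mask.n_nuclei == 0:
        pytest.skip("fixture rendered no distractors")
    from scipy.spatial import cKDTree

    d, _ = cKDTree(mask.centroids).query(nuclei_scene.lymphocyte_centroids)
    assert (d > 5).all()
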