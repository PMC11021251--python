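"""Low-level operator tests against brute-force oracles on small grids."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter1d

from neoseg import imageops
from neoseg.types import DegenerateInputError, InvalidArgumentError, Volume

import oracles


# ---------------------------------------------------------------------------
# spherical elements
# ---------------------------------------------------------------------------

class TestSphericalElement:
    def test_subvoxel_radius_is_origin_only(self):
        e = imageops.spherical_element(0.5, (1, 1, 1))
        assert e.shape == (1, 1, 1) and e.all()

    def test_unit_radius_is_six_neighbourhood_cross(self):
        e = imageops.spherical_element(1.0, (1, 1, 1))
        assert e.sum() == 7
        assert e[1, 1, 1] and e[0, 1, 1] and e[1, 0, 1] and e[1, 1, 0]
        assert not e[0, 0, 0]

    def test_anisotropic_count_matches_enumeration(self):
        r, sp = 4.0, (0.63, 0.63, 0.63)
        e = imageops.spherical_element(r, sp)
        count = 0
        for i in range(-7, 8):
            for j in range(-7, 8):
                for k in range(-7, 8):
                    if (i * sp[0]) ** 2 + (j * sp[1]) ** 2 + (k * sp[2]) ** 2 <= r * r + 1e-9:
                        count += 1
        assert e.sum() == count

    def test_symmetric_and_monotone_in_radius(self):
        prev = 0
        for r in (0.5, 1.0, 1.7, 2.3, 3.1):
            e = imageops.spherical_element(r, (1.0, 0.8, 1.2))
            assert np.array_equal(e, e[::-1, ::-1, ::-1])
            assert e.sum() >= prev
            prev = e.sum()

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            imageops.spherical_element(0.0, (1, 1, 1))
        with pytest.raises(InvalidArgumentError):
            imageops.spherical_element(1.0, (1, -1, 1))


# ---------------------------------------------------------------------------
# derivative filters
# ---------------------------------------------------------------------------

class TestDerivativeFilters:
    def _plane_volume(self, side_a, stripe, side_b):
        # slightly asymmetric flanks so the stripe has nonzero gradient
        # (a perfectly symmetric stripe center is the locally-uniform case
        # and maps to 0 by convention)
        data = np.empty((9, 9, 9))
        data[:4] = side_a
        data[4] = stripe
        data[5:] = side_b
        return Volume(data=data)

    def test_constant_volume_gives_zero(self):
        v = Volume(data=np.full((6, 6, 6), 5.0))
        assert np.all(imageops.directional_second_derivative(v, 1.0).data == 0)
        # discrete Gaussian-derivative kernels carry a ~0.1% truncation
        # residual on constants
        assert np.allclose(imageops.laplacian_of_gaussian(v, 1.0).data, 0, atol=0.01)

    @pytest.mark.parametrize(
        "side_a,stripe,side_b,sign",
        [(100.0, 40.0, 80.0, 1), (40.0, 100.0, 60.0, -1)],
    )
    def test_plane_sign_matches_1d_oracle(self, side_a, stripe, side_b, sign):
        v = self._plane_volume(side_a, stripe, side_b)
        d2 = imageops.directional_second_derivative(v, 1.0).data
        profile = np.empty(9)
        profile[:4] = side_a
        profile[4] = stripe
        profile[5:] = side_b
        oracle = gaussian_filter1d(profile, 1.0, order=2)
        assert np.sign(oracle[4]) == sign
        assert np.all(np.sign(d2[4, 2:7, 2:7]) == sign)

    def test_inversion_negates_response(self):
        rng = np.random.default_rng(0)
        data = rng.random((8, 8, 8)) * 50 + 20
        v = Volume(data=data)
        d2 = imageops.directional_second_derivative(v, 1.0).data
        d2_inv = imageops.directional_second_derivative(v.with_data(-data), 1.0).data
        nz = d2 != 0
        assert np.allclose(d2[nz], -d2_inv[nz], rtol=1e-6, atol=1e-9)

    @pytest.mark.parametrize("delta,sign", [(-50.0, 1), (50.0, -1)])
    def test_log_single_voxel_sign(self, delta, sign):
        data = np.full((9, 9, 9), 60.0)
        data[4, 4, 4] += delta
        log = imageops.laplacian_of_gaussian(Volume(data=data), 1.0).data
        assert np.sign(log[4, 4, 4]) == sign


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

class TestComponents:
    def test_empty_mask_has_no_components(self):
        labels, sizes = imageops.connected_components(np.zeros((4, 4, 4), bool))
        assert sizes == [] and not labels.any()

    def test_two_cubes_sizes(self):
        m = np.zeros((10, 10, 10), bool)
        m[0:2, 0:2, 0:2] = True
        m[5:8, 5:8, 5:8] = True
        _, sizes = imageops.connected_components(m, 26)
        assert sorted(sizes) == [8, 27]

    def test_corner_touching_cubes_connectivity(self):
        m = np.zeros((6, 6, 6), bool)
        m[0:2, 0:2, 0:2] = True
        m[2:4, 2:4, 2:4] = True
        _, s26 = imageops.connected_components(m, 26)
        _, s6 = imageops.connected_components(m, 6)
        assert len(s26) == 1 and len(s6) == 2

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(10):
            m = rng.random((7, 7, 7)) < 0.3
            for conn in (6, 26):
                _, sizes = imageops.connected_components(m, conn)
                _, osizes = oracles.flood_components(m, conn)
                assert sorted(sizes) == sorted(osizes)

    def test_largest_component_and_tie_break(self):
        m = np.zeros((10, 10, 10), bool)
        m[0:2, 0:5, 0:1] = True   # 10 voxels
        m[5:6, 5:10, 5:6] = True  # 5 voxels
        out = imageops.largest_component(m)
        assert out.sum() == 10 and out[0, 0, 0]
        # equal sizes: the component whose first voxel comes first in scan
        # order wins
        m2 = np.zeros((8, 8, 8), bool)
        m2[0:2, 0:2, 0:2] = True
        m2[5:7, 5:7, 5:7] = True
        out2 = imageops.largest_component(m2)
        assert out2[0, 0, 0] and not out2[5, 5, 5]

    def test_single_component_unchanged(self):
        m = np.zeros((5, 5, 5), bool)
        m[1:4, 1:4, 1:4] = True
        assert np.array_equal(imageops.largest_component(m), m)


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

class TestMorphology:
    def test_opening_keeps_large_ball_removes_speck(self):
        xx, yy, zz = np.meshgrid(*[np.arange(15)] * 3, indexing="ij")
        m = (xx - 7) ** 2 + (yy - 7) ** 2 + (zz - 7) ** 2 <= 36
        el = imageops.spherical_element(2.0, (1, 1, 1))
        opened = imageops.binary_opening(m, el)
        # interior preserved
        interior = (xx - 7) ** 2 + (yy - 7) ** 2 + (zz - 7) ** 2 <= 9
        assert np.all(opened[interior])
        speck = np.zeros((9, 9, 9), bool)
        speck[4, 4, 4] = True
        assert not imageops.binary_opening(speck, el).any()

    def test_closing_bridges_one_voxel_gap(self):
        m = np.zeros((9, 9, 9), bool)
        m[1:4, 2:7, 2:7] = True
        m[5:8, 2:7, 2:7] = True
        el = imageops.spherical_element(1.0, (1, 1, 1))
        closed = imageops.binary_closing(m, el)
        # oracle: dilate then erode with explicit offsets on a padded grid
        pad = np.pad(m, 1)
        o = oracles.erode(oracles.dilate(pad, el), el)[1:-1, 1:-1, 1:-1]
        assert np.array_equal(closed, o)
        assert closed[4, 4, 4]

    def test_matches_offset_oracle_on_random_masks(self, rng):
        el = imageops.spherical_element(1.5, (1, 1, 1))
        for _ in range(5):
            m = rng.random((6, 6, 6)) < 0.4
            assert np.array_equal(imageops.binary_dilate(m, el), oracles.dilate(m, el))
            assert np.array_equal(imageops.binary_erode(m, el), oracles.erode(m, el))

    def test_ball_morphology_equals_footprint_morphology(self, rng):
        sp = (1.0, 0.8, 1.2)
        for r in (1.0, 2.4):
            el = imageops.spherical_element(r, sp)
            for _ in range(3):
                m = rng.random((8, 8, 8)) < 0.4
                assert np.array_equal(
                    imageops.dilate_ball(m, r, sp), imageops.binary_dilate(m, el)
                )
                assert np.array_equal(
                    imageops.erode_ball(m, r, sp), imageops.binary_erode(m, el)
                )
                assert np.array_equal(
                    imageops.close_ball(m, r, sp), imageops.binary_closing(m, el)
                )

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_open_subset_mask_subset_close(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((7, 7, 7)) < 0.35
        el = imageops.spherical_element(1.0 + 2 * rng.random(), (1, 1, 1))
        opened = imageops.binary_opening(m, el)
        closed = imageops.binary_closing(m, el)
        assert np.all(opened <= m)
        assert np.all(m <= closed)

    def test_iterations_variant_uses_unit_cross(self):
        m = np.zeros((9, 9, 9), bool)
        m[4, 4, 4] = True
        d2 = imageops.binary_dilate(m, iterations=2)
        # two iterations of the 6-neighbourhood: L1 ball of radius 2
        xx, yy, zz = np.meshgrid(*[np.arange(9)] * 3, indexing="ij")
        assert np.array_equal(d2, np.abs(xx - 4) + np.abs(yy - 4) + np.abs(zz - 4) <= 2)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

class TestDistances:
    def test_chessboard_examples(self):
        m = np.zeros((7, 7, 7), bool)
        m[3, 3, 3] = True
        d = imageops.chessboard_distance(m)
        assert d[3, 3, 3] == 0
        assert d[4, 4, 4] == 1  # diagonal neighbour
        assert d[6, 5, 4] == 3  # offset (3, 2, 1)

    def test_euclidean_examples(self):
        m = np.zeros((7, 7, 7), bool)
        m[3, 3, 3] = True
        d = imageops.euclidean_distance(m, (0.63, 0.63, 0.63))
        assert d[3, 3, 3] == 0
        assert np.isclose(d[5, 3, 3], 1.26)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(5):
            m = rng.random((6, 6, 6)) < 0.1
            if not m.any():
                m[0, 0, 0] = True
            assert np.array_equal(imageops.chessboard_distance(m), oracles.chessboard(m))
            sp = (1.0, 0.7, 1.3)
            assert np.allclose(
                imageops.euclidean_distance(m, sp), oracles.euclidean(m, sp), atol=1e-9
            )

    def test_empty_mask_is_an_error(self):
        with pytest.raises(InvalidArgumentError):
            imageops.chessboard_distance(np.zeros((3, 3, 3), bool))


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

class TestKMeans:
    def test_separated_modes_recovered_exactly(self, rng):
        modes = [10, 40, 70, 100]
        values = np.concatenate([rng.normal(m, 1.0, 200) for m in modes])
        truth = np.repeat(np.arange(4), 200)
        got = imageops.kmeans_intensity(values, k=4, seed=0)
        assert np.array_equal(got, truth)

    def test_two_values_two_classes(self):
        got = imageops.kmeans_intensity([5.0, 50.0], k=2, seed=0)
        assert list(got) == [0, 1]

    def test_identical_values_raise(self):
        with pytest.raises(DegenerateInputError):
            imageops.kmeans_intensity([3.0] * 10, k=2, seed=0)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_order_and_shift_invariance(self, seed):
        rng = np.random.default_rng(seed)
        values = np.concatenate([rng.normal(m, 2.0, 50) for m in (0, 30, 80)])
        base = imageops.kmeans_intensity(values, k=3, seed=0)
        perm = rng.permutation(len(values))
        permuted = imageops.kmeans_intensity(values[perm], k=3, seed=0)
        assert np.array_equal(base[perm], permuted)
        shifted = imageops.kmeans_intensity(values + 123.4, k=3, seed=0)
        assert np.array_equal(base, shifted)


# ---------------------------------------------------------------------------
# convex hull
# ---------------------------------------------------------------------------

class TestConvexHull:
    def test_empty_and_superset(self, rng):
        assert not imageops.convex_hull_mask(np.zeros((4, 4, 4), bool)).any()
        m = rng.random((6, 6, 6)) < 0.2
        assert np.all(m <= imageops.convex_hull_mask(m))

    def test_c_shape_cavity_filled(self):
        m = np.zeros((8, 8, 8), bool)
        m[1:7, 1:7, 1:7] = True
        m[3:5, 3:7, 3:5] = False  # carve a cavity opening to one face
        hull = imageops.convex_hull_mask(m)
        # half-space oracle: every carved voxel lies between mask voxels
        assert np.all(hull[3:5, 3:7, 3:5])

    def test_solid_ball_nearly_unchanged(self):
        xx, yy, zz = np.meshgrid(*[np.arange(11)] * 3, indexing="ij")
        ball = (xx - 5) ** 2 + (yy - 5) ** 2 + (zz - 5) ** 2 <= 16
        hull = imageops.convex_hull_mask(ball)
        assert np.all(ball <= hull)
        # discretisation may add only a thin boundary shell
        added = hull & ~ball
        assert ((xx[added] - 5) ** 2 + (yy[added] - 5) ** 2 + (zz[added] - 5) ** 2 <= 30).all()


# ---------------------------------------------------------------------------
# edge detection
# ---------------------------------------------------------------------------

class TestEdgeMask:
    def test_constant_volume_has_no_edges(self):
        v = Volume(data=np.full((8, 8, 8), 7.0))
        assert not imageops.edge_mask(v, 0.1, 0.2, 1.0).any()

    def test_sharp_step_detected_as_plane(self):
        data = np.full((12, 12, 12), 10.0)
        data[6:, :, :] = 100.0
        v = Volume(data=data)
        edges = imageops.edge_mask(v, 5.0, 15.0, 1.0)
        assert edges.any()
        # edge voxels lie on the step plane: x in {5, 6}
        xs = np.unique(np.argwhere(edges)[:, 0])
        assert set(xs) <= {5, 6}
        # 1-D oracle: gradient maximum of the smoothed profile is at the step
        prof = np.full(12, 10.0)
        prof[6:] = 100.0
        g = np.abs(gaussian_filter1d(prof, 1.0, order=1))
        assert g.argmax() in (5, 6)

    def test_step_below_low_threshold_ignored(self):
        data = np.full((10, 10, 10), 10.0)
        data[5:, :, :] = 12.0
        v = Volume(data=data)
        assert not imageops.edge_mask(v, 5.0, 15.0, 1.0).any()


# ---------------------------------------------------------------------------
# perimeter scoring
# ---------------------------------------------------------------------------

class TestPerimeterFraction:
    def test_hand_counted_small_component(self):
        comp = np.zeros((5, 5, 5), bool)
        comp[2, 2, 2] = True
        ref = np.zeros((5, 5, 5), bool)
        ref[1, 2, 2] = True
        ref[3, 2, 2] = True
        # perimeter = 6 face neighbours, 2 in ref
        assert imageops.component_perimeter_fraction(comp, ref) == pytest.approx(2 / 6)

    def test_matches_oracle_on_random_masks(self, rng):
        for _ in range(10):
            comp = rng.random((6, 6, 6)) < 0.3
            ref = rng.random((6, 6, 6)) < 0.4
            if not comp.any():
                comp[2, 2, 2] = True
            assert imageops.component_perimeter_fraction(comp, ref) == pytest.approx(
                oracles.perimeter_fraction(comp, ref)
            )
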