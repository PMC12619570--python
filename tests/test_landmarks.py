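import numpy as np
import pytest
from hypothesis import given, strategies as st

from vesselvpop import (Centerline, LandmarkSet, ShapeVector, build_population,
                        from_shape_vector, resample_equal_arclength,
                        to_shape_vector)
from vesselvpop.errors import ParameterError
from vesselvpop.landmarks import arc_lengths

from conftest import random_centerline


class TestResample:
    def test_equal_arc_stations_on_a_line(self):
        c = Centerline(points=[[0, 0, 0], [1, 0, 0], [3, 0, 0]], radii=[1, 1, 1])
        l = resample_equal_arclength(c, 3)
        np.testing.assert_allclose(l.positions,
                                   [[0, 0, 0], [1.5, 0, 0], [3, 0, 0]], atol=1e-12)
        np.testing.assert_allclose(l.radii, 1.0)

    def test_k2_returns_exact_endpoints(self):
        rng = np.random.default_rng(3)
        c = random_centerline(rng, 17)
        l = resample_equal_arclength(c, 2)
        np.testing.assert_array_equal(l.positions[0], c.points[0])
        np.testing.assert_array_equal(l.positions[-1], c.points[-1])

    def test_semicircle_quartile_stations(self, semicircle_dense):
        # oracle: dense cumulative arc-length summation gives the target stations
        l = resample_equal_arclength(semicircle_dense, 5)
        s_dense = arc_lengths(semicircle_dense.points)
        L = s_dense[-1]
        for j, lm in enumerate(l.positions):
            target = j * L / 4
            idx = np.searchsorted(s_dense, target)
            idx = min(idx, len(s_dense) - 1)
            assert np.linalg.norm(lm - semicircle_dense.points[idx]) < 1e-3 * L

    def test_k_below_2_rejected(self, straight_centerline):
        with pytest.raises(ParameterError):
            resample_equal_arclength(straight_centerline, 1)

    def test_equal_spacing_within_tolerance(self, ica_pop_30):
        l = resample_equal_arclength(ica_pop_30[0], 40)
        gaps = np.linalg.norm(np.diff(l.positions, axis=0), axis=1)
        s = arc_lengths(l.positions)
        # chords of equal-arc stations on a smooth-ish curve are near-equal
        assert gaps.std() / gaps.mean() < 0.2

    def test_idempotent_on_equal_chord_polylines(self, straight_centerline):
        # exact idempotence holds when the polyline has equal chords (then
        # equal-arc stations coincide with the vertices); general curves shift
        # interior points by the chord-length variation
        theta = np.linspace(0, np.pi, 25)
        arc = Centerline(
            points=np.column_stack([10 * np.cos(theta), 10 * np.sin(theta),
                                    np.zeros(25)]),
            radii=np.full(25, 2.0),
        )
        for c, k in ((arc, 25), (straight_centerline, 11)):
            l1 = resample_equal_arclength(c, k)
            np.testing.assert_allclose(l1.positions, c.points, atol=1e-9)
            as_curve = Centerline(points=l1.positions, radii=l1.radii)
            l2 = resample_equal_arclength(as_curve, k)
            np.testing.assert_allclose(l2.landmarks, l1.landmarks, atol=1e-9)

    def test_chord_shortening_and_convergence(self, semicircle_dense):
        L = arc_lengths(semicircle_dense.points)[-1]
        lengths = []
        for k in (5, 20, 80):
            l = resample_equal_arclength(semicircle_dense, k)
            lk = arc_lengths(l.positions)[-1]
            assert lk <= L + 1e-12
            lengths.append(lk)
        assert lengths == sorted(lengths)
        assert L - lengths[-1] < 0.01 * L


class TestShapeVector:
    def test_block_ordering(self):
        l = LandmarkSet(landmarks=[[0, 0, 0, 1], [1, 2, 3, 4]])
        np.testing.assert_array_equal(to_shape_vector(l).values,
                                      [0, 1, 0, 2, 0, 3, 1, 4])

    def test_inverse_mapping(self):
        l = from_shape_vector(np.array([0.0, 1, 0, 2, 0, 3, 1, 4]))
        np.testing.assert_array_equal(l.landmarks, [[0, 0, 0, 1], [1, 2, 3, 4]])

    @given(seed=st.integers(0, 5_000))
    def test_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        l = LandmarkSet(landmarks=rng.normal(size=(int(rng.integers(2, 12)), 4)))
        assert from_shape_vector(to_shape_vector(l)) == l

    def test_length_not_divisible_by_four_rejected(self):
        with pytest.raises(ParameterError):
            from_shape_vector(np.zeros(10))

    def test_k1_rejected(self):
        with pytest.raises(ParameterError):
            from_shape_vector(np.zeros(4))

    def test_declared_k_must_match_values(self):
        with pytest.raises(ParameterError):
            ShapeVector(values=np.zeros(8), k=3)


class TestPopulation:
    def test_identical_sets_give_identical_rows(self):
        l = LandmarkSet(landmarks=[[0, 0, 0, 1], [1, 2, 3, 4]])
        P = build_population([l, l, l])
        assert P.n == 3 and P.k == 2
        assert np.all(P.matrix == P.matrix[0])

    def test_mixed_k_rejected(self):
        l5 = LandmarkSet(landmarks=np.zeros((5, 4)) + np.arange(5)[:, None])
        l6 = LandmarkSet(landmarks=np.zeros((6, 4)) + np.arange(6)[:, None])
        with pytest.raises(ParameterError, match="mixed"):
            build_population([l5, l6])

    def test_empty_list_rejected(self):
        with pytest.raises(ParameterError):
            build_population([])

    def test_single_set_builds_n1_matrix(self):
        l = LandmarkSet(landmarks=[[0, 0, 0, 1], [1, 2, 3, 4]])
        assert build_population([l]).n == 1
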