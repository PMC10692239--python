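"""Frame construction and the 6D transform codec."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from domassembly.errors import GeometryError, ValidationError
from domassembly.frames import (AffineTransform, Transform6D, affine_from_6d,
                                build_frame, compose, euler_to_rotation,
                                invert, relative_transform,
                                rotation_to_euler, spherical_to_translation,
                                translation_to_spherical, wrap_angle)

from conftest import random_rotation


def brute_force_frame(n, ca, c):
    """Explicit Gram-Schmidt with projection formulas (independent path)."""
    x = (c - ca) / np.linalg.norm(c - ca)
    v = n - ca
    y = v - np.dot(v, x) * x
    y = y / np.linalg.norm(y)
    z = np.cross(x, y)
    return np.column_stack([x, y, z]), ca


class TestBuildFrame:
    def test_axis_aligned_construction_gives_identity(self):
        f = build_frame(np.array([-0.5, 1.4, 0.0]), np.zeros(3),
                        np.array([1.525, 0.0, 0.0]))
        assert np.allclose(f.R, np.eye(3), atol=1e-12)
        assert np.allclose(f.t, 0.0, atol=1e-12)

    def test_orthonormal_proper_rotation(self, rng):
        for _ in range(50):
            n, ca, c = rng.normal(size=(3, 3)) * 3.0
            f = build_frame(n, ca, c)
            assert np.allclose(f.R.T @ f.R, np.eye(3), atol=1e-9)
            assert abs(np.linalg.det(f.R) - 1.0) < 1e-9

    def test_matches_brute_force_gram_schmidt(self, rng):
        for _ in range(20):
            n, ca, c = rng.normal(size=(3, 3)) * 4.0
            f = build_frame(n, ca, c)
            R, t = brute_force_frame(n, ca, c)
            assert np.allclose(f.R, R, atol=1e-12)
            assert np.allclose(f.t, t, atol=1e-12)

    def test_collinear_atoms_rejected(self):
        with pytest.raises(GeometryError):
            build_frame(np.array([2.0, 0, 0]), np.zeros(3),
                        np.array([1.0, 0, 0]))


class TestEulerCodec:
    def test_zero_angles_identity(self):
        assert np.allclose(euler_to_rotation(0, 0, 0), np.eye(3))

    def test_single_axis_z_quarter_turn(self):
        expected = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0],
                             [0.0, 0.0, 1.0]])
        assert np.allclose(euler_to_rotation(0, 0, np.pi / 2), expected,
                           atol=1e-12)

    def test_matches_explicit_matrix_product(self, rng):
        def rx(a):
            return np.array([[1, 0, 0], [0, np.cos(a), -np.sin(a)],
                             [0, np.sin(a), np.cos(a)]])

        def ry(b):
            return np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0],
                             [-np.sin(b), 0, np.cos(b)]])

        def rz(g):
            return np.array([[np.cos(g), -np.sin(g), 0],
                             [np.sin(g), np.cos(g), 0], [0, 0, 1]])

        for _ in range(30):
            a, b, g = rng.uniform(-np.pi, np.pi, 3)
            assert np.allclose(euler_to_rotation(a, b, g),
                               rz(g) @ ry(b) @ rx(a), atol=1e-12)

    def test_round_trip_interior(self, rng):
        for _ in range(100):
            a, g = rng.uniform(-np.pi, np.pi, 2)
            b = rng.uniform(-np.pi / 2 + 1e-3, np.pi / 2 - 1e-3)
            R = euler_to_rotation(a, b, g)
            a2, b2, g2 = rotation_to_euler(R)
            assert np.allclose([a, b, g], [a2, b2, g2], atol=1e-9)

    def test_gimbal_lock_reconstructs_rotation(self, rng):
        for beta in (np.pi / 2, -np.pi / 2):
            for a in rng.uniform(-np.pi, np.pi, 5):
                R = euler_to_rotation(a, beta, 0.3)
                angles = rotation_to_euler(R)
                assert angles[0] == 0.0
                assert np.allclose(euler_to_rotation(*angles), R, atol=1e-9)

    def test_non_rotation_rejected(self):
        with pytest.raises(ValidationError):
            rotation_to_euler(np.diag([1.0, 1.0, 2.0]))
        with pytest.raises(ValidationError):
            rotation_to_euler(np.diag([1.0, 1.0, -1.0]))  # reflection


class TestSphericalCodec:
    @pytest.mark.parametrize("t, expected", [
        ((0, 0, 1), (1.0, 0.0, 0.0)),
        ((np.sqrt(2), np.sqrt(2), 0), (2.0, np.pi / 2, np.pi / 4)),
        ((0, 0, 0), (0.0, 0.0, 0.0)),
    ])
    def test_analytic_cases(self, t, expected):
        assert np.allclose(translation_to_spherical(np.array(t, float)),
                           expected, atol=1e-12)

    @pytest.mark.parametrize("rtp, expected", [
        ((0, 0.7, 1.2), (0, 0, 0)),
        ((1, 0, 2.5), (0, 0, 1)),
        ((2, np.pi / 2, np.pi / 4), (np.sqrt(2), np.sqrt(2), 0)),
    ])
    def test_inverse_analytic_cases(self, rtp, expected):
        assert np.allclose(spherical_to_translation(*rtp), expected,
                           atol=1e-12)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValidationError):
            spherical_to_translation(-1.0, 0.0, 0.0)

    def test_round_trip(self, rng):
        for _ in range(100):
            t = rng.normal(size=3) * 10
            r, th, ph = translation_to_spherical(t)
            assert np.allclose(spherical_to_translation(r, th, ph), t,
                               atol=1e-12)
            assert 0 <= th <= np.pi and -np.pi <= ph < np.pi


class TestRelativeTransform:
    def test_same_frame_is_zero(self, rng):
        n, ca, c = rng.normal(size=(3, 3)) * 3
        f = build_frame(n, ca, c)
        v = relative_transform(f, f)
        assert np.allclose(v.as_array(), 0.0, atol=1e-9)

    def test_pure_translation_along_z(self):
        f1 = AffineTransform.identity()
        f2 = AffineTransform(np.eye(3), np.array([0.0, 0.0, 5.0]))
        v = relative_transform(f1, f2)
        assert np.isclose(v.r, 5.0) and np.isclose(v.theta, 0.0)
        assert np.allclose([v.alpha, v.beta, v.gamma], 0.0)

    def test_matches_homogeneous_matrix_oracle(self, rng):
        for _ in range(20):
            fi = build_frame(*(rng.normal(size=(3, 3)) * 3))
            fj = build_frame(*(rng.normal(size=(3, 3)) * 3 + 5.0))
            v = relative_transform(fi, fj)
            rel = affine_from_6d(v)
            expected = np.linalg.inv(fi.matrix()) @ fj.matrix()
            assert np.allclose(rel.matrix(), expected, atol=1e-9)

    def test_r_equals_origin_distance(self, rng):
        for _ in range(20):
            pi, pj = rng.normal(size=(2, 3, 3)) * 4
            fi, fj = build_frame(*pi), build_frame(*pj)
            v = relative_transform(fi, fj)
            assert np.isclose(v.r, np.linalg.norm(pj[1] - pi[1]), atol=1e-9)


class TestComposeInvert:
    def test_inverse_composes_to_identity(self, rng):
        for _ in range(20):
            a = AffineTransform(random_rotation(rng), rng.normal(size=3) * 5)
            ai = compose(a, invert(a))
            assert np.allclose(ai.R, np.eye(3), atol=1e-12)
            assert np.allclose(ai.t, 0.0, atol=1e-12)

    def test_associativity_and_homogeneous_action(self, rng):
        for _ in range(20):
            a, b, c = (AffineTransform(random_rotation(rng),
                                       rng.normal(size=3) * 5)
                       for _ in range(3))
            left = compose(compose(a, b), c)
            right = compose(a, compose(b, c))
            assert np.allclose(left.matrix(), right.matrix(), atol=1e-12)
            p = rng.normal(size=3)
            hom = (a.matrix() @ np.append(p, 1.0))[:3]
            assert np.allclose(a.apply(p), hom, atol=1e-12)


class TestSixDCodec:
    def test_zero_vector_is_identity(self):
        t = affine_from_6d(Transform6D.zero())
        assert np.allclose(t.R, np.eye(3)) and np.allclose(t.t, 0.0)

    def test_matches_factor_product(self, rng):
        for _ in range(20):
            v = Transform6D(*rng.uniform(-np.pi, np.pi, 3),
                            rng.uniform(0, 30),
                            rng.uniform(0, np.pi),
                            rng.uniform(-np.pi, np.pi))
            t = affine_from_6d(v)
            R = euler_to_rotation(v.alpha, v.beta, v.gamma)
            tr = spherical_to_translation(v.r, v.theta, v.phi)
            assert np.allclose(t.R, R) and np.allclose(t.t, tr)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(st.tuples(
        st.floats(-np.pi + 1e-5, np.pi - 1e-5),
        st.floats(-np.pi / 2 + 1e-3, np.pi / 2 - 1e-3),
        st.floats(-np.pi + 1e-5, np.pi - 1e-5),
        st.floats(0.1, 39.0),
        st.floats(1e-3, np.pi - 1e-3),
        st.floats(-np.pi + 1e-5, np.pi - 1e-5)))
    def test_codec_bijective_on_interior(self, params):
        v = Transform6D(*params)
        t = affine_from_6d(v)
        a, b, g = rotation_to_euler(t.R)
        r, th, ph = translation_to_spherical(t.t)
        assert np.allclose([a, b, g, r, th, ph], v.as_array(), atol=1e-9)


def test_wrap_angle_range(rng):
    a = rng.uniform(-20, 20, 1000)
    w = wrap_angle(a)
    assert np.all((w >= -np.pi) & (w < np.pi))
    assert np.allclose(np.cos(w), np.cos(a))
    assert np.allclose(np.sin(w), np.sin(a))
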