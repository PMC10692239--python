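"""Local residue frames and the 6D transform codec.

Each residue gets an orthonormal local frame built from its N, CA and C
atoms by Gram-Schmidt: origin at CA, x along CA->C, y the component of
CA->N orthogonal to x, z = x cross y. Frames are stored as local->ground
affine transforms (R, t): a point with local coordinates p sits at
``R @ p + t`` in the ground (laboratory) frame.

The relative transform between two residues i, j is ``A_i^{-1} o A_j``. Its
rotation part is encoded as intrinsic Z-Y-X Euler angles (alpha about x
applied first, then beta about y, then gamma about z, i.e.
``R = Rz(gamma) @ Ry(beta) @ Rx(alpha)``) and its translation as spherical
coordinates (r, theta, phi). Together they form the 6D interaction vector
(alpha, beta, gamma, r, theta, phi). Because frame origins are CA atoms, r
always equals the CA-CA distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, ValidationError

TWO_PI = 2.0 * np.pi


def wrap_angle(a):
    """Wrap angle(s) to [-pi, pi)."""
    return np.mod(np.asarray(a, dtype=float) + np.pi, TWO_PI) - np.pi


@dataclass
class AffineTransform:
    """Rigid transform: rotation ``R`` (3x3) plus translation ``t`` (A)."""

    R: np.ndarray
    t: np.ndarray

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float).reshape(3, 3)
        self.t = np.asarray(self.t, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.R.T + self.t

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.R
        m[:3, 3] = self.t
        return m

    def validate(self, tol: float = 1e-6) -> "AffineTransform":
        if not np.allclose(self.R.T @ self.R, np.eye(3), atol=tol):
            raise ValidationError("R is not orthonormal")
        if abs(np.linalg.det(self.R) - 1.0) > tol:
            raise ValidationError("R is not a proper rotation")
        return self


@dataclass
class Transform6D:
    """(alpha, beta, gamma, r, theta, phi): Euler angles of the rotation and
    spherical coordinates of the translation. Angles in radians, r in A."""

    alpha: float
    beta: float
    gamma: float
    r: float
    theta: float
    phi: float

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma,
                         self.r, self.theta, self.phi])

    @classmethod
    def from_array(cls, v) -> "Transform6D":
        a, b, g, r, t, p = (float(x) for x in v)
        return cls(a, b, g, r, t, p)

    @classmethod
    def zero(cls) -> "Transform6D":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Frame construction


def build_frame(n, ca, c) -> AffineTransform:
    """Local->ground frame of one residue from its N, CA, C positions."""
    R, t = build_frames(np.asarray([n]), np.asarray([ca]), np.asarray([c]))
    return AffineTransform(R[0], t[0])


def build_frames(n: np.ndarray, ca: np.ndarray,
                 c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized frame construction; returns ``(R (n,3,3), t (n,3))``."""
    n = np.atleast_2d(np.asarray(n, dtype=float))
    ca = np.atleast_2d(np.asarray(ca, dtype=float))
    c = np.atleast_2d(np.asarray(c, dtype=float))
    x = c - ca
    nx = np.linalg.norm(x, axis=1, keepdims=True)
    if np.any(nx < 1e-9):
        raise GeometryError("CA and C coincide")
    x = x / nx
    v = n - ca
    y = v - np.sum(v * x, axis=1, keepdims=True) * x
    ny = np.linalg.norm(y, axis=1, keepdims=True)
    if np.any(ny < 1e-9):
        raise GeometryError("collinear N/CA/C: frame undefined")
    y = y / ny
    z = np.cross(x, y)
    R = np.stack([x, y, z], axis=2)  # columns are the axes
    return R, ca.copy()


def structure_frames(structure) -> tuple[np.ndarray, np.ndarray]:
    """Frames of every residue of a BackboneStructure."""
    return build_frames(structure.coords[:, 0], structure.coords[:, 1],
                        structure.coords[:, 2])


# ---------------------------------------------------------------------------
# Euler / spherical codecs


def euler_to_rotation(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """``R = Rz(gamma) @ Ry(beta) @ Rx(alpha)`` (leftmost applied last)."""
    return rotations_from_euler(np.array([[alpha, beta, gamma]]))[0]


def rotations_from_euler(abg: np.ndarray) -> np.ndarray:
    """Vectorized ZYX Euler -> rotation matrices; ``abg`` is ``(n, 3)``."""
    abg = np.atleast_2d(np.asarray(abg, dtype=float))
    ca, cb, cg = np.cos(abg[:, 0]), np.cos(abg[:, 1]), np.cos(abg[:, 2])
    sa, sb, sg = np.sin(abg[:, 0]), np.sin(abg[:, 1]), np.sin(abg[:, 2])
    R = np.empty((len(abg), 3, 3))
    R[:, 0, 0] = cb * cg
    R[:, 0, 1] = sa * sb * cg - ca * sg
    R[:, 0, 2] = ca * sb * cg + sa * sg
    R[:, 1, 0] = cb * sg
    R[:, 1, 1] = sa * sb * sg + ca * cg
    R[:, 1, 2] = ca * sb * sg - sa * cg
    R[:, 2, 0] = -sb
    R[:, 2, 1] = sa * cb
    R[:, 2, 2] = ca * cb
    return R


GIMBAL_EPS = 1e-8


def rotation_to_euler(R: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_rotation`.

    ``beta = asin(-R[2,0])`` under the ZYX factorization. At gimbal lock
    (|cos beta| < 1e-8) alpha is set to 0 and the residual rotation is
    absorbed into gamma; the returned triple still reconstructs R exactly
    even though the decomposition is not unique there.
    """
    a = eulers_from_rotations(np.asarray(R, dtype=float)[None])
    return float(a[0, 0]), float(a[0, 1]), float(a[0, 2])


def eulers_from_rotations(R: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Vectorized rotation -> ZYX Euler angles, ``(n, 3)``."""
    R = np.asarray(R, dtype=float)
    if R.ndim == 2:
        R = R[None]
    err = np.abs(np.einsum("nij,nik->njk", R, R) - np.eye(3)).max()
    det = np.linalg.det(R)
    if err > tol or np.any(np.abs(det - 1.0) > max(tol, 1e-6)):
        raise ValidationError("input is not a proper rotation matrix")
    out = np.empty((len(R), 3))
    sb = np.clip(-R[:, 2, 0], -1.0, 1.0)
    out[:, 1] = np.arcsin(sb)
    cb = np.cos(out[:, 1])
    regular = cb >= GIMBAL_EPS
    out[regular, 0] = np.arctan2(R[regular, 2, 1], R[regular, 2, 2])
    out[regular, 2] = np.arctan2(R[regular, 1, 0], R[regular, 0, 0])
    locked = ~regular
    # beta = +/- pi/2: only (alpha -+ gamma) is determined; take alpha = 0.
    out[locked, 0] = 0.0
    out[locked, 2] = np.arctan2(-R[locked, 0, 1], R[locked, 1, 1])
    return out


def translation_to_spherical(t) -> tuple[float, float, float]:
    """``(r, theta, phi)`` with theta the polar angle from +z and phi the
    azimuth; ``r = 0`` maps to ``(0, 0, 0)`` by convention."""
    t = np.asarray(t, dtype=float).reshape(3)
    r = float(np.linalg.norm(t))
    if r < 1e-12:
        return 0.0, 0.0, 0.0
    theta = float(np.arccos(np.clip(t[2] / r, -1.0, 1.0)))
    phi = float(np.arctan2(t[1], t[0]))
    if phi == np.pi:  # keep phi in [-pi, pi)
        phi = -np.pi
    return r, theta, phi


def spherical_to_translation(r: float, theta: float, phi: float) -> np.ndarray:
    """``t = (r sin(theta) cos(phi), r sin(theta) sin(phi), r cos(theta))``."""
    if r < 0:
        raise ValidationError("spherical radius must be non-negative")
    st = np.sin(theta)
    return np.array([r * st * np.cos(phi), r * st * np.sin(phi),
                     r * np.cos(theta)])


# ---------------------------------------------------------------------------
# Composition and the 6D codec


def compose(a: AffineTransform, b: AffineTransform) -> AffineTransform:
    """``(a o b)(p) = a(b(p))``."""
    return AffineTransform(a.R @ b.R, a.R @ b.t + a.t)


def invert(a: AffineTransform) -> AffineTransform:
    return AffineTransform(a.R.T, -a.R.T @ a.t)


def relative_transform(frame_i: AffineTransform,
                       frame_j: AffineTransform) -> Transform6D:
    """6D encoding of ``frame_i^{-1} o frame_j`` (residue-j local
    coordinates expressed in residue i's frame)."""
    rel = compose(invert(frame_i), frame_j)
    alpha, beta, gamma = rotation_to_euler(rel.R)
    r, theta, phi = translation_to_spherical(rel.t)
    return Transform6D(alpha, beta, gamma, r, theta, phi)


def affine_from_6d(v: Transform6D) -> AffineTransform:
    return AffineTransform(
        euler_to_rotation(v.alpha, v.beta, v.gamma),
        spherical_to_translation(v.r, v.theta, v.phi))


# ---------------------------------------------------------------------------
# Vectorized helpers used by the interaction and potential modules


def sixd_from_frame_pairs(Ri, ti, Rj, tj) -> np.ndarray:
    """6D vectors of ``A_i^{-1} o A_j`` for stacks of frames, ``(n, 6)``."""
    Rrel = np.einsum("nji,njk->nik", Ri, Rj)          # Ri^T @ Rj
    trel = np.einsum("nji,nj->ni", Ri, tj - ti)        # Ri^T (tj - ti)
    abg = eulers_from_rotations(Rrel)
    r = np.linalg.norm(trel, axis=1)
    safe = r > 1e-12
    theta = np.zeros_like(r)
    phi = np.zeros_like(r)
    theta[safe] = np.arccos(np.clip(trel[safe, 2] / r[safe], -1.0, 1.0))
    phi[safe] = np.arctan2(trel[safe, 1], trel[safe, 0])
    phi[phi == np.pi] = -np.pi
    return np.column_stack([abg, r, theta, phi])


def affines_from_6d(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 6D -> (R (n,3,3), t (n,3))."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    R = rotations_from_euler(values[:, :3])
    r, theta, phi = values[:, 3], values[:, 4], values[:, 5]
    st = np.sin(theta)
    t = np.column_stack([r * st * np.cos(phi), r * st * np.sin(phi),
                         r * np.cos(theta)])
    return R, t
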