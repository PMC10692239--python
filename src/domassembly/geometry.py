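"""Internal-coordinate helpers: dihedrals, axis rotations and NeRF atom
placement (natural extension of reference frame), shared by the kinematics
and synthetic modules."""

from __future__ import annotations

import numpy as np

from .errors import GeometryError


def dihedral(a, b, c, d) -> float:
    """Signed dihedral angle a-b-c-d in radians, IUPAC sign convention."""
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b0 = a - b
    b1 = c - b
    b2 = d - c
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    return float(np.arctan2(np.cross(b1, v) @ w, v @ w))


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise GeometryError("zero-length rotation axis")
    x, y, z = axis / n
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def place_atom(a, b, c, bond: float, angle: float, torsion: float
               ) -> np.ndarray:
    """Place atom d given three predecessors so that |cd| = bond, the angle
    b-c-d equals ``angle`` and the dihedral a-b-c-d equals ``torsion``
    (radians). The standard NeRF construction."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < 1e-9:
        raise GeometryError("coincident atoms b and c")
    bc = bc / nbc
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise GeometryError("collinear a, b, c: torsion undefined")
    n = n / nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
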