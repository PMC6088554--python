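"""Low-level vector geometry: torsions, internal-coordinate atom placement, rotations.

All angles are degrees at the API surface (Ramachandran convention,
wrapped to (-180, 180]); radians internally.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "angular_difference",
    "dihedral",
    "place_atom",
    "rotation_about_axis",
    "random_rotation_matrix",
]


def wrap_angle(angle_deg):
    """Wrap angle(s) in degrees onto (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0
    return wrapped if wrapped.ndim else float(wrapped)


def angular_difference(a_deg, b_deg):
    """Smallest absolute difference between two angles on the circle, degrees in [0, 180]."""
    d = np.abs(np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 360.0
    out = np.where(d > 180.0, 360.0 - d, d)
    return out if out.ndim else float(out)


def dihedral(p0, p1, p2, p3):
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention.

    Zero for the cis (eclipsed) arrangement, positive for a clockwise rotation
    of the far bond when sighting down p1->p2. Matches Bio.PDB.calc_dihedral.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 == 0.0:
        raise ValueError("degenerate dihedral: central bond has zero length")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond_length, bond_angle_deg, torsion_deg):
    """Place atom D given three predecessors via internal coordinates (NeRF).

    D is at distance ``bond_length`` from ``c``, with angle b-c-D equal to
    ``bond_angle_deg`` and torsion a-b-c-D equal to ``torsion_deg``.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(bond_angle_deg)
    chi = np.radians(torsion_deg)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        # a, b, c collinear: torsion reference plane undefined; pick any normal
        n = np.cross(bc, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(n) < 1e-12:
            n = np.cross(bc, np.array([0.0, 1.0, 0.0]))
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def rotation_about_axis(origin, axis, angle_deg):
    """Return (R, t) for rotation by angle about a line through ``origin`` along ``axis``.

    Apply as ``x @ R.T + t`` for row-vector coordinate arrays.
    """
    origin = np.asarray(origin, dtype=float)
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("rotation axis has zero length")
    k = axis / n
    th = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1.0 - np.cos(th)) * (K @ K)
    t = origin - origin @ R.T
    return R, t


def random_rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via the quaternion method."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
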