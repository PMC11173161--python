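"""Vector geometry for residue-pair orientation features.

All angles are in radians. Dihedral signs follow the right-hand rule
(IUPAC convention); planar angles lie in [0, pi].
"""

from __future__ import annotations

import numpy as np

# Ideal internal coordinates for a virtual beta carbon, placed off the
# N/CA/C frame: bond CA-CB 1.522 A, angle N-CA-CB 110.4 deg, dihedral
# C-N-CA-CB -122.8 deg.
VIRTUAL_CB_BOND = 1.522
VIRTUAL_CB_ANGLE = 1.927  # rad
VIRTUAL_CB_DIHEDRAL = -2.143  # rad


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Planar angle between two vectors, in [0, pi]. Degenerate input -> 0."""
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return 0.0
    c = np.dot(v1, v2) / (n1 * n2)
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def planar_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Angle at vertex p2 formed by p1-p2-p3, in [0, pi]."""
    return angle_between(p1 - p2, p3 - p2)


def dihedral(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed dihedral angle p1-p2-p3-p4 in (-pi, pi].

    Returns 0.0 when any of the frame vectors degenerates to zero length.
    """
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12 or nb2 < 1e-12:
        return 0.0
    m1 = np.cross(n1, b2 / nb2)
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.arctan2(y, x))
    if ang <= -np.pi:  # normalize -pi to +pi
        ang = np.pi
    return ang


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle: float,
    torsion: float,
) -> np.ndarray:
    """Place atom d from internal coordinates relative to the a-b-c frame.

    The new atom sits at distance ``bond`` from c, with angle(b, c, d) =
    ``angle`` and dihedral(a, b, c, d) = ``torsion`` (NeRF construction).
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m - d_local[2] * n


def virtual_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal-geometry beta-carbon position from backbone N, CA, C."""
    return place_atom(c, n, ca, VIRTUAL_CB_BOND, VIRTUAL_CB_ANGLE, VIRTUAL_CB_DIHEDRAL)


def rotation_matrix(axis: np.ndarray, theta: float) -> np.ndarray:
    """Rotation matrix about ``axis`` by ``theta`` radians (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    a = np.cos(theta / 2.0)
    b, c, d = -axis * np.sin(theta / 2.0)
    return np.array(
        [
            [a * a + b * b - c * c - d * d, 2 * (b * c + a * d), 2 * (b * d - a * c)],
            [2 * (b * c - a * d), a * a + c * c - b * b - d * d, 2 * (c * d + a * b)],
            [2 * (b * d + a * c), 2 * (c * d - a * b), a * a + d * d - b * b - c * c],
        ]
    )


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Returns (R, t) such that mobile @ R + t best fits target. Both inputs
    are (n, 3) with fixed row correspondence.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    s = np.diag([1.0, 1.0, d])
    r = u @ s @ vt
    t = tc - mc @ r
    return r, t
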