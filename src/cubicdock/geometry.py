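"""Rigid-body geometry helpers shared across modules.

All rotations are proper (det = +1) 3x3 matrices acting on column vectors;
angles are in degrees unless noted.  The Euler convention used throughout
the package is intrinsic Z-Y-Z.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_x(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_to_matrix(psi: float, theta: float, phi: float) -> np.ndarray:
    """Intrinsic Z-Y-Z rotation matrix, angles in degrees."""
    return rot_z(psi) @ _rot_y(theta) @ rot_z(phi)


def matrix_to_euler(m: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix` (angles in degrees).

    At the theta = 0 gimbal singularity psi absorbs the full Z rotation.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        psi, theta, phi = Rotation.from_matrix(m).as_euler("ZYZ", degrees=True)
    return float(psi), float(theta), float(phi)


def rotation_axis_angle(m: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotation axis (unit vector) and angle in degrees, angle in [0, 180]."""
    rv = Rotation.from_matrix(m).as_rotvec()
    angle = float(np.linalg.norm(rv))
    if angle < 1e-12:
        return np.array([0.0, 0.0, 1.0]), 0.0
    return rv / angle, float(np.degrees(angle))


def align_vectors_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rotation matrix sending unit vector ``a`` onto unit vector ``b``."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degree turn: any axis perpendicular to a
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-6:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        return Rotation.from_rotvec(np.pi * perp).as_matrix()
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Plain coordinate RMSD without superposition."""
    d = np.asarray(p, float) - np.asarray(q, float)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t with R @ p_i + t ~= q_i."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    r = _svd_rotation((q - qc).T @ (p - pc))
    return r, qc - r @ pc


def superposed_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """RMSD after optimal rigid superposition of p onto q."""
    r, t = kabsch(p, q)
    return rmsd((r @ np.asarray(p, float).T).T + t, q)


def rotation_about_origin(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Best pure rotation about the origin mapping p onto q (no centering)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    return _svd_rotation(q.T @ p)


def _svd_rotation(h: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def dihedral(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention."""
    b0 = np.asarray(p0, float) - np.asarray(p1, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b1 /= np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement of atom d given atoms a-b-c, internal coordinates.

    ``bond`` is the c-d distance, ``angle`` the b-c-d angle and ``torsion``
    the a-b-c-d dihedral, both in degrees.
    """
    a, b, c = (np.asarray(v, float) for v in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
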