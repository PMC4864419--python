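"""Small-vector geometry used throughout the package.

All coordinates are in Angstrom, all angles in degrees unless a function
says otherwise.  These helpers are deliberately plain numpy: they operate
on (3,) or (n, 3) float arrays and carry no molecular semantics.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "bond_angle",
    "dihedral",
    "nerf_place",
    "rotation_about_axis",
    "kabsch",
    "fit_line",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return v normalised to unit length."""
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def bond_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, w = unit(a - b), unit(c - b)
    return float(np.degrees(np.arccos(np.clip(u @ w, -1.0, 1.0))))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention
    (positive = clockwise rotation of the far bond viewed from p1 to p2)."""
    b0 = np.asarray(p0, dtype=float) - np.asarray(p1)
    b1 = unit(np.asarray(p2) - np.asarray(p1))
    b2 = np.asarray(p3, dtype=float) - np.asarray(p2)
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    return float(np.degrees(np.arctan2(y, x)))


def nerf_place(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom d given chain a-b-c with |c-d| = bond, angle(b,c,d) and
    torsion(a,b,c,d).  Natural extension reference frame construction."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    ang = np.radians(angle)
    tor = np.radians(torsion)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about *axis*."""
    k = unit(np.asarray(axis, dtype=float))
    th = np.radians(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)


def kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal least-squares superposition of *mobile* onto *reference*.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits *reference*.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[0] < 3:
        raise ValueError("need two matched (n>=3, 3) coordinate sets")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(((moved - Q) ** 2).sum(axis=1).mean()))
    return R, t, rmsd


def fit_line(points: np.ndarray):
    """Best-fit line through *points*; returns (centroid, unit direction)."""
    X = np.asarray(points, dtype=float)
    c = X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X - c)
    return c, Vt[0]
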