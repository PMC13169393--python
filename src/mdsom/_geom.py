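"""Small rigid-body geometry helpers shared across modules.

All coordinates are in Angstrom; rotations are proper (det = +1).
"""
from __future__ import annotations

import numpy as np


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation mapping `mobile` onto `target`.

    Returns (R, t) such that mobile @ R.T + t best superposes onto target
    in the least-squares sense.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape:
        raise ValueError(f"shape mismatch: {mobile.shape} vs {target.shape}")
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    return R, t


def superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Return `mobile` rigidly superposed onto `target`."""
    R, t = kabsch(mobile, target)
    return mobile @ R.T + t


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without any fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def fit_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    """RMSD after optimal superposition (Kabsch)."""
    return rmsd(superpose(mobile, target), target)


def rotation_about_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a (unit) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero rotation axis")
    x, y, z = axis / n
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    C = 1.0 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_rad: float, dihedral_rad: float) -> np.ndarray:
    """Place atom D from internal coordinates (NeRF).

    D is at distance `bond` from c, with angle b-c-D equal to `angle_rad`
    and dihedral a-b-c-D equal to `dihedral_rad`.
    """
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond * np.array([
        -np.cos(angle_rad),
        np.cos(dihedral_rad) * np.sin(angle_rad),
        np.sin(dihedral_rad) * np.sin(angle_rad),
    ])
    M = np.stack([bc, m, n], axis=1)
    return c + M @ d2


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in radians (IUPAC convention)."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.arctan2(y, x))
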