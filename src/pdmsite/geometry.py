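"""Shared geometric primitives: dihedrals, rigid superposition, local frames."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["dihedral", "kabsch_superpose", "local_frame", "fibonacci_sphere"]


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees in (-180, 180] for four points."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray):
    """Optimal rigid-body superposition of ``mobile`` onto ``target``.

    Returns ``(R, t, rmsd)`` with the least-squares rotation matrix ``R``
    and translation ``t`` such that ``mobile @ R.T + t`` best fits
    ``target`` (Kabsch via SVD, proper rotation enforced).
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    if len(mobile) < 3:
        raise ValueError("need at least 3 paired points for superposition")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - ct, mobile - cm)
    R = rot.as_matrix()
    t = ct - cm @ R.T
    rmsd = rssd / np.sqrt(len(mobile))
    return R, t, float(rmsd)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector in frame construction")
    return v / n


def local_frame(central: np.ndarray, bonded: list, support: list | None = None) -> np.ndarray:
    """Right-handed orthonormal frame (columns x, y, z) at a central atom.

    x points along the mean of the bond unit vectors; z along the normal of
    the first two non-collinear directions.  With a single bonded neighbor
    (or collinear neighbors) the plane is completed from ``support``
    coordinates (e.g. second-shell covalent neighbors), which keeps the
    frame covariant under rigid motion of the molecule; only if no usable
    support exists does a fixed global-axis convention apply.
    """
    central = np.asarray(central, float)
    bonded = [np.asarray(b, float) for b in (bonded or [])]
    if not bonded:
        raise ValueError("local frame requires at least one bonded neighbor")
    dirs = [_unit(b - central) for b in bonded]
    x = np.mean(dirs, axis=0)
    if np.linalg.norm(x) < 1e-8:  # symmetric arrangement; fall back to first bond
        x = dirs[0]
    x = _unit(x)

    z = None
    candidates = dirs[1:]
    if support:
        candidates = candidates + [_unit(np.asarray(s, float) - central) for s in support]
    ref = dirs[0]
    for d in candidates:
        n = np.cross(ref, d)
        if np.linalg.norm(n) > 1e-6:
            z = _unit(n)
            break
    if z is None:
        # fixed convention: global axis least aligned with x
        axis = np.eye(3)[np.argmin(np.abs(x))]
        z = _unit(np.cross(x, axis))
    y = _unit(np.cross(z, x))
    z = np.cross(x, y)
    frame = np.column_stack([x, y, z])
    return frame


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    zc = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - zc * zc))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), zc])
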