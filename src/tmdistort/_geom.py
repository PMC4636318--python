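"""Small 3D geometry helpers shared by builders and analysis code."""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot normalise the zero vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, IUPAC convention."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def angle_deg(p0, p1, p2) -> float:
    """Bond angle p0-p1-p2 in degrees."""
    u = unit(np.asarray(p0) - np.asarray(p1))
    v = unit(np.asarray(p2) - np.asarray(p1))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |cd|=bond, ∠(b,c,d)=angle and
    dihedral(a,b,c,d)=torsion (degrees)."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    th = np.radians(angle)
    ph = np.radians(torsion)
    d_local = bond * np.array(
        [-np.cos(th), np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph)]
    )
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def rotate_about_axis(
    points: np.ndarray, origin: np.ndarray, axis: np.ndarray, angle_degrees: float
) -> np.ndarray:
    """Rotate points about the line (origin, axis) by the given angle."""
    rot = Rotation.from_rotvec(np.radians(angle_degrees) * unit(np.asarray(axis)))
    return rot.apply(np.asarray(points) - origin) + origin


def any_perpendicular(v: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to v."""
    v = unit(np.asarray(v))
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    return unit(np.cross(v, ref))
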