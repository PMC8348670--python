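"""Low-level vector geometry: internal-coordinate atom placement, dihedrals,
axis fitting and rigid-body transforms.

All coordinates are in Å, all angles in degrees at the public surface
(converted to radians internally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RigidTransform",
    "place_atom",
    "dihedral",
    "bond_angle",
    "fit_line",
    "rotation_about_axis",
    "unit",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return v normalised to unit length; raises on a near-zero vector."""
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("cannot normalise a near-zero vector")
    return v / n


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """Place atom D from three reference atoms by internal coordinates.

    The new atom D is at distance ``bond_length`` from C, forming the angle
    B-C-D = ``angle_deg`` and the dihedral A-B-C-D = ``dihedral_deg``
    (NeRF-style chain extension).
    """
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(dihedral_deg)
    bc = unit(c - b)
    n = unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond_length * np.cos(theta),
            bond_length * np.sin(theta) * np.cos(phi),
            bond_length * np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in [-180, 180)."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1u = unit(b1)
    v = b0 - np.dot(b0, b1u) * b1u
    w = b2 - np.dot(b2, b1u) * b1u
    x = np.dot(v, w)
    y = np.dot(np.cross(b1u, v), w)
    ang = np.degrees(np.arctan2(y, x))
    return ang if ang < 180.0 else ang - 360.0


def bond_angle(p0, p1, p2) -> float:
    """Angle p0-p1-p2 in degrees."""
    u = unit(np.asarray(p0) - np.asarray(p1))
    v = unit(np.asarray(p2) - np.asarray(p1))
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))


def fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Best-fit (least-squares) line through 3D points.

    Returns ``(centroid, direction)`` where direction is the principal
    component (unit vector).  Needs >= 2 distinct points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise ValueError("need at least two points to fit a line")
    centroid = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - centroid)
    return centroid, vt[0]


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues)."""
    k = unit(np.asarray(axis, dtype=float))
    t = np.deg2rad(angle_deg)
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * kx + (1 - np.cos(t)) * (kx @ kx)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length-3")
        if abs(np.linalg.det(r) - 1.0) > 1e-8:
            raise ValueError("rotation matrix must be proper (det = +1)")
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation matrix must be orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        c = np.asarray(coords, dtype=float)
        return c @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def to_json(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }
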