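"""Geometric kernel: neighbor search, ring-plane fitting and Kabsch superposition.

All coordinates are in Angstrom. These routines are deliberately free of any
structure-object knowledge; they operate on plain ``(n, 3)`` float arrays so the
interaction detectors and the clustering pipeline can share them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np


class GeometryError(ValueError):
    """Degenerate geometric input (collinear ring, too few points, ...)."""


@dataclass(frozen=True)
class RingPlane:
    """Least-squares plane through an aromatic ring.

    Attributes
    ----------
    centroid : (3,) array, Å — mean of the member coordinates.
    normal : (3,) unit array — smallest-singular-vector normal, sign fixed
        deterministically (positive z component; ties broken toward +x, then +y).
    member_atom_names : names of the atoms the plane was fitted to.
    """

    centroid: np.ndarray
    normal: np.ndarray
    member_atom_names: tuple[str, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (rotation 3x3, det=+1; translation Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def neighbor_pairs(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    cutoff: float,
) -> list[tuple[int, int, float]]:
    """All index pairs ``(i, j)`` with ``|a_i - b_j| <= cutoff``.

    Uses a uniform cell list with edge length equal to the cutoff, so the
    expected cost is linear in the number of points for bounded density.

    Returns a list of ``(index_a, index_b, distance)`` sorted by ``(i, j)``.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if len(a) == 0 or len(b) == 0:
        return []

    # Hash B points into cubic cells of edge `cutoff`; for each A point only
    # the 27 surrounding cells can contain a partner.
    cells: dict[tuple[int, int, int], list[int]] = {}
    b_cells = np.floor(b / cutoff).astype(np.int64)
    for j, c in enumerate(map(tuple, b_cells)):
        cells.setdefault(c, []).append(j)

    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    out: list[tuple[int, int, float]] = []
    a_cells = np.floor(a / cutoff).astype(np.int64)
    for i in range(len(a)):
        cx, cy, cz = a_cells[i]
        cand: list[int] = []
        for dx, dy, dz in offsets:
            cand.extend(cells.get((cx + dx, cy + dy, cz + dz), ()))
        if not cand:
            continue
        idx = np.array(cand, dtype=np.int64)
        d = np.linalg.norm(b[idx] - a[i], axis=1)
        keep = d <= cutoff
        for j, dist in zip(idx[keep], d[keep]):
            out.append((i, int(j), float(dist)))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


def fit_ring_plane(
    coords: np.ndarray, member_atom_names: Sequence[str] = ()
) -> RingPlane:
    """Least-squares plane through ``coords`` (>= 3 non-collinear points).

    The normal is the right singular vector of the centred coordinates with the
    smallest singular value. Its sign is fixed so downstream angle computations
    are deterministic: positive dot product with +z, falling back to +x then +y
    when the preceding components vanish.
    """
    pts = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise GeometryError(f"need >= 3 points to fit a plane, got {len(pts)}")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8:
        raise GeometryError("points are collinear; plane is undefined")
    normal = vt[2]
    for k in (2, 0, 1):  # z, then x, then y
        if abs(normal[k]) > 1e-12:
            if normal[k] < 0:
                normal = -normal
            break
    normal = normal / np.linalg.norm(normal)
    return RingPlane(centroid=centroid, normal=normal,
                     member_atom_names=tuple(member_atom_names))


def kabsch(x: np.ndarray, y: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal superposition of ``y`` onto ``x`` (Kabsch, closed form).

    Returns the proper rigid transform minimizing the RMSD of ``R @ y + t``
    against ``x``, and that minimal RMSD. Reflections are never returned: the
    smallest singular direction is flipped when the correlation matrix has
    negative determinant.
    """
    X = np.asarray(x, dtype=float).reshape(-1, 3)
    Y = np.asarray(y, dtype=float).reshape(-1, 3)
    if X.shape != Y.shape:
        raise ValueError(f"point sets differ in shape: {X.shape} vs {Y.shape}")
    n = len(X)
    if n < 3:
        raise ValueError(f"need >= 3 points for superposition, got {n}")
    cx = X.mean(axis=0)
    cy = Y.mean(axis=0)
    H = (Y - cy).T @ (X - cx)
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cx - R @ cy
    diff = (Y @ R.T + t) - X
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return RigidTransform(rotation=R, translation=t), rmsd


def folded_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two directions folded into [0°, 90°] (sign-free)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = abs(float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a–b–c at vertex ``b``, degrees in [0, 180]."""
    u = np.asarray(a, dtype=float) - b
    v = np.asarray(c, dtype=float) - b
    cos = float(np.dot(u, v)) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
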