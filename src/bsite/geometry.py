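"""Geometric primitives: centers, minimum distances, rigid-body superposition.

All coordinates are in Angstroms, in the orthogonal frame of the input
structures. Rotations are proper (determinant +1); reflections are never
returned by the superposition routine.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "Transform",
    "Center",
    "geometric_center",
    "min_distance",
    "kabsch_superpose",
    "apply_transform",
]

_ORTHO_TOL = 1e-6


@dataclass(frozen=True)
class Transform:
    """A rigid-body motion: ``y = rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        rot = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        tra = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", rot)
        object.__setattr__(self, "translation", tra)
        if not np.allclose(rot @ rot.T, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(rot), 1.0, atol=_ORTHO_TOL):
            raise ValueError("rotation matrix is not a proper rotation (det != +1)")

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "Transform":
        rot_inv = self.rotation.T
        return Transform(rot_inv, -rot_inv @ self.translation)

    def compose(self, other: "Transform") -> "Transform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return Transform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class Center:
    """A geometric center with a note of which atom set it averages."""

    coords: np.ndarray
    source: str = "atoms"

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float).reshape(3)
        object.__setattr__(self, "coords", c)
        if not np.all(np.isfinite(c)):
            raise ValueError("center coordinates must be finite")


def _as_coords(atoms) -> np.ndarray:
    """Accept an (n, 3) array or a list of objects with ``.coords``."""
    if isinstance(atoms, np.ndarray):
        arr = np.asarray(atoms, dtype=float)
    else:
        atoms = list(atoms)
        if atoms and hasattr(atoms[0], "coords"):
            arr = np.asarray([a.coords for a in atoms], dtype=float)
        else:
            arr = np.asarray(atoms, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, 3)
    return arr


def geometric_center(atoms, source: str = "atoms") -> Center:
    """Unweighted mean of atom coordinates (no mass weighting)."""
    coords = _as_coords(atoms)
    if coords.size == 0:
        raise ValueError("geometric_center requires at least one atom")
    return Center(coords.mean(axis=0), source=source)


def min_distance(point, atoms) -> float:
    """Minimum Euclidean distance from ``point`` to any atom in the set."""
    coords = _as_coords(atoms)
    if coords.size == 0:
        raise ValueError("min_distance requires at least one atom")
    p = np.asarray(point, dtype=float).reshape(1, 3)
    return float(cdist(p, coords).min())


def kabsch_superpose(moving, fixed) -> tuple[Transform, float]:
    """Least-squares rigid superposition of ``moving`` onto ``fixed``.

    Returns the proper-rotation transform minimizing the RMSD of the paired
    coordinates, and that minimal RMSD. Requires >= 3 non-degenerate points.
    """
    mov = _as_coords(moving)
    fix = _as_coords(fixed)
    if mov.shape != fix.shape:
        raise ValueError(f"point sets differ in shape: {mov.shape} vs {fix.shape}")
    if mov.shape[0] < 3:
        raise ValueError("superposition requires at least 3 point pairs")
    mov_c = mov.mean(axis=0)
    fix_c = fix.mean(axis=0)
    h = (mov - mov_c).T @ (fix - fix_c)
    u, s, vt = np.linalg.svd(h)
    # collinear/coincident point sets leave the rotation underdetermined
    if s[1] < 1e-9 * max(s[0], 1e-12):
        raise ValueError("degenerate (collinear or coincident) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    tra = fix_c - rot @ mov_c
    t = Transform(rot, tra)
    delta = t.apply(mov) - fix
    rmsd = float(np.sqrt((delta**2).sum() / mov.shape[0]))
    return t, rmsd


def apply_transform(t: Transform, atoms):
    """Transform coordinates; non-coordinate atom fields are untouched.

    Accepts an (n, 3) array (returns an array) or a list of Atom-like objects
    (returns new objects via their ``with_coords`` method).
    """
    if isinstance(atoms, np.ndarray):
        return t.apply(atoms)
    atoms = list(atoms)
    if atoms and hasattr(atoms[0], "with_coords"):
        moved = t.apply(np.asarray([a.coords for a in atoms]))
        return [a.with_coords(c) for a, c in zip(atoms, moved)]
    return t.apply(np.asarray(atoms, dtype=float))
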