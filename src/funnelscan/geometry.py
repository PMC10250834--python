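"""Rigid-body superposition and distance primitives.

Least-squares superposition is solved with the Kabsch algorithm (through
``scipy.spatial.transform.Rotation.align_vectors``, which enforces a proper
rotation) and, independently, with Horn's closed-form quaternion method.
The two routes are algorithmically distinct, so one can serve as an oracle
for the other. Protein chirality rules out reflections: only det(R)=+1
transforms are ever produced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation


class GeometryError(ValueError):
    """Raised for degenerate geometric input."""


_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t (rotation then translation, Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if r.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-6):
            raise GeometryError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-6:
            raise GeometryError("reflections are not allowed (det must be +1)")
        # Re-orthonormalize via SVD so RtR = I holds to tight tolerance.
        u, _, vt = np.linalg.svd(r)
        r = u @ vt
        if np.linalg.det(r) < 0:
            u[:, -1] *= -1
            r = u @ vt
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rinv = self.rotation.T
        return RigidTransform(rinv, -rinv @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


def apply_transform(transform: RigidTransform, points: np.ndarray) -> np.ndarray:
    return transform.apply(points)


def _check_point_sets(moving: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    moving = np.asarray(moving, dtype=float)
    target = np.asarray(target, dtype=float)
    if moving.ndim != 2 or moving.shape[1] != 3 or moving.shape != target.shape:
        raise GeometryError("point sets must be matching (n, 3) arrays")
    if len(moving) < 3:
        raise GeometryError("superposition needs at least 3 points")
    for pts, name in ((moving, "moving"), (target, "target")):
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            raise GeometryError(f"{name} points are collinear; rotation is underdetermined")
    return moving, target


def superposition_rmsd(moving: np.ndarray, target: np.ndarray, transform: RigidTransform) -> float:
    diff = transform.apply(moving) - np.asarray(target, dtype=float)
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def kabsch_superpose(moving: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal proper-rotation superposition of ``moving`` onto ``target``.

    Returns the minimizing :class:`RigidTransform` and the minimal RMSD.
    """
    moving, target = _check_point_sets(moving, target)
    cm, ct = moving.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, moving - cm)
    r = rot.as_matrix()
    transform = RigidTransform(r, ct - r @ cm)
    return transform, superposition_rmsd(moving, target, transform)


def horn_superpose(moving: np.ndarray, target: np.ndarray) -> tuple[RigidTransform, float]:
    """Closed-form quaternion superposition (Horn 1987).

    Builds the 4x4 key matrix from the cross-covariance of the centered
    point sets; the eigenvector of its largest eigenvalue is the optimal
    unit quaternion. Used as the independent cross-check of
    :func:`kabsch_superpose`.
    """
    moving, target = _check_point_sets(moving, target)
    cm, ct = moving.mean(axis=0), target.mean(axis=0)
    a, b = moving - cm, target - ct
    m = a.T @ b  # cross-covariance
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    key = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    eigvals, eigvecs = np.linalg.eigh(key)
    q = eigvecs[:, -1]  # w, x, y, z of the optimal rotation
    w, x, y, z = q
    r = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    transform = RigidTransform(r, ct - r @ cm)
    return transform, superposition_rmsd(moving, target, transform)


def min_interchain_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Exact minimum Euclidean distance between two heavy-atom coordinate sets."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise GeometryError("distance query on an empty atom set")
    dists, _ = cKDTree(b).query(a, k=1)
    return float(np.min(dists))


def pairs_within(a: np.ndarray, b: np.ndarray, cutoff: float):
    """Indices (i, j) with ||a_i - b_j|| <= cutoff, exact (kd-tree backed)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise GeometryError("distance query on an empty atom set")
    tree_a, tree_b = cKDTree(a), cKDTree(b)
    pairs = tree_a.query_ball_tree(tree_b, r=cutoff)
    return [(i, j) for i, js in enumerate(pairs) for j in js]
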