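"""Rigid-body geometry primitives: transforms and least-squares superposition.

Coordinates are in Angstroms throughout. Rotations are proper (det = +1);
reflections are always rejected so chirality is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

__all__ = ["RigidTransform", "superimpose"]


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R @ x + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite transform components")
        if np.linalg.norm(R.T @ R - np.eye(3)) > 1e-8:
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (reflection) rejected")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array or a single 3-vector."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying `other` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rinv = self.rotation.T
        return RigidTransform(Rinv, -Rinv @ self.translation)

    def power(self, n: int) -> "RigidTransform":
        """Compose the transform with itself n times (n >= 0)."""
        out = RigidTransform.identity()
        for _ in range(n):
            out = self.compose(out)
        return out

    def angle_deg(self) -> float:
        """Rotation angle in degrees, in [0, 180]."""
        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))

    def axis(self) -> np.ndarray:
        """Unit rotation axis.

        For the degenerate 180-degree case the rotation-vector route is
        numerically fine; for near-identity rotations the axis is ill-defined
        and the +z axis is returned.
        """
        rotvec = Rotation.from_matrix(self.rotation).as_rotvec()
        norm = np.linalg.norm(rotvec)
        if norm < 1e-12:
            return np.array([0.0, 0.0, 1.0])
        return rotvec / norm


def superimpose(
    mobile: np.ndarray, target: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of `mobile` onto `target` (Kabsch).

    Parameters
    ----------
    mobile, target
        (N, 3) coordinate arrays of equal length N >= 3, typically CA traces.

    Returns
    -------
    transform
        The proper rigid motion minimizing || target - (R @ mobile + t) ||.
    rmsd
        Root-mean-square deviation after applying the transform, in Angstroms.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be (N, 3) arrays of equal shape")
    if len(mobile) < 3:
        raise ValueError("need at least 3 points for superposition")

    mob_mean = mobile.mean(axis=0)
    tgt_mean = target.mean(axis=0)
    mob_c = mobile - mob_mean
    tgt_c = target - tgt_mean

    # scipy's align_vectors is the Kabsch solution with the reflection
    # correction built in (proper rotation guaranteed).
    if np.linalg.matrix_rank(mob_c, tol=1e-9) < 2:
        logger.warning("rank-deficient (collinear) point set in superposition")
    rot, _ = Rotation.align_vectors(tgt_c, mob_c)
    R = rot.as_matrix()
    t = tgt_mean - R @ mob_mean
    transform = RigidTransform(R, t)
    diff = transform.apply(mobile) - target
    rmsd = float(np.sqrt((diff**2).sum() / len(mobile)))
    return transform, rmsd
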