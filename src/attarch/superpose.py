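"""Rigid-body superposition and transform algebra.

Every model-building step in this package — placing half-site complexes on
scaffold duplexes, deriving helical step transforms, comparing NCS copies —
reduces to a least-squares superposition of ordered point sets followed by
application of the resulting proper rigid transform.  The fit is the classic
Kabsch solution: SVD of the cross-covariance matrix with the determinant sign
correction that excludes reflections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "RigidTransform",
    "Correspondence",
    "DegenerateFitError",
    "kabsch_fit",
    "apply_transform",
    "rmsd",
]

_ORTHO_TOL = 1e-8


class DegenerateFitError(ValueError):
    """Raised when a superposition problem is under-determined."""


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``x -> R x + t`` in Angstroms.

    ``rotation`` is orthonormal with det +1 (checked on construction to 1e-8).
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.all(np.isfinite(R)) or not np.all(np.isfinite(t)):
            raise ValueError("non-finite rigid transform")
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation is not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has determinant -1 (improper transform)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec_deg(cls, axis: Sequence[float], angle_deg: float,
                        translation: Sequence[float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        """Rotation of ``angle_deg`` about ``axis`` (through the origin), then translation."""
        from scipy.spatial.transform import Rotation

        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("zero rotation axis")
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / n).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    @property
    def angle_deg(self) -> float:
        """Rotation angle in degrees, in [0, 180]."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def screw_axis(self) -> np.ndarray:
        """Unit rotation axis (arbitrary for the identity)."""
        from scipy.spatial.transform import Rotation

        v = Rotation.from_matrix(self.rotation).as_rotvec()
        n = np.linalg.norm(v)
        return v / n if n > 1e-12 else np.array([0.0, 0.0, 1.0])

    def to_flat(self) -> list[float]:
        """12-number row-major serialization (9 rotation + 3 translation)."""
        return [*self.rotation.reshape(9).tolist(), *self.translation.tolist()]

    @classmethod
    def from_flat(cls, values: Sequence[float]) -> "RigidTransform":
        v = np.asarray(values, dtype=float)
        if v.shape != (12,):
            raise ValueError("expected 12 numbers")
        return cls(v[:9].reshape(3, 3), v[9:])

    def almost_equal(self, other: "RigidTransform", tol: float = 1e-8) -> bool:
        return (np.abs(self.rotation - other.rotation).max() < tol
                and np.abs(self.translation - other.translation).max() < tol)


@dataclass
class Correspondence:
    """Ordered point-pair correspondence for a superposition problem."""

    moving: np.ndarray
    fixed: np.ndarray
    labels: Optional[list[str]] = field(default=None)

    def __post_init__(self) -> None:
        self.moving = np.asarray(self.moving, dtype=float).reshape(-1, 3)
        self.fixed = np.asarray(self.fixed, dtype=float).reshape(-1, 3)
        if len(self.moving) != len(self.fixed):
            raise ValueError(
                f"point lists differ in length ({len(self.moving)} vs {len(self.fixed)})")
        if self.labels is not None:
            if len(self.labels) != len(self.moving):
                raise ValueError("labels length mismatch")
            if len(set(self.labels)) != len(self.labels):
                raise ValueError("duplicated correspondence label")


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation of two equally long point lists (no fitting)."""
    a = np.asarray(a, dtype=float).reshape(-1, 3)
    b = np.asarray(b, dtype=float).reshape(-1, 3)
    if len(a) != len(b):
        raise ValueError(f"point lists differ in length ({len(a)} vs {len(b)})")
    if len(a) == 0:
        raise ValueError("empty point lists")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_fit(corr: Correspondence | None = None,
               moving: Optional[np.ndarray] = None,
               fixed: Optional[np.ndarray] = None) -> tuple[RigidTransform, float]:
    """Least-squares proper rigid superposition of ``moving`` onto ``fixed``.

    Returns the optimal :class:`RigidTransform` and the RMSD evaluated after
    applying it.  Requires at least three non-collinear point pairs; degenerate
    configurations raise :class:`DegenerateFitError` naming the degeneracy.
    """
    if corr is None:
        if moving is None or fixed is None:
            raise ValueError("provide a Correspondence or both point lists")
        corr = Correspondence(np.asarray(moving), np.asarray(fixed))
    P, Q = corr.moving, corr.fixed
    n = len(P)
    if n < 3:
        raise DegenerateFitError(f"need >= 3 point pairs, got {n}")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    # Collinear (or coincident) moving set leaves rotation about the line free.
    s = np.linalg.svd(P0, compute_uv=False)
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateFitError("moving points are collinear or coincident")
    H = P0.T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    tr = RigidTransform(R, t)
    return tr, rmsd(tr.apply(P), Q)


def apply_transform(transform: RigidTransform, obj):
    """Apply a rigid transform to points or to any object with ``transformed``.

    Point arrays are returned as transformed copies; objects implementing a
    ``transformed(transform)`` method (structures, duplexes, complexes)
    delegate to it.  The input is never mutated.
    """
    if hasattr(obj, "transformed"):
        return obj.transformed(transform)
    return transform.apply(np.asarray(obj, dtype=float))
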