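"""Rigid (rotation + translation) transforms in 3D.

All coordinates in the package are centimeters, right-handed, with the
y-axis vertical (body height). A :class:`RigidTransform` maps points from
one frame into another; cameras store their camera-to-world pose as one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform"]

_ORTHO_ATOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform ``x -> R @ x + t``.

    Parameters
    ----------
    rotation : (3, 3) array
        Orthonormal matrix with determinant +1.
    translation : (3,) array
        Offset in cm.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R @ R.T, np.eye(3), atol=_ORTHO_ATOL):
            raise ValueError("rotation is not orthonormal (R @ R.T != I)")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is improper (det = -1); reflections are not rigid")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix."""
        M = np.asarray(matrix, dtype=float).reshape(4, 4)
        return cls(M[:3, :3], M[:3, 3])

    @classmethod
    def from_axis_angle(cls, axis, angle_rad: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        return cls(R, np.asarray(translation, dtype=float))

    # -- algebra ------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other``: apply *other* first, then *self*."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform points, shape (n, 3) or (3,)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_vectors(self, vectors: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (no translation)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    # -- diagnostics --------------------------------------------------
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = np.clip((np.trace(self.rotation) - 1.0) / 2.0, -1.0, 1.0)
        return float(np.degrees(np.arccos(c)))

    def distance_to(self, other: "RigidTransform") -> tuple[float, float]:
        """(rotation angle deg, translation norm cm) of ``self.inverse() @ other``."""
        d = self.inverse() @ other
        return d.rotation_angle_deg(), float(np.linalg.norm(d.translation))
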