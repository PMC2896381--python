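"""Rigid (rotation + translation) transforms on calibrated 3D coordinates.

A :class:`RigidTransform` maps points ``p`` to ``R @ p + t`` where ``R`` is a
proper rotation (orthonormal, det = +1) and ``t`` a translation in physical
units (µm). These transforms serve both as per-content local transforms in
the scene graph and as the output of landmark-based registration.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "rotation_about_axis"]

_ORTHO_ATOL = 1e-6


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Return the 3x3 proper rotation of ``angle_deg`` degrees about ``axis``.

    ``axis`` need not be normalized but must be non-zero.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be non-zero")
    return Rotation.from_rotvec(axis / norm * np.deg2rad(angle_deg)).as_matrix()


class RigidTransform:
    """Rotation plus translation, stored as ``(R, t)``.

    Parameters
    ----------
    rotation : (3, 3) array_like, optional
        Proper rotation matrix; identity if omitted.
    translation : (3,) array_like, optional
        Translation in µm; zero if omitted.
    """

    __slots__ = ("rotation", "translation")

    def __init__(self, rotation=None, translation=None):
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if t.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=_ORTHO_ATOL):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_ATOL):
            raise ValueError("rotation must have det = +1 (no reflections)")
        self.rotation = R
        self.translation = t

    # -- constructors -------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, center=None) -> "RigidTransform":
        """Rotation about an axis through ``center`` (origin if omitted)."""
        R = rotation_about_axis(axis, angle_deg)
        if center is None:
            return cls(R, np.zeros(3))
        c = np.asarray(center, dtype=float)
        return cls(R, c - R @ c)

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        """Build from a 4x4 homogeneous matrix (must be rigid)."""
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("expected a 4x4 homogeneous matrix")
        return cls(m[:3, :3], m[:3, 3])

    # -- algebra ------------------------------------------------------
    def matrix(self) -> np.ndarray:
        """The equivalent 4x4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def apply(self, points) -> np.ndarray:
        """Transform one point or an (N, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    # -- misc ---------------------------------------------------------
    def is_identity(self, atol: float = 1e-12) -> bool:
        return np.allclose(self.rotation, np.eye(3), atol=atol) and np.allclose(
            self.translation, 0.0, atol=atol
        )

    def __eq__(self, other):
        if not isinstance(other, RigidTransform):
            return NotImplemented
        return np.array_equal(self.rotation, other.rotation) and np.array_equal(
            self.translation, other.translation
        )

    def __repr__(self):
        angle = np.rad2deg(
            np.arccos(np.clip((np.trace(self.rotation) - 1) / 2, -1, 1))
        )
        return (
            f"RigidTransform(angle={angle:.3f}°, "
            f"t=({self.translation[0]:.3g}, {self.translation[1]:.3g}, "
            f"{self.translation[2]:.3g}))"
        )
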