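"""Rotation and rigid-transform primitives shared by all pipeline stages.

Conventions (used everywhere in this package):

* Euler angles ``(rot, tilt, psi)`` are intrinsic ZYZ, in degrees.  The
  resulting matrix maps reference-frame coordinates to the particle
  (projection) frame; projection is along +z of the particle frame.
* ``tilt`` lies in ``[0, 180]``; ``rot`` and ``psi`` in ``(-180, 180]``.
* Coordinates are right-handed, in Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "normalize_angle",
    "euler_to_matrix",
    "matrix_to_euler",
    "axis_rotation_matrix",
    "TransformRT",
]


def normalize_angle(angle: float) -> float:
    """Wrap an angle in degrees into the canonical interval ``(-180, 180]``."""
    wrapped = math.remainder(float(angle), 360.0)
    if wrapped <= -180.0:
        wrapped += 360.0
    return wrapped


def euler_to_matrix(rot: float, tilt: float, psi: float) -> np.ndarray:
    """Rotation matrix for intrinsic ZYZ Euler angles in degrees.

    Maps reference-frame vectors into the particle projection frame:
    ``R = Rz(rot) @ Ry(tilt) @ Rz(psi)``.
    """
    return Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> tuple[float, float, float]:
    """Inverse of :func:`euler_to_matrix`; tilt is returned in ``[0, 180]``.

    At the gimbal singularity (tilt 0 or 180) the in-plane angle is folded
    into ``rot`` and ``psi`` is set to 0, which is a valid representative.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        rot, tilt, psi = Rotation.from_matrix(matrix).as_euler("ZYZ", degrees=True)
    return normalize_angle(rot), float(tilt), normalize_angle(psi)


def axis_rotation_matrix(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Proper rotation by ``angle_deg`` about an arbitrary (unnormalized) axis."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("rotation axis must be non-zero")
    return Rotation.from_rotvec(axis / norm * np.deg2rad(angle_deg)).as_matrix()


@dataclass(frozen=True)
class TransformRT:
    """Rigid transform: proper rotation plus translation in Angstrom."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        rotation = np.asarray(self.rotation, dtype=float)
        translation = np.asarray(self.translation, dtype=float)
        if rotation.shape != (3, 3):
            raise ValueError("rotation must be a 3x3 matrix")
        if translation.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        if not np.allclose(rotation @ rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not math.isclose(float(np.linalg.det(rotation)), 1.0, abs_tol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", rotation)
        object.__setattr__(self, "translation", translation)

    @classmethod
    def identity(cls) -> "TransformRT":
        return cls()

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an ``(3,)`` point or ``(n, 3)`` point array."""
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "TransformRT") -> "TransformRT":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return TransformRT(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "TransformRT":
        rot_inv = self.rotation.T
        return TransformRT(rotation=rot_inv, translation=-rot_inv @ self.translation)

    def rotation_angle(self) -> float:
        """Magnitude of the rotation in degrees."""
        return float(
            np.rad2deg(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )
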