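"""Two-landmark rigid + isotropic-scale registration.

Each brain is annotated with a single line between two recognizable
landmarks. The line's in-plane direction fixes the rotation about z, its
in-plane length fixes the scale, and its first endpoint fixes the
translation. Brains are assumed flat-landed, so there is no tilt about x or
y; z is handled by translation (and, optionally, the same isotropic scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import ImageStack

__all__ = ["LandmarkLine", "PoseZ", "pose_from_landmarks", "apply_pose"]


@dataclass
class LandmarkLine:
    """A line between two landmark points, in 0-based (z, y, x) voxel coords."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.p0 = tuple(float(v) for v in self.p0)  # type: ignore[assignment]
        self.p1 = tuple(float(v) for v in self.p1)  # type: ignore[assignment]
        if self.p0 == self.p1:
            raise ValueError("landmark endpoints must differ")
        if self.inplane_length() == 0:
            raise ValueError("landmark line must have a nonzero in-plane component")

    def inplane_vector(self) -> tuple[float, float]:
        """(dy, dx) of p1 - p0."""
        return (self.p1[1] - self.p0[1], self.p1[2] - self.p0[2])

    def inplane_length(self) -> float:
        dy, dx = self.inplane_vector()
        return math.hypot(dy, dx)

    def inplane_angle(self) -> float:
        dy, dx = self.inplane_vector()
        return math.atan2(dy, dx)


@dataclass
class PoseZ:
    """Rotation about z by ``theta_rad``, isotropic scale, then translation.

    Maps sample coordinates p = (z, y, x) to reference coordinates:

        q = S * R_z(theta) @ p + t

    where R_z rotates the (y, x) plane and S scales in-plane (and along z
    when ``scale_z`` is true, the default). Coordinates are 0-based,
    voxel-center convention.
    """

    theta_rad: float
    scale: float
    translation: tuple[float, float, float]
    scale_z: bool = True

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        self.translation = tuple(float(v) for v in self.translation)  # type: ignore[assignment]

    def matrix(self) -> np.ndarray:
        """3x3 linear part, acting on (z, y, x) column vectors.

        cos/sin values within 1e-12 of 0 or +/-1 are snapped, so quarter
        turns are exact permutations (otherwise boundary voxels fall a few
        ulps outside the grid and resample as background)."""
        c, s = math.cos(self.theta_rad), math.sin(self.theta_rad)
        c, s = (round(v) if abs(v - round(v)) < 1e-12 else v for v in (c, s))
        sz = self.scale if self.scale_z else 1.0
        # rotating the (y, x) plane: y' = c*y + s*x ; x' = -s*y + c*x
        return np.array(
            [
                [sz, 0.0, 0.0],
                [0.0, self.scale * c, self.scale * s],
                [0.0, -self.scale * s, self.scale * c],
            ]
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (N, 3) array of (z, y, x) points."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix().T + np.asarray(self.translation)

    def inverse(self) -> "PoseZ":
        inv_lin = np.linalg.inv(self.matrix())
        t = -inv_lin @ np.asarray(self.translation)
        return PoseZ(
            theta_rad=-self.theta_rad,
            scale=1.0 / self.scale,
            translation=tuple(t),
            scale_z=self.scale_z,
        )


def pose_from_landmarks(
    sample: LandmarkLine, reference: LandmarkLine, scale_z: bool = True
) -> PoseZ:
    """Pose that carries the sample's landmark line onto the reference's.

    theta is the in-plane angle difference, scale the in-plane length ratio,
    and the translation places the rotated+scaled ``sample.p0`` on
    ``reference.p0`` (z purely translational when ``scale_z`` is false).
    """
    theta = reference.inplane_angle() - sample.inplane_angle()
    scale = reference.inplane_length() / sample.inplane_length()
    pose = PoseZ(theta_rad=theta, scale=scale, translation=(0.0, 0.0, 0.0), scale_z=scale_z)
    mapped_p0 = pose.apply(np.array(sample.p0))[0]
    t = np.asarray(reference.p0) - mapped_p0
    return PoseZ(theta_rad=theta, scale=scale, translation=tuple(t), scale_z=scale_z)


def apply_pose(
    stack: ImageStack,
    pose: PoseZ,
    out_shape: tuple[int, int, int] | None = None,
    order: int = 1,
) -> ImageStack:
    """Resample a stack into the reference frame of ``pose``.

    Inverse-mapped resampling: each output voxel q is filled from the sample
    at ``pose.inverse() @ q``. Out-of-bounds voxels are 0. Use ``order=0``
    (nearest) for label volumes, ``order=1`` (trilinear) for intensities.
    """
    if out_shape is None:
        out_shape = stack.shape
    if any(s <= 0 for s in out_shape):
        raise ValueError("out_shape must be positive")
    inv = pose.inverse()
    out = ndimage.affine_transform(
        stack.data.astype(float, copy=False),
        matrix=inv.matrix(),
        offset=np.asarray(inv.translation),
        output_shape=tuple(out_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=(order > 1),
    )
    if np.issubdtype(stack.data.dtype, np.integer) and order == 0:
        out = np.rint(out).astype(stack.data.dtype)
    return ImageStack(data=out, spacing_um=stack.spacing_um, channel=stack.channel)
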