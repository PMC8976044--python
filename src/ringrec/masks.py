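"""Layered z-masks and soft shape masks with raised-cosine transitions.

A layered mask is 1 inside a physical z-interval, 0 outside, with a
cos^2 ramp of width ``w`` centered on each boundary (half inside, half
outside), so that contiguous layers sharing a boundary and width sum to
exactly 1 — a partition of unity along z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import VolumeGrid

__all__ = ["LayerSpec", "MaskError", "make_layer_mask", "apply_mask", "soft_sphere_mask"]


class MaskError(ValueError):
    pass


@dataclass(frozen=True)
class LayerSpec:
    """Physical z-interval (A) with a raised-cosine transition width (A)."""

    z_start: float
    z_end: float
    transition_width: float = 0.0

    def __post_init__(self) -> None:
        if not self.z_start < self.z_end:
            raise ValueError("z_start must be < z_end")
        if self.transition_width < 0:
            raise ValueError("transition width must be >= 0")
        if self.transition_width > self.z_end - self.z_start:
            raise ValueError("transition width must not exceed the layer height")


def _ramp_profile(z: np.ndarray, spec: LayerSpec) -> np.ndarray:
    w = spec.transition_width
    if w == 0.0:
        return ((z > spec.z_start) & (z < spec.z_end)).astype(np.float64)
    m = np.zeros_like(z)
    core = (z >= spec.z_start + w / 2) & (z <= spec.z_end - w / 2)
    m[core] = 1.0
    rising = (z > spec.z_start - w / 2) & (z < spec.z_start + w / 2)
    m[rising] = np.cos(np.pi * (z[rising] - spec.z_start - w / 2) / (2 * w)) ** 2
    falling = (z > spec.z_end - w / 2) & (z < spec.z_end + w / 2)
    m[falling] = np.cos(np.pi * (z[falling] - spec.z_end + w / 2) / (2 * w)) ** 2
    return m


def make_layer_mask(grid_n: int, pixel_size: float, spec: LayerSpec) -> VolumeGrid:
    """Layered mask, constant over x and y; values in [0, 1].

    The voxel exactly at a boundary gets value 0.5 (ramp midpoint).
    """
    n = grid_n
    z = (np.arange(n) - n // 2) * pixel_size
    profile = _ramp_profile(z, spec)
    if profile.max() == 0.0:
        raise MaskError(
            f"layer [{spec.z_start}, {spec.z_end}] A does not intersect the grid "
            f"(z range [{z[0]}, {z[-1]}] A)"
        )
    data = np.broadcast_to(profile[:, None, None], (n, n, n)).copy()
    return VolumeGrid(data=data, pixel_size=pixel_size)


def apply_mask(volume: VolumeGrid, mask: VolumeGrid) -> VolumeGrid:
    """Voxelwise product of a volume and a mask on the same grid."""
    if volume.data.shape != mask.data.shape:
        raise MaskError(
            f"shape mismatch: volume {volume.data.shape} vs mask {mask.data.shape}"
        )
    return VolumeGrid(data=volume.data * mask.data, pixel_size=volume.pixel_size)


def soft_sphere_mask(
    grid_n: int, pixel_size: float, radius: float, transition_width: float = 0.0
) -> VolumeGrid:
    """Spherical mask: 1 inside, raised-cosine shell of width ``w`` at ``radius``."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = grid_n
    axis = (np.arange(n) - n // 2) * pixel_size
    zz, yy, xx = np.meshgrid(axis, axis, axis, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    w = transition_width
    if w == 0.0:
        data = (r < radius).astype(np.float64)
    else:
        data = np.zeros_like(r)
        data[r <= radius - w / 2] = 1.0
        shell = (r > radius - w / 2) & (r < radius + w / 2)
        data[shell] = np.cos(np.pi * (r[shell] - radius + w / 2) / (2 * w)) ** 2
    return VolumeGrid(data=data, pixel_size=pixel_size)
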