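"""Composite ring assembly: place one subunit into all symmetry positions.

Mirrors the map-level procedure of aligning a single-subunit reconstruction
to each position of a C-symmetric ring reconstruction, then placing the
subunit model with each fitted transform to build the composite ring model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import TransformRT, axis_rotation_matrix
from .io_formats import AtomicModel, VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "RingPlacement",
    "assemble_ring",
    "fit_subunit_positions",
    "ring_diameters",
    "RingDiameters",
]


@dataclass
class RingPlacement:
    """One rigid transform per subunit position, with fit scores."""

    transforms: list[TransformRT]
    n_sym: int
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    scores: list[float] = field(default_factory=list)
    unreliable: list[bool] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.transforms) != self.n_sym:
            raise ValueError("need exactly one transform per symmetry position")

    @classmethod
    def ideal(
        cls, n_sym: int, axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    ) -> "RingPlacement":
        """Exact C_n placements about ``axis`` (no translation)."""
        transforms = [
            TransformRT(rotation=axis_rotation_matrix(np.asarray(axis), k * 360.0 / n_sym))
            for k in range(n_sym)
        ]
        return cls(transforms=transforms, n_sym=n_sym, axis=axis,
                   scores=[1.0] * n_sym, unreliable=[False] * n_sym)


def assemble_ring(model: AtomicModel, placement: RingPlacement) -> AtomicModel:
    """Concatenate transformed copies of the subunit model.

    Chain ids get a ``_s<k>`` suffix per subunit position; no clash check is
    performed (overlap, if any, is the caller's to inspect).
    """
    if placement.n_sym == 1 and placement.transforms[0].rotation_angle() < 1e-12 \
            and np.allclose(placement.transforms[0].translation, 0.0):
        return model
    chains = []
    sse = []
    for k, rt in enumerate(placement.transforms):
        copy = model.transformed(rt, chain_suffix=f"_s{k}")
        chains.extend(copy.chains)
        sse.extend(copy.sse)
    return AtomicModel(chains=chains, sse=sse)


def _rotate_about_z(data: np.ndarray, angle_deg: float, order: int = 3) -> np.ndarray:
    """Rotate a [z, y, x] volume about the +z axis through the n//2 center."""
    n = data.shape[0]
    rot = axis_rotation_matrix(np.array([0.0, 0.0, 1.0]), angle_deg)
    mat = rot.T[::-1, ::-1]
    center = np.full(3, n // 2, dtype=float)
    offset = center - mat @ center
    return ndimage.affine_transform(data, mat, offset=offset, order=order)


def fit_subunit_positions(
    subunit_volume: VolumeGrid,
    ring_volume: VolumeGrid,
    n_sym: int,
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
    angle_window: float = 15.0,
    angle_step: float = 1.0,
    translation_window: float = 0.0,
    score_floor: float = 0.2,
    support_threshold: float = 0.2,
) -> RingPlacement:
    """Fit the subunit density into each of the ``n_sym`` ring positions.

    For every position ``k`` a rotation about ``axis`` near ``k*360/n_sym``
    is scanned (coarse grid then parabolic refinement) maximizing the
    real-space Pearson correlation between the rotated subunit and the ring,
    computed over the subunit's support.  An optional small in-plane
    translation search (``translation_window`` in Angstrom) follows.
    Positions whose correlation stays below ``score_floor`` are flagged
    unreliable.  The correlation is evaluated over the subunit's support
    (voxels above ``support_threshold`` of its peak); the default 0.2 keeps
    the fit insensitive to density of the neighboring subunits leaking into
    the support's low tail.
    """
    if subunit_volume.pixel_size != ring_volume.pixel_size:
        raise ValueError("subunit and ring must share a pixel size")
    if not np.allclose(np.asarray(axis), (0.0, 0.0, 1.0)):
        raise NotImplementedError("fitting currently assumes the +z ring axis")
    sub = subunit_volume.data.astype(np.float64)
    ring = ring_volume.data.astype(np.float64)
    support = sub > support_threshold * sub.max()

    def corr_at(angle: float) -> float:
        rotated = _rotate_about_z(sub, angle)
        rotated_support = _rotate_about_z(support.astype(np.float64), angle) > 0.5
        sel = rotated_support
        if sel.sum() < 10:
            return -1.0
        a = rotated[sel]
        b = ring[sel]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        return float((a * b).sum() / denom) if denom > 0 else -1.0

    transforms = []
    scores = []
    unreliable = []
    pixel = ring_volume.pixel_size
    for k in range(n_sym):
        nominal = k * 360.0 / n_sym
        grid = np.arange(nominal - angle_window, nominal + angle_window + 1e-9, angle_step)
        vals = np.array([corr_at(a) for a in grid])
        i = int(np.argmax(vals))
        best_angle = grid[i]
        best_val = vals[i]
        if 0 < i < len(grid) - 1:
            # parabolic sub-step refinement
            y0, y1, y2 = vals[i - 1], vals[i], vals[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                best_angle = grid[i] + 0.5 * (y0 - y2) / denom * angle_step
                best_val = float(corr_at(best_angle))
        translation = np.zeros(3)
        if translation_window > 0:
            rotated = _rotate_about_z(sub, best_angle)
            translation, best_val = _refine_translation(
                rotated, ring, pixel, translation_window, best_val
            )
        flag = best_val < score_floor
        if flag:
            logger.warning(
                "fit position %d: correlation %.3f below floor %.3f",
                k, best_val, score_floor,
            )
        transforms.append(
            TransformRT(
                rotation=axis_rotation_matrix(np.asarray(axis), best_angle),
                translation=translation,
            )
        )
        scores.append(float(best_val))
        unreliable.append(bool(flag))
    return RingPlacement(
        transforms=transforms, n_sym=n_sym, axis=axis, scores=scores,
        unreliable=unreliable,
    )


def _refine_translation(
    rotated: np.ndarray,
    ring: np.ndarray,
    pixel: float,
    window: float,
    fallback_score: float,
) -> tuple[np.ndarray, float]:
    """Integer-voxel in-plane translation search within ``window`` Angstrom."""
    max_vox = int(window / pixel)
    if max_vox < 1:
        return np.zeros(3), fallback_score
    best = (0, 0)
    best_val = -np.inf
    support = rotated > 0.2 * rotated.max()
    for dy in range(-max_vox, max_vox + 1):
        for dx in range(-max_vox, max_vox + 1):
            shifted_ring = np.roll(ring, (-dy, -dx), axis=(1, 2))
            sel = support
            a = rotated[sel] - rotated[sel].mean()
            b = shifted_ring[sel] - shifted_ring[sel].mean()
            denom = np.sqrt((a**2).sum() * (b**2).sum())
            val = float((a * b).sum() / denom) if denom > 0 else -1.0
            if val > best_val:
                best_val = val
                best = (dx, dy)
    return np.array([best[0] * pixel, best[1] * pixel, 0.0]), best_val


@dataclass(frozen=True)
class RingDiameters:
    """Ring diameters from Calpha radial distances about the axis (A)."""

    inner: float
    outer: float
    inner_robust: float  # 1st percentile radius x 2
    outer_robust: float  # 99th percentile radius x 2


def ring_diameters(
    model: AtomicModel, axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
) -> RingDiameters:
    """Min/max (and robust percentile) Calpha diameters about the ring axis."""
    if len(model.chains) < 2:
        logger.warning("ring_diameters on a single-chain model reflects one wedge")
    axis_v = np.asarray(axis, dtype=float)
    axis_v = axis_v / np.linalg.norm(axis_v)
    coords = model.ca_coords()
    axial = coords @ axis_v
    radial = coords - axial[:, None] * axis_v
    r = np.linalg.norm(radial, axis=1)
    return RingDiameters(
        inner=float(2 * r.min()),
        outer=float(2 * r.max()),
        inner_robust=float(2 * np.percentile(r, 1)),
        outer_robust=float(2 * np.percentile(r, 99)),
    )
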