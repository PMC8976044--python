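"""Synthetic ground-truth generators: ring volumes, particle stacks, toy models.

Everything here is a pure function of its spec and seed, so downstream
stages (reconstruction, subparticle bookkeeping, structural analysis) can be
tested end-to-end without external data.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .ctf_projection import CTFParams, FourierProjector, evaluate_ctf
from .geometry import TransformRT, axis_rotation_matrix
from .io_formats import (
    AtomicModel,
    Chain,
    ImageStack,
    ParticleRecord,
    ParticleTable,
    Residue,
    SSEAnnotation,
    VolumeGrid,
)

__all__ = [
    "PseudoAtom",
    "RingSpec",
    "CollectionSpec",
    "default_motif",
    "make_toy_ring_volume",
    "simulate_particles",
    "make_toy_models",
]


@dataclass(frozen=True)
class PseudoAtom:
    """Gaussian blob: offset from the subunit center (A), weight, width (A)."""

    position: tuple[float, float, float]
    weight: float = 1.0
    sigma: float = 3.0


def default_motif() -> list[PseudoAtom]:
    """Six Gaussians in a chiral arrangement (all three Euler angles are
    identifiable from projections).

    The axial spread (z from -24 to +28 A) is deliberately large so that
    small tilts remain identifiable in near-top views: a feature at height z
    moves by ~z*sin(tilt) in projection, which must exceed a pixel for the
    tilt grid steps used in refinement tests.
    """
    return [
        PseudoAtom((0.0, 0.0, -6.0), 1.4, 6.0),
        PseudoAtom((11.0, 0.0, 6.0), 1.0, 5.0),
        PseudoAtom((0.0, 12.0, 0.0), 1.2, 5.0),
        PseudoAtom((0.0, 0.0, 28.0), 1.0, 5.0),
        PseudoAtom((8.0, 8.0, -24.0), 0.8, 5.0),
        PseudoAtom((-7.0, 6.0, 18.0), 0.9, 5.0),
    ]


@dataclass(frozen=True)
class RingSpec:
    """C-symmetric ring of Gaussian-blob subunits."""

    ring_radius: float
    n_sym: int = 8
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    motif: list[PseudoAtom] = field(default_factory=default_motif)

    def __post_init__(self) -> None:
        if self.n_sym < 1:
            raise ValueError("n_sym must be >= 1")
        if self.ring_radius <= 0:
            raise ValueError("ring_radius must be positive")
        if not self.motif:
            raise ValueError("motif must be non-empty")

    def subunit_center(self) -> np.ndarray:
        """Center of the canonical (k = 0) subunit in the ring frame."""
        return np.array([self.ring_radius, 0.0, 0.0])

    def symmetry_matrices(self) -> list[np.ndarray]:
        return [
            axis_rotation_matrix(np.asarray(self.axis), k * 360.0 / self.n_sym)
            for k in range(self.n_sym)
        ]


@dataclass(frozen=True)
class CollectionSpec:
    """Imaging-model parameters for a simulated tilted collection."""

    n_particles: int
    snr: float = 1.0
    tilt_angles: tuple[float, ...] = (0.0, 30.0, 45.0, 55.0)
    tilt_weights: tuple[float, ...] | None = None
    tilt_jitter_sd: float = 2.0
    defocus_range: tuple[float, float] = (15000.0, 30000.0)
    shift_range: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.defocus_range
        if not (0 < lo <= hi):
            raise ValueError("defocus_range must be positive and ordered")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.tilt_weights is not None and len(self.tilt_weights) != len(
            self.tilt_angles
        ):
            raise ValueError("tilt_weights must match tilt_angles")


_CHAIN_LETTERS = string.ascii_uppercase


def _subunit_chain_id(k: int) -> str:
    if k < len(_CHAIN_LETTERS):
        return _CHAIN_LETTERS[k]
    return f"S{k}"


def make_toy_ring_volume(
    ring_spec: RingSpec, grid_n: int, pixel_size: float, seed: int = 0
) -> tuple[VolumeGrid, AtomicModel]:
    """Rasterize the C-symmetric ring of Gaussian blobs onto a cubic grid.

    Returns the density plus a ground-truth pseudo-atom model with one chain
    per subunit copy.  Raises if the ring (plus 4 sigma of blob support)
    does not fit inside the grid, stating the minimum grid size required.
    """
    del seed  # generator is deterministic; kept for API uniformity
    center0 = ring_spec.subunit_center()
    extent = max(
        np.linalg.norm(center0 + np.asarray(a.position)) + 4 * a.sigma
        for a in ring_spec.motif
    )
    half_box = grid_n * pixel_size / 2.0
    if extent >= half_box:
        needed = int(np.ceil(2 * extent / pixel_size / 2.0) * 2)
        raise ValueError(
            f"ring (extent {extent:.1f} A) exceeds the grid half-width "
            f"{half_box:.1f} A; use grid_n >= {needed}"
        )

    n = grid_n
    data = np.zeros((n, n, n), dtype=np.float64)
    axis_coords = np.arange(n) - n // 2
    chains = []
    for k, sym in enumerate(ring_spec.symmetry_matrices()):
        residues = []
        for i, atom in enumerate(ring_spec.motif, start=1):
            pos = sym @ (center0 + np.asarray(atom.position))
            residues.append(Residue(number=i, aa="ALA", ca=pos.copy()))
            _splat_gaussian(data, axis_coords, pos, atom.weight, atom.sigma, pixel_size)
        chains.append(
            Chain(
                chain_id=_subunit_chain_id(k),
                entity_name="subunit",
                residues=residues,
                copy_label=str(k),
            )
        )
    volume = VolumeGrid(data=data, pixel_size=pixel_size)
    return volume, AtomicModel(chains=chains)


def _splat_gaussian(
    data: np.ndarray,
    axis_coords: np.ndarray,
    pos: np.ndarray,
    weight: float,
    sigma: float,
    pixel_size: float,
) -> None:
    """Add a Gaussian of physical width sigma (A) over its +-4 sigma support."""
    n = data.shape[0]
    pos_vox = pos / pixel_size + n // 2  # (x, y, z) in voxel units
    half = 4.0 * sigma / pixel_size
    los = np.maximum(np.floor(pos_vox - half).astype(int), 0)
    his = np.minimum(np.ceil(pos_vox + half).astype(int) + 1, n)
    if np.any(los >= his):
        return
    xs = axis_coords[los[0] : his[0]] * pixel_size - pos[0]
    ys = axis_coords[los[1] : his[1]] * pixel_size - pos[1]
    zs = axis_coords[los[2] : his[2]] * pixel_size - pos[2]
    zz, yy, xx = np.meshgrid(zs, ys, xs, indexing="ij")
    blob = weight * np.exp(-(xx**2 + yy**2 + zz**2) / (2.0 * sigma**2))
    data[los[2] : his[2], los[1] : his[1], los[0] : his[0]] += blob


def soft_disc_weights(box: int, radius_frac: float = 0.45, edge_px: float = 2.0) -> np.ndarray:
    """Soft circular mask used in the SNR definition (radius 0.45 box)."""
    axis = np.arange(box) - box // 2
    yy, xx = np.meshgrid(axis, axis, indexing="ij")
    r = np.hypot(xx, yy)
    radius = radius_frac * box
    w = np.clip((radius + edge_px / 2 - r) / edge_px, 0.0, 1.0)
    return np.sin(w * np.pi / 2) ** 2


def _masked_variance(image: np.ndarray, weights: np.ndarray) -> float:
    total = weights.sum()
    mean = float((weights * image).sum() / total)
    return float((weights * (image - mean) ** 2).sum() / total)


def simulate_particles(
    volume: VolumeGrid, spec: CollectionSpec, stack_name: str = "simulated.mrcs"
) -> tuple[ImageStack, ParticleTable]:
    """Simulate a tilted-collection particle stack from a reference volume.

    Per particle: uniform ``rot``/``psi``, ``tilt`` drawn from the collection
    tilt angles plus Gaussian jitter, CTF with defocus uniform in range,
    then white Gaussian noise scaled so that the variance ratio of the
    CTF-filtered signal to noise inside a soft disc equals ``spec.snr``.
    The returned table carries the ground-truth poses.
    """
    rng = np.random.default_rng(spec.seed)
    n = volume.n
    pixel = volume.pixel_size
    projector = FourierProjector(volume)
    disc = soft_disc_weights(n)

    n_tilts = len(spec.tilt_angles)
    weights = (
        np.asarray(spec.tilt_weights, dtype=float)
        if spec.tilt_weights is not None
        else np.ones(n_tilts)
    )
    weights = weights / weights.sum()

    # draw all pose/CTF randomness up front so runs that differ only in the
    # noise setting (e.g. snr=inf references) share identical ground truth
    m = spec.n_particles
    rots = rng.uniform(-180.0, 180.0, m)
    psis = rng.uniform(-180.0, 180.0, m)
    tilt_classes = rng.choice(n_tilts, size=m, p=weights)
    tilts = np.clip(
        np.asarray(spec.tilt_angles)[tilt_classes]
        + rng.normal(0.0, spec.tilt_jitter_sd, m),
        0.0,
        180.0,
    )
    shifts = rng.uniform(-spec.shift_range, spec.shift_range, size=(m, 2))
    defoci = rng.uniform(*spec.defocus_range, size=m)

    images = np.empty((m, n, n), dtype=np.float32)
    records = []
    for i in range(m):
        ctf = evaluate_ctf(
            CTFParams(defocus_u=defoci[i], defocus_v=defoci[i]), n, pixel
        )
        signal = projector.project(
            rots[i], tilts[i], psis[i],
            shift=(shifts[i, 0], shifts[i, 1]), ctf=ctf,
        )
        sig_var = _masked_variance(signal, disc)
        realized_snr = np.inf
        if np.isfinite(spec.snr):
            noise = rng.normal(0.0, np.sqrt(sig_var / spec.snr), size=(n, n))
            realized_snr = sig_var / _masked_variance(noise, disc)
            signal = signal + noise
        images[i] = signal.astype(np.float32)
        records.append(
            ParticleRecord(
                image_name=stack_name,
                image_index=i,
                rot=float(rots[i]),
                tilt=float(tilts[i]),
                psi=float(psis[i]),
                shift_x=float(shifts[i, 0]),
                shift_y=float(shifts[i, 1]),
                defocus_u=float(defoci[i]),
                defocus_v=float(defoci[i]),
                astig_angle=0.0,
                pixel_size=pixel,
                group_id=int(tilt_classes[i]),
                extras={"_ringrecSnr": f"{realized_snr:.4f}"},
            )
        )
    stack = ImageStack(data=images, pixel_size=pixel, name=stack_name)
    table = ParticleTable.from_records(records, provenance="simulated bin1")
    return stack, table


# ---------------------------------------------------------------------------
# toy atomic-model fixtures
# ---------------------------------------------------------------------------


def _ideal_helix(n_res: int, start: np.ndarray, direction_z: bool = True) -> np.ndarray:
    """Calpha trace of an ideal alpha-helix (rise 1.5 A, 100 deg/residue)."""
    t = np.arange(n_res)
    angle = np.deg2rad(100.0 * t)
    coords = np.stack(
        [2.3 * np.cos(angle), 2.3 * np.sin(angle), 1.5 * t], axis=1
    )
    return coords + start


def make_toy_models(
    seed: int, jitter_sd: float = 0.0
) -> tuple[AtomicModel, AtomicModel, TransformRT, list]:
    """Build two-chain fixture models for superposition and contact tests.

    Model A has a helix chain and a partner chain whose loop runs along the
    helix (a planted helix-loop interface).  Model B is A moved by a random
    rigid transform plus optional per-atom Gaussian jitter.  The returned
    contact list is computed by brute-force all-pairs Calpha distances at
    the default 8 A cutoff.
    """
    from .struct_analysis import CA_CONTACT_CUTOFF, ContactRecord

    rng = np.random.default_rng(seed)

    helix = _ideal_helix(30, np.zeros(3))
    tail = np.stack(
        [
            6.0 + 1.2 * np.arange(10),
            np.full(10, 3.0),
            np.full(10, 47.0),
        ],
        axis=1,
    )
    chain_x_coords = np.concatenate([helix, tail])
    # partner loop running parallel to the helix at ~6.5 A from its axis,
    # then a short helix leading away
    loop = np.stack(
        [
            np.full(12, 6.5),
            np.full(12, 1.0),
            3.0 * np.arange(12) + 2.0,
        ],
        axis=1,
    )
    away = _ideal_helix(15, np.array([25.0, 25.0, 40.0]))
    chain_y_coords = np.concatenate([loop, away])

    def build(coords_x: np.ndarray, coords_y: np.ndarray) -> AtomicModel:
        chains = [
            Chain(
                chain_id="X",
                entity_name="protA",
                residues=[
                    Residue(number=i + 1, aa="ALA", ca=c)
                    for i, c in enumerate(coords_x)
                ],
                copy_label="single",
            ),
            Chain(
                chain_id="Y",
                entity_name="protB",
                residues=[
                    Residue(number=i + 1, aa="GLY", ca=c)
                    for i, c in enumerate(coords_y)
                ],
                copy_label="single",
            ),
        ]
        sse = [
            SSEAnnotation("helix_a1", "X", 1, 30),
            SSEAnnotation("loop_t1", "X", 31, 40),
            SSEAnnotation("loop_l1", "Y", 1, 12),
            SSEAnnotation("helix_a2", "Y", 13, 27),
        ]
        return AtomicModel(chains=chains, sse=sse)

    model_a = build(chain_x_coords, chain_y_coords)

    true_rt = TransformRT(
        rotation=Rotation.random(rng=rng).as_matrix(),
        translation=rng.uniform(-20.0, 20.0, size=3),
    )
    bx = true_rt.apply(chain_x_coords)
    by = true_rt.apply(chain_y_coords)
    if jitter_sd > 0:
        bx = bx + rng.normal(0.0, jitter_sd, bx.shape)
        by = by + rng.normal(0.0, jitter_sd, by.shape)
    model_b = build(bx, by)

    contacts = []
    for res_x in model_a.chain("X").residues:
        for res_y in model_a.chain("Y").residues:
            dist = float(np.linalg.norm(res_x.ca - res_y.ca))
            if dist <= CA_CONTACT_CUTOFF:
                contacts.append(
                    ContactRecord(
                        chain_a="X",
                        residue_a=res_x.number,
                        sse_a=model_a.sse_label_for("X", res_x.number),
                        chain_b="Y",
                        residue_b=res_y.number,
                        sse_b=model_a.sse_label_for("Y", res_y.number),
                        distance=dist,
                        mode="ca",
                    )
                )
    contacts.sort(key=lambda c: (c.chain_a, c.residue_a, c.chain_b, c.residue_b))
    return model_a, model_b, true_rt, contacts
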