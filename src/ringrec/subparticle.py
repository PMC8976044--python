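"""Symmetry expansion, subparticle re-centering/extraction and local refinement.

This is the block-based processing stage: each ring particle is replicated
once per symmetry operator, re-centered on one subunit (updating shifts,
integer extraction offsets and the axial defocus component), cut out into a
smaller box, and locally refined against a subunit reference with a confined
exhaustive grid search.

Defocus sign convention: ``+z`` of the rotated (particle) frame points away
from the focal plane toward larger underfocus, so a subunit whose center
maps to ``q`` in the particle frame acquires ``defocus + q_z``.  The
convention is validated against the simulator, not against any external
metadata dialect.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft

from .ctf_projection import CTFParams, FourierProjector, evaluate_ctf
from .geometry import axis_rotation_matrix, euler_to_matrix, matrix_to_euler
from .io_formats import ImageStack, ParticleTable, VolumeGrid

logger = logging.getLogger(__name__)

__all__ = [
    "SubunitFrame",
    "symmetry_expand",
    "recenter_subparticles",
    "extract_subparticles",
    "local_refine",
    "OFFSET_X_TAG",
    "OFFSET_Y_TAG",
]

OFFSET_X_TAG = "_ringrecOffsetXPx"
OFFSET_Y_TAG = "_ringrecOffsetYPx"
SCORE_TAG = "_ringrecScore"


@dataclass(frozen=True)
class SubunitFrame:
    """Location of the canonical subunit in the ring reference frame."""

    center: tuple[float, float, float]
    n_sym: int = 8
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        radial = center - (center @ axis) * axis
        if self.n_sym > 1 and np.linalg.norm(radial) < 1e-9:
            raise ValueError(
                "subunit center lies on the symmetry axis; copies would coincide"
            )


def symmetry_expand(
    table: ParticleTable,
    n_sym: int,
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> ParticleTable:
    """Replicate each record once per symmetry operator.

    Record ``k`` gets pose ``R @ S_k`` (``S_k`` = rotation by ``k*360/n_sym``
    about ``axis``) and ``subunit_index = k``; shifts and defoci are copied.
    With ``n_sym=1`` the table is returned unchanged (minus no-op copy).
    """
    if n_sym < 1:
        raise ValueError("n_sym must be >= 1")
    if n_sym == 1:
        return table.copy()
    sym_mats = [axis_rotation_matrix(np.asarray(axis), k * 360.0 / n_sym) for k in range(n_sym)]
    df = table.df
    rows = []
    for i in range(len(df)):
        row = df.iloc[i]
        base = euler_to_matrix(row["rot"], row["tilt"], row["psi"])
        for k, sym in enumerate(sym_mats):
            rot, tilt, psi = matrix_to_euler(base @ sym)
            new = row.copy()
            new["rot"], new["tilt"], new["psi"] = rot, tilt, psi
            new["subunit_index"] = k
            rows.append(new)
    import pandas as pd

    out = pd.DataFrame(rows).reset_index(drop=True)
    return table.with_rows(out, provenance=f"{table.provenance} expanded C{n_sym}".strip())


def recenter_subparticles(
    table: ParticleTable,
    frame: SubunitFrame,
    src_box: int | None = None,
) -> ParticleTable:
    """Re-center each (symmetry-expanded) record on its subunit.

    For each record with pose ``R``: ``q = R @ center`` is the subunit
    position in the particle frame.  The in-plane part moves the extraction
    window — the integer pixel offset is stored in the offset columns and
    the fractional remainder stays in the shift fields — and the axial part
    adjusts the defocus (``defocus += q_z``).  Records whose subunit center
    falls outside the source box (when ``src_box`` is given) are excluded
    and counted in the log.
    """
    center = np.asarray(frame.center, dtype=float)
    df = table.df.copy()
    pixel = table.pixel_size
    n = len(df)
    offs_x = np.zeros(n, dtype=int)
    offs_y = np.zeros(n, dtype=int)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        row = df.iloc[i]
        rotation = euler_to_matrix(row["rot"], row["tilt"], row["psi"])
        q = rotation @ center
        # integer window offset from the subunit displacement only; the
        # fractional remainder (plus any pre-existing shift) stays in the
        # shift fields
        ox = int(np.round(q[0] / pixel))
        oy = int(np.round(q[1] / pixel))
        if src_box is not None and (abs(ox) >= src_box // 2 or abs(oy) >= src_box // 2):
            keep[i] = False
            continue
        offs_x[i] = ox
        offs_y[i] = oy
        df.iloc[i, df.columns.get_loc("shift_x")] = row["shift_x"] + q[0] - ox * pixel
        df.iloc[i, df.columns.get_loc("shift_y")] = row["shift_y"] + q[1] - oy * pixel
        df.iloc[i, df.columns.get_loc("defocus_u")] = row["defocus_u"] + q[2]
        df.iloc[i, df.columns.get_loc("defocus_v")] = row["defocus_v"] + q[2]
    df[OFFSET_X_TAG] = offs_x
    df[OFFSET_Y_TAG] = offs_y
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.warning("recenter: excluded %d subparticles outside the box", n_excluded)
    df = df[keep].reset_index(drop=True)
    return table.with_rows(df, provenance=f"{table.provenance} recentered".strip())


def extract_subparticles(
    stack: ImageStack,
    table: ParticleTable,
    box: int,
    stack_name: str = "subparticles.mrcs",
) -> tuple[ImageStack, ParticleTable]:
    """Cut sub-boxes at the integer offsets computed by re-centering.

    Windows extending beyond the source image are padded with the source
    image mean (flagged in the log).  Image references are rewritten to the
    new stack; offset columns are consumed.
    """
    src = stack.box
    if box > src:
        raise ValueError(f"box {box} larger than source image size {src}")
    if OFFSET_X_TAG not in table.df.columns:
        raise ValueError("table has no extraction offsets; run recenter first")
    df = table.df.copy()
    n = len(df)
    half = box // 2
    out = np.empty((n, box, box), dtype=np.float32)
    n_padded = 0
    for i in range(n):
        row = df.iloc[i]
        img = stack.data[int(row["image_index"])]
        cy = src // 2 + int(row[OFFSET_Y_TAG])
        cx = src // 2 + int(row[OFFSET_X_TAG])
        y0, y1 = cy - half, cy + box - half
        x0, x1 = cx - half, cx + box - half
        if y0 < 0 or x0 < 0 or y1 > src or x1 > src:
            n_padded += 1
            window = np.full((box, box), img.mean(), dtype=np.float32)
            sy0, sy1 = max(y0, 0), min(y1, src)
            sx0, sx1 = max(x0, 0), min(x1, src)
            window[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = img[sy0:sy1, sx0:sx1]
            out[i] = window
        else:
            out[i] = img[y0:y1, x0:x1]
    if n_padded:
        logger.warning("extract: %d windows padded at image edges", n_padded)
    df["image_name"] = stack_name
    df["image_index"] = np.arange(n)
    df = df.drop(columns=[OFFSET_X_TAG, OFFSET_Y_TAG])
    new_table = table.with_rows(df, provenance=f"{table.provenance} box{box}".strip())
    return ImageStack(data=out, pixel_size=stack.pixel_size, name=stack_name), new_table


def _delta_grid(rng: float, step: float) -> np.ndarray:
    if rng < 0 or step < 0:
        raise ValueError("search range and step must be non-negative")
    if rng == 0 or step == 0:
        return np.array([0.0])
    n = int(np.floor(rng / step + 1e-9))
    return np.arange(-n, n + 1) * step


def _wrap_bilinear(cc: np.ndarray, sy: np.ndarray, sx: np.ndarray) -> np.ndarray:
    """Bilinear sample of batched cc maps ``(n_rot, n, n)`` at wrapped pixel
    shifts ``sy``/``sx`` of shape ``(n_shift,)``; returns ``(n_rot, n_shift)``."""
    n = cc.shape[-1]
    y0 = np.floor(sy).astype(int)
    x0 = np.floor(sx).astype(int)
    fy = sy - y0
    fx = sx - x0
    val = np.zeros((cc.shape[0], len(sy)))
    for dy in (0, 1):
        wy = fy if dy else 1.0 - fy
        for dx in (0, 1):
            wx = fx if dx else 1.0 - fx
            val = val + wy * wx * cc[:, (y0 + dy) % n, (x0 + dx) % n]
    return val


def local_refine(
    stack: ImageStack,
    reference: VolumeGrid,
    table: ParticleTable,
    angular_range: float,
    angular_step: float,
    shift_range: float,
    shift_step: float,
    rounds: int = 1,
    ctf_kwargs: dict | None = None,
    interp_order: int = 1,
    final_order: int = 1,
    oversample: int = 2,
) -> ParticleTable:
    """Confined exhaustive grid search over pose and shift perturbations.

    Per record the score is the normalized (zero-mean) cross-correlation
    between the particle image and the CTF-filtered projection of the
    reference at the perturbed pose; the arg-max wins, ties broken toward
    the smallest perturbation norm and then lexicographically, so runs are
    bit-stable.  ``rounds > 1`` repeats the search centered on the current
    best pose with halved steps.

    Rounds score with fast trilinear slices by default (``interp_order``);
    setting ``final_order=3`` switches the last round to cubic-spline
    interpolation of the reference spectrum (~10x lower projection error,
    ~3x slower).

    Angular quantities in degrees, shifts in Angstrom.
    """
    if stack.box != reference.n:
        raise ValueError("reference and stack box sizes differ")
    d_ang = _delta_grid(angular_range, angular_step)
    d_sh = _delta_grid(shift_range, shift_step)
    if len(d_ang) == 0 or len(d_sh) == 0:
        raise ValueError("empty search grid")

    projector = FourierProjector(
        reference, oversample=oversample, order=max(interp_order, final_order)
    )
    n = stack.box
    pixel = table.pixel_size
    half = n // 2
    ctf_kwargs = ctf_kwargs or {}
    k1d = np.fft.fftshift(np.fft.fftfreq(n, d=pixel))
    freq_y, freq_x = np.meshgrid(k1d, k1d, indexing="ij")  # cycles/A, centered

    df = table.df.copy()
    scores = np.zeros(len(df))
    for round_idx in range(rounds):
        order = final_order if round_idx == rounds - 1 else interp_order
        scale = 0.5**round_idx
        ang_deltas = d_ang * scale
        sh_deltas = d_sh * scale
        # deterministic tie-break order: smallest perturbation norm, then lex
        ang_combos = sorted(
            itertools.product(ang_deltas, repeat=3),
            key=lambda t: (t[0] ** 2 + t[1] ** 2 + t[2] ** 2, t),
        )
        sh_combos = sorted(
            itertools.product(sh_deltas, repeat=2),
            key=lambda t: (t[0] ** 2 + t[1] ** 2, t),
        )
        ang_combos = np.array(ang_combos)
        sh_combos = np.array(sh_combos)

        for i in range(len(df)):
            row = df.iloc[i]
            img = stack.data[int(row["image_index"])].astype(np.float64)
            img_f = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img)))
            img_f[half, half] = 0.0
            ctf = evaluate_ctf(
                CTFParams(
                    defocus_u=row["defocus_u"],
                    defocus_v=row["defocus_v"],
                    astig_angle=row["astig_angle"],
                    **ctf_kwargs,
                ),
                n,
                pixel,
            )
            rotations = np.stack(
                [
                    euler_to_matrix(row["rot"] + da[0], row["tilt"] + da[1], row["psi"] + da[2])
                    for da in ang_combos
                ]
            )
            slabs = projector.slice_batch(rotations, order=order)
            slabs = (slabs * ctf).astype(np.complex64)
            slabs[:, half, half] = 0.0
            norms = np.sqrt(np.sum(np.abs(slabs) ** 2, axis=(1, 2)))
            norms[norms == 0] = np.inf
            img_norm = np.sqrt(np.sum(np.abs(img_f) ** 2))

            sx = np.asarray(row["shift_x"] + sh_combos[:, 0])
            sy = np.asarray(row["shift_y"] + sh_combos[:, 1])
            if round_idx == rounds - 1:
                # exact phase-sum scores: no interpolation bias at the
                # (generally fractional-pixel) candidate shifts
                cross = (
                    img_f.astype(np.complex64).ravel()[None, :]
                    * np.conj(slabs.reshape(len(rotations), -1))
                )
                phases = np.exp(
                    2j * np.pi
                    * (freq_x.ravel()[None, :] * sx[:, None]
                       + freq_y.ravel()[None, :] * sy[:, None])
                ).astype(np.complex64)
                vals = (cross @ phases.T).real / (norms[:, None] * img_norm)
            else:
                cc = spfft.ifft2(
                    np.fft.ifftshift(
                        img_f.astype(np.complex64) * np.conj(slabs), axes=(-2, -1)
                    ),
                    axes=(-2, -1),
                ).real
                # candidate shifts in pixels, wrapped into the cc maps
                vals = _wrap_bilinear(cc, sy / pixel, sx / pixel)
                vals = vals * n * n / (norms[:, None] * img_norm)

            flat = np.argmax(vals)
            best_r, best_s = np.unravel_index(flat, vals.shape)
            da = ang_combos[best_r]
            ds = sh_combos[best_s]
            # canonicalize through the matrix so tilt stays in [0, 180]
            # without corrupting the scored rotation
            rot_n, tilt_n, psi_n = matrix_to_euler(rotations[best_r])
            df.iloc[i, df.columns.get_loc("rot")] = rot_n
            df.iloc[i, df.columns.get_loc("tilt")] = tilt_n
            df.iloc[i, df.columns.get_loc("psi")] = psi_n
            df.iloc[i, df.columns.get_loc("shift_x")] = row["shift_x"] + ds[0]
            df.iloc[i, df.columns.get_loc("shift_y")] = row["shift_y"] + ds[1]
            scores[i] = vals[best_r, best_s]
    df[SCORE_TAG] = [f"{s:.6f}" for s in scores]
    return table.with_rows(df, provenance=f"{table.provenance} refined".strip())
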