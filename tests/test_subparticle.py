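import numpy as np
import pytest

from ringrec.ctf_projection import compute_fsc, project, reconstruct, resolution_at
from ringrec.geometry import TransformRT, axis_rotation_matrix, euler_to_matrix
from ringrec.io_formats import ImageStack, ParticleRecord, ParticleTable
from ringrec.subparticle import (
    OFFSET_X_TAG,
    OFFSET_Y_TAG,
    SubunitFrame,
    extract_subparticles,
    local_refine,
    recenter_subparticles,
    symmetry_expand,
)
from ringrec.synthetic_data import CollectionSpec, RingSpec, simulate_particles, make_toy_ring_volume

from conftest import SMALL_GRID, SMALL_PIXEL, SMALL_RADIUS


# ---------------------------------------------------------------------------
# symmetry expansion
# ---------------------------------------------------------------------------


def test_expand_nsym1_is_identity(ten_row_table):
    out = symmetry_expand(ten_row_table, 1)
    assert out.df.drop(columns=[], errors="ignore").equals(ten_row_table.df)


def test_expand_multiplies_rows(ten_row_table):
    out = symmetry_expand(ten_row_table, 8)
    assert len(out) == 80
    assert sorted(set(out.column("subunit_index"))) == list(range(8))


def test_expand_identity_pose_inplane_angles_differ_by_45():
    table = ParticleTable.from_records(
        [ParticleRecord(image_name="s", image_index=0, pixel_size=2.0)]
    )
    out = symmetry_expand(table, 8)
    mats = [euler_to_matrix(r.rot, r.tilt, r.psi) for r in out.records()]
    for k in range(7):
        delta = TransformRT(rotation=mats[k].T @ mats[k + 1]).rotation_angle()
        assert delta == pytest.approx(45.0, abs=1e-9)


def test_expand_composes_rotation_matrices(ten_row_table):
    out = symmetry_expand(ten_row_table, 4)
    base = ten_row_table.records()
    sym = [axis_rotation_matrix(np.array([0.0, 0.0, 1.0]), 90.0 * k) for k in range(4)]
    for i, rec in enumerate(out.records()):
        expected = euler_to_matrix(
            base[i // 4].rot, base[i // 4].tilt, base[i // 4].psi
        ) @ sym[i % 4]
        got = euler_to_matrix(rec.rot, rec.tilt, rec.psi)
        assert np.abs(got - expected).max() < 1e-9


def test_expanded_ring_projections_match_original(small_ring):
    """Projecting the C8 ring at each expanded pose reproduces the original
    projection (the ring is C8-symmetric)."""
    vol, _ = small_ring
    table = ParticleTable.from_records(
        [ParticleRecord(image_name="s", image_index=0, rot=25.0, tilt=40.0,
                        psi=-60.0, pixel_size=SMALL_PIXEL)]
    )
    base_img = project(vol, 25.0, 40.0, -60.0)
    for rec in symmetry_expand(table, 8).records():
        img = project(vol, rec.rot, rec.tilt, rec.psi)
        assert np.abs(img - base_img).max() < 0.01 * np.abs(base_img).max()


# ---------------------------------------------------------------------------
# re-centering
# ---------------------------------------------------------------------------


def test_recenter_zero_center_is_noop(ten_row_table):
    frame = SubunitFrame(center=(0.0, 0.0, 0.0), n_sym=1)
    out = recenter_subparticles(ten_row_table, frame)
    for a, b in zip(ten_row_table.records(), out.records()):
        assert b.shift_x == pytest.approx(a.shift_x)
        assert b.shift_y == pytest.approx(a.shift_y)
        assert b.defocus_u == pytest.approx(a.defocus_u)


def test_recenter_axial_center_shifts_defocus_only():
    c = 120.0
    table = ParticleTable.from_records(
        [ParticleRecord(image_name="s", image_index=0, defocus_u=20000.0,
                        defocus_v=21000.0, pixel_size=2.0)]
    )
    frame = SubunitFrame(center=(0.0, 0.0, c), n_sym=1)
    rec = recenter_subparticles(table, frame).records()[0]
    assert rec.defocus_u == pytest.approx(20000.0 + c)
    assert rec.defocus_v == pytest.approx(21000.0 + c)
    assert rec.shift_x == pytest.approx(0.0)
    assert rec.shift_y == pytest.approx(0.0)


def test_recenter_defocus_matches_simulation_oracle(small_sim):
    """Adjusted defocus equals particle defocus plus the independently
    computed axial component of the rotated subunit center."""
    from scipy.spatial.transform import Rotation

    _, table = small_sim
    frame = SubunitFrame(center=(SMALL_RADIUS, 0.0, 0.0), n_sym=8)
    expanded = symmetry_expand(table, 8)
    recentered = recenter_subparticles(expanded, frame)
    base = {i: r for i, r in enumerate(table.records())}
    center = np.array([SMALL_RADIUS, 0.0, 0.0])
    n_checked = 0
    for rec in recentered.records():
        src = base[rec.image_index]
        rot_m = Rotation.from_euler(
            "ZYZ", [src.rot, src.tilt, src.psi], degrees=True
        ).as_matrix()
        sym = Rotation.from_rotvec(
            [0, 0, np.deg2rad(45.0 * rec.subunit_index)]
        ).as_matrix()
        qz = (rot_m @ sym @ center)[2]
        assert rec.defocus_u == pytest.approx(src.defocus_u + qz, abs=1e-6)
        n_checked += 1
    assert n_checked == 8 * len(table)


def test_recenter_fractional_shift_bookkeeping():
    """Integer offset plus fractional remainder reconstructs the full shift."""
    table = ParticleTable.from_records(
        [ParticleRecord(image_name="s", image_index=0, rot=0.0, tilt=0.0,
                        psi=0.0, shift_x=1.3, shift_y=-2.2, pixel_size=2.0)]
    )
    frame = SubunitFrame(center=(37.0, 5.0, 0.0), n_sym=8)
    out = recenter_subparticles(table, frame)
    rec = out.records()[0]
    ox = rec.extras[OFFSET_X_TAG]
    oy = rec.extras[OFFSET_Y_TAG]
    # offset captures the subunit displacement to the nearest pixel; the
    # remainder plus the old shift stays in the shift fields
    assert ox == round(37.0 / 2.0)
    assert oy == round(5.0 / 2.0)
    assert rec.shift_x + ox * 2.0 == pytest.approx(1.3 + 37.0)
    assert rec.shift_y + oy * 2.0 == pytest.approx(-2.2 + 5.0)


def test_recenter_excludes_out_of_box(small_sim):
    _, table = small_sim
    # absurdly distant center: everything lands outside a tiny source box
    frame = SubunitFrame(center=(1e4, 0.0, 0.0), n_sym=8)
    expanded = symmetry_expand(table, 8)
    out = recenter_subparticles(expanded, frame, src_box=SMALL_GRID)
    assert len(out) == 0 or len(out) < len(expanded)


def test_subunit_frame_rejects_on_axis_center():
    with pytest.raises(ValueError, match="axis"):
        SubunitFrame(center=(0.0, 0.0, 5.0), n_sym=8)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def _stack_with_blob(q_px=(7, -5), n=48):
    img = np.zeros((n, n), dtype=np.float32)
    yy, xx = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    cy, cx = n // 2 + q_px[1], n // 2 + q_px[0]
    img += np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * 2.0**2))
    return ImageStack(img[None], pixel_size=2.0)


def _offset_table(ox, oy, pixel=2.0):
    table = ParticleTable.from_records(
        [ParticleRecord(image_name="s", image_index=0, pixel_size=pixel)]
    )
    df = table.df.copy()
    df[OFFSET_X_TAG] = [ox]
    df[OFFSET_Y_TAG] = [oy]
    return table.with_rows(df)


def test_extract_identity_crop():
    stack = _stack_with_blob()
    sub_stack, sub_table = extract_subparticles(stack, _offset_table(0, 0), 48)
    assert np.array_equal(sub_stack.data[0], stack.data[0])
    rec = sub_table.records()[0]
    assert rec.image_index == 0
    assert OFFSET_X_TAG not in sub_table.df.columns


def test_extract_centers_known_blob():
    """Centroid oracle: blob at q lands within 1 pixel of the sub-box center."""
    stack = _stack_with_blob(q_px=(7, -5))
    sub_stack, _ = extract_subparticles(stack, _offset_table(7, -5), 16)
    img = sub_stack.data[0].astype(float)
    yy, xx = np.meshgrid(np.arange(16), np.arange(16), indexing="ij")
    cy = (img * yy).sum() / img.sum()
    cx = (img * xx).sum() / img.sum()
    assert abs(cx - 8) <= 1.0 and abs(cy - 8) <= 1.0


def test_extract_edge_padding_uses_source_mean():
    stack = _stack_with_blob()
    src_mean = float(stack.data[0].mean())
    sub_stack, _ = extract_subparticles(stack, _offset_table(22, 0), 16)
    # right half of the window falls outside: padded region equals the mean
    padded_region = sub_stack.data[0][:, -4:]
    assert np.abs(padded_region - src_mean).max() < 1e-6


def test_extract_rejects_oversized_box():
    stack = _stack_with_blob()
    with pytest.raises(ValueError, match="larger than source"):
        extract_subparticles(stack, _offset_table(0, 0), 64)


def test_extract_requires_offsets(ten_row_table):
    stack = ImageStack(np.zeros((10, 32, 32), dtype=np.float32), 5.548)
    with pytest.raises(ValueError, match="recenter"):
        extract_subparticles(stack, ten_row_table, 16)


# ---------------------------------------------------------------------------
# local refinement
# ---------------------------------------------------------------------------


def test_refine_noise_free_truth_in_grid_returns_truth(small_ring):
    """Truth pose on the grid, zero noise: tie-breaking keeps the zero
    perturbation and the table is returned unchanged."""
    vol, _ = small_ring
    spec = CollectionSpec(n_particles=4, snr=np.inf, seed=3, shift_range=2.0)
    stack, table = simulate_particles(vol, spec)
    refined = local_refine(
        stack, vol, table, angular_range=4.0, angular_step=2.0,
        shift_range=2.0, shift_step=1.0, rounds=1, final_order=3,
    )
    for a, b in zip(table.records(), refined.records()):
        # poses are re-canonicalized; compare rotations geodesically
        delta = TransformRT(
            rotation=euler_to_matrix(a.rot, a.tilt, a.psi).T
            @ euler_to_matrix(b.rot, b.tilt, b.psi)
        ).rotation_angle()
        assert delta < 1e-6
        assert b.shift_x == pytest.approx(a.shift_x, abs=1e-9)
        assert b.shift_y == pytest.approx(a.shift_y, abs=1e-9)


def test_refine_recovers_perturbed_poses(small_ring, small_sim):
    """Small-scale recovery smoke test (the full criterion lives in the
    acceptance suite): >=90% of 40 particles within one grid step."""
    vol, _ = small_ring
    stack, table = small_sim
    rng = np.random.default_rng(17)
    df = table.df.copy()
    true = df[["rot", "tilt", "psi", "shift_x", "shift_y"]].to_numpy().copy()
    n = len(df)
    df["rot"] += rng.uniform(-4, 4, n)
    df["tilt"] = np.clip(df["tilt"] + rng.uniform(-4, 4, n), 0, 180)
    df["psi"] += rng.uniform(-4, 4, n)
    df["shift_x"] += rng.uniform(-3, 3, n)
    df["shift_y"] += rng.uniform(-3, 3, n)
    refined = local_refine(
        stack, vol, table.with_rows(df), angular_range=6.0, angular_step=3.0,
        shift_range=4.0, shift_step=2.0, rounds=2,
    )
    est = refined.df[["rot", "tilt", "psi", "shift_x", "shift_y"]].to_numpy()
    geo = np.array([
        TransformRT(
            rotation=euler_to_matrix(*true[i, :3]).T @ euler_to_matrix(*est[i, :3])
        ).rotation_angle()
        for i in range(n)
    ])
    shift_err = np.hypot(est[:, 3] - true[:, 3], est[:, 4] - true[:, 4])
    ok = (geo <= 3.0) & (shift_err <= 2.0)
    assert ok.mean() >= 0.90


def test_refine_never_worsens_resolution(small_ring):
    """FSC resolution after refinement <= before, for 3 seeds."""
    vol, _ = small_ring
    for seed in (0, 1, 2):
        spec = CollectionSpec(n_particles=32, snr=1.0, seed=seed, shift_range=2.0)
        stack, table = simulate_particles(vol, spec)
        rng = np.random.default_rng(100 + seed)
        df = table.df.copy()
        n = len(df)
        df["rot"] += rng.uniform(-4, 4, n)
        df["tilt"] = np.clip(df["tilt"] + rng.uniform(-4, 4, n), 0, 180)
        df["psi"] += rng.uniform(-4, 4, n)
        perturbed = table.with_rows(df)

        def res(t):
            ha, hb = reconstruct(stack, t, half_sets=True)
            return resolution_at(compute_fsc(ha, hb))

        refined = local_refine(
            stack, vol, perturbed, angular_range=6.0, angular_step=2.0,
            shift_range=0.0, shift_step=0.0, rounds=2,
        )
        assert res(refined) <= res(perturbed) + 1e-9, f"seed {seed}"


def test_refine_validates_grid(small_ring, small_sim):
    vol, _ = small_ring
    stack, table = small_sim
    with pytest.raises(ValueError):
        local_refine(stack, vol, table, angular_range=-1.0, angular_step=1.0,
                     shift_range=0.0, shift_step=0.0)


def test_refine_deterministic(small_ring, small_sim):
    vol, _ = small_ring
    stack, table = small_sim
    sub = table.with_rows(table.df.iloc[:6])
    a = local_refine(stack, vol, sub, angular_range=4, angular_step=2,
                     shift_range=2, shift_step=1, rounds=2)
    b = local_refine(stack, vol, sub, angular_range=4, angular_step=2,
                     shift_range=2, shift_step=1, rounds=2)
    assert a.df.equals(b.df)
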