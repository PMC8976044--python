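import numpy as np
import pytest
from scipy.optimize import brentq

from ringrec.ctf_projection import (
    CTFParams,
    FourierProjector,
    backproject,
    compute_fsc,
    electron_wavelength,
    evaluate_ctf,
    project,
    reconstruct,
    resolution_at,
)
from ringrec.geometry import euler_to_matrix
from ringrec.io_formats import ImageStack, ParticleRecord, ParticleTable, VolumeGrid
from ringrec.synthetic_data import (
    CollectionSpec,
    PseudoAtom,
    RingSpec,
    make_toy_ring_volume,
    simulate_particles,
)

from conftest import SMALL_GRID, SMALL_PIXEL


# ---------------------------------------------------------------------------
# CTF
# ---------------------------------------------------------------------------


def test_ctf_at_zero_frequency_is_minus_amplitude_contrast():
    for a in (0.0, 0.07, 0.1, 1.0):
        params = CTFParams(defocus_u=20000, defocus_v=20000, amplitude_contrast=a)
        ctf = evaluate_ctf(params, 32, 2.0)
        assert ctf[16, 16] == pytest.approx(-a, abs=1e-12)


def test_ctf_no_astigmatism_is_rotationally_symmetric():
    params = CTFParams(defocus_u=21000, defocus_v=21000, astig_angle=37.0)
    ctf = evaluate_ctf(params, 64, 2.0)
    # swapping kx and ky is a 90-degree rotation of the frequency grid
    assert np.abs(ctf - ctf.T).max() < 1e-9


def test_ctf_astigmatism_breaks_symmetry():
    params = CTFParams(defocus_u=25000, defocus_v=15000, astig_angle=0.0)
    ctf = evaluate_ctf(params, 64, 2.0)
    assert np.abs(ctf - ctf.T).max() > 0.1


def test_ctf_first_zero_matches_root_find_oracle():
    """Scalar brentq root of the independently restated CTF formula."""
    voltage, z, cs_mm, a = 300.0, 20000.0, 2.7, 0.1
    lam = 12.2643 / np.sqrt(voltage * 1e3 * (1 + voltage * 1e3 * 0.978466e-6))
    cs = cs_mm * 1e7

    def ctf_1d(f):
        gamma = np.pi * lam * z * f**2 - 0.5 * np.pi * cs * lam**3 * f**4
        return -(np.sqrt(1 - a**2) * np.sin(gamma) + a * np.cos(gamma))

    # bracket the first sign change on a fine grid
    grid = np.linspace(1e-5, 0.2, 4000)
    vals = ctf_1d(grid)
    i = int(np.nonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))[0][0])
    oracle_zero = brentq(ctf_1d, grid[i], grid[i + 1], xtol=1e-10)

    # package route: evaluate on a dense 1D transect and interpolate the zero
    n, px = 4096, 1.0
    params = CTFParams(defocus_u=z, defocus_v=z, voltage=voltage, cs_mm=cs_mm,
                       amplitude_contrast=a)
    ctf = evaluate_ctf(params, n, px)
    row = ctf[n // 2, n // 2 + 1 :]
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=px))[n // 2 + 1 :]
    j = int(np.nonzero(np.sign(row[:-1]) != np.sign(row[1:]))[0][0])
    pkg_zero = freqs[j] + (freqs[j + 1] - freqs[j]) * row[j] / (row[j] - row[j + 1])
    assert pkg_zero == pytest.approx(oracle_zero, abs=1e-4)


def test_electron_wavelength_300kv():
    # 300 kV electrons: ~0.0197 A
    assert electron_wavelength(300.0) == pytest.approx(0.0197, abs=1e-4)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def _spherical_gaussian(n=48, px=3.2, sigma=9.0):
    ax = (np.arange(n) - n // 2) * px
    zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
    return VolumeGrid(np.exp(-(xx**2 + yy**2 + zz**2) / (2 * sigma**2)), px)


def test_identity_projection_radially_symmetric():
    vol = _spherical_gaussian()
    img = project(vol, 0.0, 0.0, 0.0)
    assert np.abs(img - img.T).max() < 1e-9 * img.max()
    # flip about the center voxel n//2 (roll realigns the even-grid center)
    flipped = np.roll(img[::-1, ::-1], (1, 1), axis=(0, 1))
    assert np.abs(img - flipped).max() < 1e-6 * img.max()
    # analytic: projection of an isotropic Gaussian
    ax = (np.arange(48) - 24) * 3.2
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    analytic = np.exp(-(xx**2 + yy**2) / (2 * 81.0)) * np.sqrt(2 * np.pi) * 9.0
    assert np.abs(img - analytic).max() < 1e-3 * analytic.max()


def test_projection_equivariance_against_rotated_ring(small_ring_spec):
    """project(V, R) equals project(V_rotated_by_R, identity) within 1%."""
    from ringrec.synthetic_data import _splat_gaussian

    vol, _ = make_toy_ring_volume(small_ring_spec, SMALL_GRID, SMALL_PIXEL)
    rot, tilt, psi = 20.0, 40.0, -30.0
    rotation = euler_to_matrix(rot, tilt, psi)
    n = SMALL_GRID
    data = np.zeros((n, n, n))
    axc = np.arange(n) - n // 2
    center0 = small_ring_spec.subunit_center()
    for sym in small_ring_spec.symmetry_matrices():
        for atom in small_ring_spec.motif:
            pos = rotation @ (sym @ (center0 + np.asarray(atom.position)))
            _splat_gaussian(data, axc, pos, atom.weight, atom.sigma, SMALL_PIXEL)
    rotated = VolumeGrid(data, SMALL_PIXEL)

    img = project(vol, rot, tilt, psi)
    ref = project(rotated, 0.0, 0.0, 0.0)
    assert np.abs(img - ref).max() < 0.01 * np.abs(ref).max()


def test_projection_mass_conservation(small_ring):
    vol, _ = small_ring
    for pose in [(0.0, 0.0, 0.0), (20.0, 40.0, -30.0), (111.0, 87.0, 12.0)]:
        img = project(vol, *pose)
        assert img.sum() == pytest.approx(vol.data.sum() * vol.pixel_size, rel=0.005)


def test_fourier_and_real_projection_agree(small_ring):
    vol, _ = small_ring
    pose = (20.0, 40.0, -30.0)
    img_f = project(vol, *pose, method="fourier")
    img_r = project(vol, *pose, method="real")
    assert np.abs(img_f - img_r).max() < 0.01 * np.abs(img_f).max()


def test_shift_moves_projection():
    vol = _spherical_gaussian()
    img = project(vol, 0.0, 0.0, 0.0, shift=(2 * 3.2, -3 * 3.2))
    iy, ix = np.unravel_index(img.argmax(), img.shape)
    assert (ix - 24, iy - 24) == (2, -3)


def test_projection_backprojection_adjointness(small_ring):
    """<project(v, p), img> == <v, backproject(img, p)> within 1%.

    The test vector is band-limited noise: discrete adjointness of the two
    spline interpolators only holds on the smooth subspace at toy scale.
    """
    from scipy.ndimage import gaussian_filter

    vol, _ = small_ring
    rng = np.random.default_rng(0)
    img = gaussian_filter(rng.normal(size=(SMALL_GRID, SMALL_GRID)), 2.0)
    pose = (25.0, 55.0, -40.0)
    lhs = float(np.sum(project(vol, *pose, method="real") * img))
    bp = backproject(img, SMALL_GRID, SMALL_PIXEL, *pose)
    rhs = float(np.sum(vol.data * bp.data))
    assert lhs == pytest.approx(rhs, rel=0.01)


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------


def _single_particle_setup():
    vol, _ = make_toy_ring_volume(
        RingSpec(ring_radius=SMALL_RADIUS_LOCAL), 32, 4.5
    )
    img = project(vol, 0.0, 0.0, 0.0)
    stack = ImageStack(img[None].astype(np.float32), 4.5)
    table = ParticleTable.from_records(
        [ParticleRecord(image_name="x", image_index=0, pixel_size=4.5,
                        defocus_u=1.0, defocus_v=1.0)]
    )
    return vol, img, stack, table


SMALL_RADIUS_LOCAL = 30.0


def test_single_particle_central_plane_identity():
    """Single particle, identity pose, CTF ~= -1: the reconstruction's
    central slice (its projection, by the central-slice theorem) equals the
    sign-flipped input image."""
    _, img, stack, table = _single_particle_setup()
    # oversample=1: a single inserted slice fills only one z-plane of the
    # padded grid, so the unpadded grid is the exact setting here
    recon = reconstruct(stack, table, eps_rel=1e-12, oversample=1,
                        ctf_kwargs={"amplitude_contrast": 1.0, "cs_mm": 0.0})
    img_rec = project(recon, 0.0, 0.0, 0.0)
    assert np.abs(-img_rec - img).max() < 1e-6 * np.abs(img).max()


def test_noise_free_reconstruction_fidelity(small_ring):
    """>= 500 spread poses, no noise: real-space correlation after a
    0.8-Nyquist lowpass exceeds 0.95."""
    vol, _ = small_ring
    tilts = tuple(np.rad2deg(np.arccos(np.linspace(0.999, -0.999, 50))))
    spec = CollectionSpec(n_particles=500, snr=np.inf, tilt_angles=tilts,
                          tilt_jitter_sd=0.0, seed=11)
    stack, table = simulate_particles(vol, spec)
    recon = reconstruct(stack, table)

    def lowpass(v):
        f = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(v.data.astype(float))))
        n = v.n
        k = np.arange(n) - n // 2
        kz, ky, kx = np.meshgrid(k, k, k, indexing="ij")
        f[np.sqrt(kx**2 + ky**2 + kz**2) > 0.8 * n / 2] = 0.0
        return np.real(np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(f))))

    a, b = lowpass(recon), lowpass(vol)
    corr = np.corrcoef(a.ravel(), b.ravel())[0, 1]
    assert corr > 0.95


def test_reconstruct_requires_two_per_half_set(small_sim):
    stack, table = small_sim
    tiny = table.with_rows(table.df.iloc[:3])
    with pytest.raises(ValueError, match="half-set"):
        reconstruct(stack, tiny, half_sets=True)


def test_more_particles_never_worsen_resolution():
    """FSC(0.143) resolution is monotone in particle count, 5 seeds."""
    spec = RingSpec(ring_radius=30.0)
    vol, _ = make_toy_ring_volume(spec, 32, 4.5)
    for seed in range(5):
        results = []
        for n_particles in (48, 96):
            cs = CollectionSpec(n_particles=n_particles, snr=0.5, seed=seed)
            stack, table = simulate_particles(vol, cs)
            ha, hb = reconstruct(stack, table, half_sets=True)
            results.append(resolution_at(compute_fsc(ha, hb)))
        assert results[1] <= results[0] + 1e-9, f"seed {seed}: {results}"


# ---------------------------------------------------------------------------
# FSC
# ---------------------------------------------------------------------------


def test_fsc_self_correlation_is_one(small_ring):
    vol, _ = small_ring
    curve = compute_fsc(vol, vol)
    assert np.allclose(curve.fsc, 1.0, atol=1e-9)


def test_fsc_white_noise_null():
    """Independent white-noise volumes: |FSC| < 3/sqrt(n_shell) for >=95%
    of shells (null-distribution oracle)."""
    rng = np.random.default_rng(5)
    a = VolumeGrid(rng.normal(size=(48, 48, 48)), 2.0)
    b = VolumeGrid(rng.normal(size=(48, 48, 48)), 2.0)
    curve = compute_fsc(a, b)
    bound = 3.0 / np.sqrt(curve.n_voxels)
    assert np.mean(np.abs(curve.fsc) < bound) >= 0.95


def test_resolution_never_finer_than_nyquist(small_ring):
    vol, _ = small_ring
    curve = compute_fsc(vol, vol)  # never crosses the threshold
    assert resolution_at(curve) == pytest.approx(2 * vol.pixel_size)
    rng = np.random.default_rng(1)
    for _ in range(3):
        a = VolumeGrid(rng.normal(size=(32, 32, 32)), 3.0)
        b = VolumeGrid(rng.normal(size=(32, 32, 32)), 3.0)
        assert resolution_at(compute_fsc(a, b)) >= 2 * 3.0


def test_fsc_symmetric_and_scale_invariant(small_ring):
    vol, _ = small_ring
    rng = np.random.default_rng(2)
    noisy = VolumeGrid(vol.data + rng.normal(size=vol.data.shape).astype(np.float32),
                       vol.pixel_size)
    c_ab = compute_fsc(vol, noisy)
    c_ba = compute_fsc(noisy, vol)
    assert np.allclose(c_ab.fsc, c_ba.fsc, atol=1e-12)
    scaled = VolumeGrid(noisy.data * 7.5, vol.pixel_size)
    c_scaled = compute_fsc(vol, scaled)
    assert np.allclose(c_ab.fsc, c_scaled.fsc, atol=1e-9)


def test_fsc_rejects_mismatched_grids(small_ring):
    vol, _ = small_ring
    other = VolumeGrid(np.zeros((16, 16, 16), dtype=np.float32), vol.pixel_size)
    with pytest.raises(ValueError):
        compute_fsc(vol, other)


def test_fsc_curve_tsv(tmp_path, small_ring):
    vol, _ = small_ring
    curve = compute_fsc(vol, vol)
    path = tmp_path / "fsc.tsv"
    curve.to_tsv(path)
    lines = path.read_text().strip().splitlines()
    assert lines[0].startswith("frequency")
    assert len(lines) == len(curve.fsc) + 1


def test_projector_order_paths_agree(small_ring):
    vol, _ = small_ring
    rotation = euler_to_matrix(20.0, 40.0, -30.0)[None]
    fine = FourierProjector(vol, order=3).slice_batch(rotation)[0]
    fast = FourierProjector(vol, order=1).slice_batch(rotation)[0]
    scale = np.abs(fine).max()
    # order-1 is scoring-grade: a few percent is expected and acceptable
    assert np.abs(fine - fast).max() < 0.05 * scale
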