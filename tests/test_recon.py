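"""Spiral design, density compensation, gridding, WSVD and MP-PCA."""

import numpy as np
import pytest
import shapely.geometry as geom

from cki import recon as R

from oracles import halfplane_voronoi_areas


# ----------------------------------------------------------------------
# spiral design
# ----------------------------------------------------------------------


def test_spiral_contract():
    traj = R.design_spiral()
    assert traj.n_points == 861
    assert traj.radius.max() <= traj.kmax
    assert traj.radius.max() == pytest.approx(np.sqrt(0.33) * 16.0, rel=1e-12)
    assert np.all(np.diff(traj.radius) >= 0)  # monotone radius growth
    again = R.design_spiral()
    np.testing.assert_array_equal(traj.kxy, again.kxy)


def test_spiral_infeasible_and_invalid():
    with pytest.raises(ValueError):
        R.design_spiral(n_points=100, coverage=1.0)
    with pytest.raises(ValueError):
        R.design_spiral(coverage=0.0)


# ----------------------------------------------------------------------
# Voronoi DCF
# ----------------------------------------------------------------------


def test_voronoi_uniform_grid_equal_interior_weights():
    xs = np.arange(-3, 4, dtype=float)
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    k = (X + 1j * Y).ravel()
    traj = R.SpiralTrajectory(kxy=k, dwell=1e-5, coverage=1.0, kmax=8.0)
    w = R.voronoi_dcf(traj, clip_radius=20.0)
    interior = (np.abs(k.real) <= 2) & (np.abs(k.imag) <= 2)
    np.testing.assert_allclose(w[interior], 1.0, rtol=1e-9)


def test_voronoi_against_halfplane_oracle():
    """Cell areas equal a brute-force half-plane polygon construction."""
    rng = np.random.default_rng(17)
    pts = rng.uniform(-8, 8, size=(400, 2))
    pts = pts[np.hypot(pts[:, 0], pts[:, 1]) < 8.0][:200]  # inside the clip disc
    assert len(pts) == 200
    k = pts[:, 0] + 1j * pts[:, 1]
    traj = R.SpiralTrajectory(kxy=k, dwell=1e-5, coverage=1.0, kmax=16.0)
    clip = 10.0
    w = R.voronoi_dcf(traj, clip_radius=clip)
    disc = geom.Point(0.0, 0.0).buffer(clip, quad_segs=64)
    expected = halfplane_voronoi_areas(pts, disc)
    np.testing.assert_allclose(w, expected, rtol=1e-9)


def test_voronoi_jitters_duplicates():
    k = np.array([0 + 0j, 0 + 0j, 1 + 0j, 0 + 1j, 1 + 1j, -1 - 1j, 2 - 1j])
    traj = R.SpiralTrajectory(kxy=k, dwell=1e-5, coverage=1.0, kmax=4.0)
    with pytest.warns(UserWarning, match="jitter"):
        w = R.voronoi_dcf(traj, clip_radius=5.0)
    assert np.all(w > 0)


def test_hann_window_endpoints():
    traj = R.design_spiral()
    w = np.ones(traj.n_points)
    out = R.apply_hanning(w, traj)
    assert out[0] == pytest.approx(1.0)  # k = 0 → factor 1
    assert out[-1] == pytest.approx(0.0, abs=1e-12)  # |k| = kmax → factor 0
    mid = traj.radius.max() / 2.0
    i = int(np.argmin(np.abs(traj.radius - mid)))
    assert out[i] == pytest.approx(
        0.5 * (1 + np.cos(np.pi * traj.radius[i] / traj.radius.max())), rel=1e-12
    )


# ----------------------------------------------------------------------
# gridding
# ----------------------------------------------------------------------


def test_gridding_adjointness(default_trajectory):
    op = R.GriddingOperator(default_trajectory)
    rng = np.random.default_rng(1)
    X = rng.standard_normal((861, 3)) + 1j * rng.standard_normal((861, 3))
    Y = rng.standard_normal((32, 32, 3)) + 1j * rng.standard_normal((32, 32, 3))
    lhs = np.vdot(Y, op.adjoint(X))
    rhs = np.vdot(op.forward(Y), X)
    assert abs(lhs - rhs) / abs(lhs) < 1e-6


def test_dc_sample_gives_flat_image(default_trajectory):
    op = R.GriddingOperator(default_trajectory)
    data = np.zeros((861, 1), dtype=complex)
    data[0] = 1.0  # the spiral starts at k = 0
    img = np.abs(op.adjoint(data)[:, :, 0])
    assert (img.max() - img.min()) / img.mean() < 1e-3


def test_gridding_linearity(default_trajectory):
    op = R.GriddingOperator(default_trajectory)
    rng = np.random.default_rng(2)
    X = rng.standard_normal((861, 2)) + 1j * rng.standard_normal((861, 2))
    Y = rng.standard_normal((861, 2)) + 1j * rng.standard_normal((861, 2))
    a, b = 2.0 - 1.0j, -0.5 + 3.0j
    lhs = op.adjoint(a * X + b * Y)
    rhs = a * op.adjoint(X) + b * op.adjoint(Y)
    np.testing.assert_allclose(lhs, rhs, rtol=1e-5, atol=1e-7)


def test_gaussian_object_reconstruction(full_coverage_trajectory):
    """Analytic phantom: NRMSE ≤ 0.05 through DCF + gridding at full coverage."""
    traj = full_coverage_trajectory
    w = R.voronoi_dcf(traj)
    op = R.GriddingOperator(traj)
    xs = (np.arange(32) - 16) / 32.0
    X, Y = np.meshgrid(xs, xs, indexing="ij")
    obj = np.exp(-(X**2 + Y**2) / (2 * 0.08**2))
    phase = np.exp(
        -2j
        * np.pi
        * (np.outer(traj.kxy.real, X.ravel()) + np.outer(traj.kxy.imag, Y.ravel()))
    )
    samples = phase @ obj.ravel().astype(complex)
    rec = op.adjoint((samples * w)[:, None])[:, :, 0]
    a = np.vdot(rec, obj) / np.vdot(rec, rec)
    assert np.linalg.norm(a * rec - obj) / np.linalg.norm(obj) <= 0.05


# ----------------------------------------------------------------------
# noise estimation
# ----------------------------------------------------------------------


def _noise_raw(trajectory, cov, sigma, n_av, seed):
    rng = np.random.default_rng(seed)
    n_coil = cov.shape[0]
    L = np.linalg.cholesky(cov)
    shape = (trajectory.n_points, 5, 64, n_coil, n_av)
    noise = sigma * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))
    data = np.einsum("dc,rkfcn->rkfdn", L, noise).astype(np.complex64)
    return R.RawKSpace(data=data, trajectory=trajectory, nz=11)


def test_noise_estimate_zero_for_identical_averages(default_trajectory):
    rng = np.random.default_rng(0)
    one = (rng.standard_normal((861, 5, 16, 2)) + 0j).astype(np.complex64)
    data = np.stack([one, one], axis=-1)
    raw = R.RawKSpace(data=data, trajectory=default_trajectory, nz=11)
    w = R.voronoi_dcf(default_trajectory)
    noise = R.estimate_noise(raw, w, fa_stride=4)
    np.testing.assert_allclose(np.abs(noise), 0.0, atol=1e-6)


def test_noise_estimate_requires_two_averages(default_trajectory):
    data = np.zeros((861, 5, 4, 2, 1), dtype=np.complex64)
    raw = R.RawKSpace(data=data, trajectory=default_trajectory, nz=11)
    with pytest.raises(ValueError):
        R.estimate_noise(raw, np.ones(861))


def test_noise_covariance_identity_coupling(default_trajectory):
    """i.i.d. complex noise with identity coupling → covariance ≈ 2σ²·I."""
    sigma = 0.7
    raw = _noise_raw(default_trajectory, np.eye(3), sigma, n_av=2, seed=5)
    w = R.voronoi_dcf(default_trajectory)
    noise = R.estimate_noise(raw, w, fa_stride=1)
    cov = R.noise_covariance(noise)
    expected = 2 * sigma**2 * np.eye(3)
    np.testing.assert_allclose(cov.real, expected, atol=0.1 * 2 * sigma**2)
    np.testing.assert_allclose(cov.imag, 0.0, atol=0.1 * 2 * sigma**2)


def test_noise_covariance_correlated_two_coils(default_trajectory):
    """Known 2×2 coupling recovered within 10 % per entry."""
    C = np.array([[1.0, 0.5], [0.5, 1.0]])
    raw = _noise_raw(default_trajectory, C, 1.0, n_av=4, seed=6)
    w = R.voronoi_dcf(default_trajectory)
    noise = R.estimate_noise(raw, w, fa_stride=1)
    assert noise.shape[0] >= 10_000
    cov = R.noise_covariance(noise).real
    np.testing.assert_allclose(cov, 2 * C, rtol=0.1)


# ----------------------------------------------------------------------
# WSVD coil combination
# ----------------------------------------------------------------------


def _phase_aligned(a, b):
    """Rotate b by the global phase that best aligns it with a."""
    ph = np.vdot(a, b)
    return b * np.exp(-1j * np.angle(ph)) if abs(ph) else b


def test_wsvd_single_coil_identity():
    rng = np.random.default_rng(3)
    x = rng.standard_normal((4, 4, 2, 16, 1)) + 1j * rng.standard_normal((4, 4, 2, 16, 1))
    out = R.wsvd_combine(x, np.eye(1))
    flat_in = x[..., 0].reshape(-1, 16)
    flat_out = out.reshape(-1, 16)
    for i in range(flat_in.shape[0]):
        aligned = _phase_aligned(flat_in[i], flat_out[i])
        np.testing.assert_allclose(aligned, flat_in[i], rtol=1e-6, atol=1e-9)


def test_wsvd_one_hot_coils():
    rng = np.random.default_rng(4)
    s = rng.standard_normal((1, 1, 1, 32)) + 1j * rng.standard_normal((1, 1, 1, 32))
    x = np.stack([s, np.zeros_like(s)], axis=-1)
    out = R.wsvd_combine(x, np.eye(2))
    assert np.linalg.norm(out) == pytest.approx(np.linalg.norm(s), rel=1e-6)


def test_wsvd_beats_sum_of_squares():
    """With correlated noise, WSVD correlates better with the true signal."""
    rng = np.random.default_rng(8)
    n_coil, n_fa, n_vox = 8, 200, 64
    truth = rng.standard_normal((n_vox, n_fa)) + 1j * rng.standard_normal((n_vox, n_fa))
    sens = rng.standard_normal((n_vox, n_coil)) + 1j * rng.standard_normal((n_vox, n_coil))
    idx = np.arange(n_coil)
    C = 0.6 ** np.abs(idx[:, None] - idx[None, :])
    L = np.linalg.cholesky(C)
    noise = np.einsum(
        "dc,vtc->vtd",
        L,
        rng.standard_normal((n_vox, n_fa, n_coil))
        + 1j * rng.standard_normal((n_vox, n_fa, n_coil)),
    )
    data = truth[:, :, None] * sens[:, None, :] + 1.0 * noise
    series = data.reshape(8, 8, 1, n_fa, n_coil)
    wsvd = R.wsvd_combine(series, C).reshape(n_vox, n_fa)
    sos = np.sqrt((np.abs(data) ** 2).sum(axis=2))

    def corr(est):
        num = np.abs(np.sum(np.conj(est) * truth, axis=1))
        return num / (np.linalg.norm(est, axis=1) * np.linalg.norm(truth, axis=1))

    assert corr(wsvd).mean() > np.abs(corr(sos)).mean()


def test_wsvd_whitening_invariance():
    """Coil recombination with transformed covariance: same temporal shape."""
    rng = np.random.default_rng(9)
    x = rng.standard_normal((2, 2, 1, 32, 3)) + 1j * rng.standard_normal((2, 2, 1, 32, 3))
    C = np.eye(3) + 0.3
    out1 = R.wsvd_combine(x, C)
    T = rng.standard_normal((3, 3)) + 1j * rng.standard_normal((3, 3))
    xt = np.einsum("dc,xyzfc->xyzfd", T, x)
    Ct = T @ C @ T.conj().T
    out2 = R.wsvd_combine(xt, Ct)
    flat1, flat2 = out1.reshape(-1, 32), out2.reshape(-1, 32)
    for i in range(flat1.shape[0]):
        a = flat1[i] / np.linalg.norm(flat1[i])
        b = flat2[i] / np.linalg.norm(flat2[i])
        b = _phase_aligned(a, b)
        np.testing.assert_allclose(b, a, rtol=1e-6, atol=1e-8)


def test_wsvd_rejects_singular_covariance():
    x = np.zeros((1, 1, 1, 4, 2), dtype=complex)
    with pytest.raises(np.linalg.LinAlgError, match="regular"):
        R.wsvd_combine(x, np.zeros((2, 2)))


# ----------------------------------------------------------------------
# MP-PCA
# ----------------------------------------------------------------------


def test_mppca_suppresses_pure_noise():
    rng = np.random.default_rng(10)
    x = (rng.standard_normal((16, 16, 4, 200)) + 1j * rng.standard_normal((16, 16, 4, 200)))
    out = R.mppca_denoise(x)
    assert out.var() <= 0.1 * x.var()


def test_mppca_preserves_rank_one():
    rng = np.random.default_rng(11)
    u = rng.standard_normal((1024, 1))
    v = rng.standard_normal((1, 64)) + 1j * rng.standard_normal((1, 64))
    x = (u @ v).reshape(32, 32, 1, 64)
    out = R.mppca_denoise(x)
    np.testing.assert_allclose(out, x, atol=1e-8 * np.abs(x).max())


def test_mppca_improves_noisy_low_rank():
    rng = np.random.default_rng(12)
    n_vox, n_fa, rank = 2048, 128, 3
    U = rng.standard_normal((n_vox, rank))
    V = rng.standard_normal((rank, n_fa)) + 1j * rng.standard_normal((rank, n_fa))
    clean = (U @ V) / np.sqrt(rank)
    p_sig = np.mean(np.abs(clean) ** 2)
    sigma = np.sqrt(p_sig / 10 ** (10.0 / 10.0) / 2.0)  # 10 dB
    noisy = clean + sigma * (
        rng.standard_normal(clean.shape) + 1j * rng.standard_normal(clean.shape)
    )
    out = R.mppca_denoise(noisy.reshape(32, 64, 1, n_fa)).reshape(n_vox, n_fa)
    err_out = np.linalg.norm(out - clean)
    err_in = np.linalg.norm(noisy - clean)
    assert err_out < err_in


def test_mppca_validations():
    with pytest.raises(ValueError):
        R.mppca_denoise(np.full((2, 2, 1, 4), np.nan, dtype=complex))
    with pytest.raises(ValueError):
        R.mppca_denoise(np.ones((1, 1, 1, 4), dtype=complex))


# ----------------------------------------------------------------------
# full chain
# ----------------------------------------------------------------------


def test_reconstruct_zero_input(default_trajectory):
    data = np.zeros((861, 5, 16, 2, 2), dtype=np.complex64)
    raw = R.RawKSpace(data=data, trajectory=default_trajectory, nz=11)
    series = R.reconstruct(raw, R.ReconConfig(denoise=False))
    np.testing.assert_allclose(np.abs(series.data), 0.0, atol=1e-12)


def test_reconstruct_linearity_without_denoiser(default_trajectory):
    rng = np.random.default_rng(13)
    data = (
        rng.standard_normal((861, 5, 16, 2, 2)) + 1j * rng.standard_normal((861, 5, 16, 2, 2))
    ).astype(np.complex64)
    raw1 = R.RawKSpace(data=data, trajectory=default_trajectory, nz=11)
    raw2 = R.RawKSpace(data=2 * data, trajectory=default_trajectory, nz=11)
    cfg = R.ReconConfig(denoise=False, noise_fa_stride=4)
    s1 = R.reconstruct(raw1, cfg)
    s2 = R.reconstruct(raw2, cfg)
    np.testing.assert_allclose(s2.data, 2 * s1.data, rtol=1e-4, atol=1e-5)


def test_raw_kspace_shape_validation(default_trajectory):
    with pytest.raises(ValueError):
        R.RawKSpace(data=np.zeros((10, 5, 4, 2, 2), dtype=complex), trajectory=default_trajectory)
    with pytest.raises(ValueError):
        R.RawKSpace(data=np.zeros((861, 5, 4, 2), dtype=complex), trajectory=default_trajectory)
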