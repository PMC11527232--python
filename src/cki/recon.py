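"""Spiral image reconstruction for the 5-D CKI raw tensor.

The raw data is ordered (readout 861, kz 5, FA 800, coil, average).  The
chain mirrors the acquisition design: 1-D Fourier transform along kz with
symmetric zero-filling of the 5 measured central planes to 11 slices;
Voronoi density compensation apodised by a radial half-period Hann window;
Kaiser-Bessel convolution gridding onto a 1.5× oversampled Cartesian grid
followed by a centred 2-D inverse FFT and deapodisation; whitened-SVD
(WSVD) coil combination per voxel using the FA index as the temporal
dimension, with the noise covariance estimated from interleaved average
differences; and Marchenko-Pastur PCA denoising of the combined series.

All k-space coordinates are expressed in cycles per field of view, so the
Nyquist radius of a 32 matrix is 16.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.fft
import scipy.sparse as sp
from scipy.spatial import Voronoi
import shapely.geometry as geom

__all__ = [
    "SpiralTrajectory",
    "RawKSpace",
    "ImageSeries",
    "ReconConfig",
    "design_spiral",
    "voronoi_dcf",
    "apply_hanning",
    "GriddingOperator",
    "grid_and_fft",
    "estimate_noise",
    "noise_covariance",
    "wsvd_combine",
    "mppca_denoise",
    "reconstruct",
]


@dataclass(frozen=True)
class SpiralTrajectory:
    """Single-shot spiral sampling of one kxy plane.

    ``kxy`` holds the complex-plane coordinates (Re = kx, Im = ky) in
    cycles/FOV; ``kmax`` is the Nyquist radius of the target matrix.
    """

    kxy: np.ndarray
    dwell: float
    coverage: float
    kmax: float

    @property
    def n_points(self) -> int:
        return self.kxy.size

    @property
    def radius(self) -> np.ndarray:
        return np.abs(self.kxy)


def design_spiral(
    n_points: int = 861,
    coverage: float = 0.33,
    matrix: int = 32,
    dwell: float = 1e-5,
    density_exponent: float = 1.3,
    n_turns: int | None = None,
) -> SpiralTrajectory:
    """Variable-density Archimedean spiral covering a fraction of the Nyquist disc.

    ``coverage`` is the sampled-area fraction of the Nyquist disc, so the
    outermost radius is √coverage · kmax.  The radius grows as t^density_exponent
    (> 1 samples the centre more densely); the number of turns defaults to
    the radial-Nyquist requirement of one cycle/FOV ring spacing.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError(f"coverage must be in (0, 1], got {coverage}")
    kmax = matrix / 2.0
    r_max = math.sqrt(coverage) * kmax
    turns = n_turns if n_turns is not None else max(1, math.ceil(r_max))
    # require enough samples to keep the along-track spacing below one
    # cycle/FOV (arc length ≈ π · turns · r_max for an Archimedean spiral)
    needed = math.pi * turns * r_max
    if n_points < needed:
        raise ValueError(
            f"{n_points} points cannot sample {turns} turns to radius {r_max:.1f} "
            f"(need >= {needed:.0f})"
        )
    t = np.linspace(0.0, 1.0, n_points)
    r = r_max * t**density_exponent
    theta = 2.0 * np.pi * turns * t
    return SpiralTrajectory(
        kxy=r * np.exp(1j * theta), dwell=dwell, coverage=coverage, kmax=kmax
    )


def _voronoi_cells_clipped(points: np.ndarray, disc: geom.Polygon) -> np.ndarray:
    """Areas of the Voronoi cells of ``points`` clipped to ``disc``.

    Guard sites on a far circle bound every data cell so each region is a
    finite polygon before clipping.
    """
    n = points.shape[0]
    r_guard = 3.0 * np.abs(points).view(float).reshape(n, 2).max() + 10.0
    phi = np.linspace(0, 2 * np.pi, 128, endpoint=False)
    guards = r_guard * np.stack([np.cos(phi), np.sin(phi)], axis=1)
    vor = Voronoi(np.vstack([points, guards]))
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise ValueError(f"degenerate Voronoi geometry at sample index {i}")
        poly = geom.Polygon(vor.vertices[region])
        areas[i] = poly.intersection(disc).area
    return areas


def voronoi_dcf(
    trajectory: SpiralTrajectory, clip_radius: float | None = None, disc_segments: int = 256
) -> np.ndarray:
    """Voronoi-cell-area density compensation weights (one per sample).

    Boundary cells are clipped to a disc of radius r_max + half the mean
    consecutive sample spacing.  Exactly duplicated k-space positions are
    jittered by a tiny epsilon (with a warning) to keep the diagram valid.
    """
    k = trajectory.kxy.astype(complex).copy()
    pts = np.stack([k.real, k.imag], axis=1)
    # jitter exact duplicates
    _, first = np.unique(pts.round(12), axis=0, return_index=True)
    dup = np.setdiff1d(np.arange(len(pts)), first)
    if dup.size:
        import warnings

        warnings.warn(f"jittering {dup.size} duplicated k-space samples")
        rng = np.random.default_rng(0)
        pts[dup] += 1e-9 * rng.standard_normal((dup.size, 2))
    if clip_radius is None:
        # half the radial ring spacing beyond the outermost sample: the gap
        # between the last two spiral turns, not the along-track spacing
        r = np.abs(k)
        theta = np.unwrap(np.angle(k + (k == 0) * 1e-12))
        inner = r[theta <= theta[-1] - 2.0 * np.pi]
        ring = r.max() - inner.max() if inner.size else np.abs(np.diff(k)).mean()
        clip_radius = float(r.max() + 0.5 * max(ring, 1e-6))
    disc = geom.Point(0.0, 0.0).buffer(clip_radius, quad_segs=disc_segments // 4)
    weights = _voronoi_cells_clipped(pts, disc)
    if np.any(~np.isfinite(weights)) or np.any(weights <= 0):
        bad = np.flatnonzero(~np.isfinite(weights) | (weights <= 0))
        raise ValueError(f"non-positive Voronoi weights at indices {bad[:10]}")
    return weights


def apply_hanning(
    weights: np.ndarray, trajectory: SpiralTrajectory, kmax: float | None = None
) -> np.ndarray:
    """Multiply the DCF by the radial half-period Hann window.

    w(|k|) = 0.5·(1 + cos(π·|k|/kmax)): unity at the k-space centre, zero at
    the outermost sampled radius, damping high spatial frequencies.
    """
    km = kmax if kmax is not None else float(trajectory.radius.max())
    hann = 0.5 * (1.0 + np.cos(np.pi * np.clip(trajectory.radius / km, 0.0, 1.0)))
    return weights * hann


class GriddingOperator:
    """Kaiser-Bessel convolution gridding between a spiral and a Cartesian grid.

    Width-4 kernel on a 1.5× oversampled grid with the standard
    minimum-aliasing shape parameter; deapodisation uses the analytic
    Fourier transform of the kernel.  ``adjoint`` (k samples → image) and
    ``forward`` (image → k samples) form an exact adjoint pair.
    """

    def __init__(
        self,
        trajectory: SpiralTrajectory,
        matrix: int = 32,
        oversampling: float = 1.5,
        width: int = 4,
    ):
        self.matrix = matrix
        self.os = oversampling
        self.width = width
        self.grid_size = int(round(matrix * oversampling))
        w, osf = width, oversampling
        self.beta = math.pi * math.sqrt((w / osf) ** 2 * (osf - 0.5) ** 2 - 0.8)
        self._build_matrix(trajectory)
        self._build_deapodisation()

    def _kernel(self, r: np.ndarray) -> np.ndarray:
        x = 1.0 - (2.0 * r / self.width) ** 2
        out = np.zeros_like(r)
        ok = x > 0
        out[ok] = np.i0(self.beta * np.sqrt(x[ok])) / np.i0(self.beta)
        return out

    def _build_matrix(self, trajectory: SpiralTrajectory) -> None:
        G = self.grid_size
        # grid cell spacing is 1/os cycles/FOV; sample u-coordinates
        u = trajectory.kxy.real * self.os + G / 2.0
        v = trajectory.kxy.imag * self.os + G / 2.0
        half = self.width / 2.0
        rows, cols, vals = [], [], []
        offs = np.arange(-int(np.ceil(half)), int(np.ceil(half)) + 1)
        for i in range(trajectory.n_points):
            iu = int(np.floor(u[i]))
            iv = int(np.floor(v[i]))
            gu = iu + offs
            gv = iv + offs
            du = self._kernel(np.abs(gu - u[i]))
            dv = self._kernel(np.abs(gv - v[i]))
            wgt = np.outer(du, dv)
            gu_m = np.mod(gu, G)
            gv_m = np.mod(gv, G)
            cell = (gu_m[:, None] * G + gv_m[None, :]).ravel()
            w = wgt.ravel()
            nz = w > 0
            rows.append(cell[nz])
            cols.append(np.full(nz.sum(), i))
            vals.append(w[nz])
        self.S = sp.csr_matrix(
            (np.concatenate(vals).astype(np.float32), (np.concatenate(rows), np.concatenate(cols))),
            shape=(G * G, trajectory.n_points),
        )
        self.ST = self.S.T.tocsr()

    def _build_deapodisation(self) -> None:
        # image-domain response of the discretely sampled kernel, so that a
        # grid-centred DC sample deapodises to an exactly flat image
        G = self.grid_size
        samp = np.zeros(G)
        offs = (np.arange(G) - G // 2).astype(float)
        samp = self._kernel(np.abs(offs))
        c = np.fft.fftshift(np.fft.ifft(np.fft.ifftshift(samp))).real
        c = c / c[G // 2]
        self.deapod = np.outer(c, c)

    def adjoint(self, data: np.ndarray) -> np.ndarray:
        """Weighted k-space samples (n_points, ...) → images (matrix, matrix, ...)."""
        d = np.asarray(data)
        flat = d.reshape(d.shape[0], -1)
        grid = (self.S @ flat).reshape(self.grid_size, self.grid_size, -1)
        img = np.fft.fftshift(
            scipy.fft.ifft2(np.fft.ifftshift(grid, axes=(0, 1)), axes=(0, 1), norm="ortho"),
            axes=(0, 1),
        )
        img /= self.deapod[:, :, None].astype(img.real.dtype)
        lo = (self.grid_size - self.matrix) // 2
        img = img[lo : lo + self.matrix, lo : lo + self.matrix]
        return np.ascontiguousarray(img).reshape(self.matrix, self.matrix, *d.shape[1:])

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Images (matrix, matrix, ...) → k-space samples (n_points, ...); adjoint of ``adjoint``."""
        im = np.asarray(image)
        flat = im.reshape(self.matrix, self.matrix, -1)
        G = self.grid_size
        lo = (G - self.matrix) // 2
        padded = np.zeros((G, G, flat.shape[-1]), dtype=np.result_type(flat.dtype, np.complex64))
        padded[lo : lo + self.matrix, lo : lo + self.matrix] = flat
        padded /= self.deapod[:, :, None].astype(padded.real.dtype)
        ksp = np.fft.fftshift(
            scipy.fft.fft2(np.fft.ifftshift(padded, axes=(0, 1)), axes=(0, 1), norm="ortho"),
            axes=(0, 1),
        )
        out = self.ST @ ksp.reshape(G * G, -1)
        return out.reshape(self.ST.shape[0], *im.shape[2:])


@dataclass
class RawKSpace:
    """5-D raw tensor (readout, kz, FA, coil, average) with its trajectory."""

    data: np.ndarray
    trajectory: SpiralTrajectory
    fov: tuple = (0.23, 0.23, 0.22)
    matrix: int = 32
    nz: int = 11

    def __post_init__(self):
        if self.data.ndim != 5:
            raise ValueError(f"raw tensor must be 5-D, got shape {self.data.shape}")
        if self.data.shape[0] != self.trajectory.n_points:
            raise ValueError("readout length does not match the trajectory")

    @property
    def n_kz(self) -> int:
        return self.data.shape[1]

    @property
    def n_coils(self) -> int:
        return self.data.shape[3]

    @property
    def n_averages(self) -> int:
        return self.data.shape[4]


@dataclass
class ImageSeries:
    """Reconstructed complex volumes (nx, ny, nz, fa [, coil])."""

    data: np.ndarray
    fov: tuple = (0.23, 0.23, 0.22)
    pcr_image: np.ndarray | None = None
    atp_image: np.ndarray | None = None
    per_coil: np.ndarray | None = None
    noise_cov: np.ndarray | None = None


@dataclass
class ReconConfig:
    denoise: bool = True
    hanning: bool = True
    matrix: int = 32
    nz: int = 11
    oversampling: float = 1.5
    kernel_width: int = 4
    noise_fa_stride: int = 16


def _kz_to_slices(data: np.ndarray, nz: int) -> np.ndarray:
    """Centred inverse DFT along the measured kz planes, zero-filled to nz slices.

    ``data``: (n_points, n_kz, ...) with kz ordered −(n_kz−1)/2 … +(n_kz−1)/2.
    """
    n_kz = data.shape[1]
    if n_kz % 2 == 0:
        raise ValueError("expected an odd number of central kz planes")
    kz = np.arange(n_kz) - n_kz // 2
    z = np.arange(nz) - nz // 2
    # zero-filling in kz is implicit: only measured planes enter the sum
    F = (np.exp(2j * np.pi * kz[:, None] * z[None, :] / nz) / nz).astype(
        np.result_type(data.dtype, np.complex64)
    )
    return np.tensordot(data, F, axes=([1], [0]))  # (n_points, ..., nz)


def grid_and_fft(
    raw: np.ndarray,
    trajectory: SpiralTrajectory,
    weights: np.ndarray,
    matrix: int = 32,
    nz: int = 11,
    operator: GriddingOperator | None = None,
) -> np.ndarray:
    """Reconstruct per-coil image series from averaged raw data.

    ``raw``: (n_points, n_kz, fa, coil) → returns (nx, ny, nz, fa, coil).
    """
    if raw.ndim != 4:
        raise ValueError(f"expected a 4-D averaged tensor, got {raw.shape}")
    if raw.shape[0] != trajectory.n_points or weights.size != trajectory.n_points:
        raise ValueError("raw/trajectory/weights shapes are inconsistent")
    op = operator or GriddingOperator(trajectory, matrix=matrix)
    n_points, n_kz, n_fa, n_coil = raw.shape
    # in-plane gridding of the measured kz planes first (cheaper), then the
    # centred zero-filled kz → z transform on the small cropped images
    wdata = raw * weights[:, None, None, None].astype(np.float32)
    img = op.adjoint(wdata.reshape(n_points, -1))  # (matrix, matrix, kz·fa·coil)
    img = img.reshape(matrix, matrix, n_kz, n_fa, n_coil)
    kzv = np.arange(n_kz) - n_kz // 2
    zv = np.arange(nz) - nz // 2
    F = (np.exp(2j * np.pi * kzv[:, None] * zv[None, :] / nz) / nz).astype(img.dtype)
    return np.einsum("xykfc,kz->xyzfc", img, F)


def noise_gain_map(
    trajectory: SpiralTrajectory,
    weights: np.ndarray,
    operator: GriddingOperator | None = None,
    n_kz: int = 5,
    nz: int = 11,
) -> np.ndarray:
    """Per-voxel amplitude gain of the recon chain for white input noise.

    For i.i.d. unit-variance raw noise, the reconstructed voxel variance is
    the squared row norm of the linear chain (weights → gridding → FFT →
    deapodisation), times the kz-transform factor n_kz/nz².  Used to
    normalise voxel-domain noise estimates back to the raw per-sample scale.
    """
    op = operator or GriddingOperator(trajectory)
    probe = np.diag(weights.astype(np.complex64))
    img = op.adjoint(probe)  # (matrix, matrix, n_points)
    g_xy = np.sqrt((np.abs(img) ** 2).sum(axis=-1))
    return g_xy * math.sqrt(n_kz) / nz


def estimate_noise(
    raw: RawKSpace,
    weights: np.ndarray,
    operator: GriddingOperator | None = None,
    fa_stride: int = 16,
) -> np.ndarray:
    """Voxel-domain noise samples per coil from interleaved average differences.

    Consecutive average pairs are subtracted (and scaled by 1/√2) so the
    signal cancels, and the differences are pushed through the same gridding
    chain; each voxel is divided by the chain's noise gain so the samples
    carry the raw per-sample covariance scale.  Returns (n_samples, n_coil)
    complex noise realisations.
    """
    if raw.n_averages < 2:
        raise ValueError("noise estimation needs at least 2 averages")
    op = operator or GriddingOperator(raw.trajectory, matrix=raw.matrix)
    gain = noise_gain_map(raw.trajectory, weights, op, n_kz=raw.n_kz, nz=raw.nz)
    diffs = (raw.data[..., 1::2] - raw.data[..., 0::2]) / math.sqrt(2.0)
    n_pairs = diffs.shape[-1]
    out = []
    for p in range(n_pairs):
        sub = diffs[:, :, ::fa_stride, :, p]
        img = grid_and_fft(
            sub, raw.trajectory, weights, matrix=raw.matrix, nz=raw.nz, operator=op
        )
        img = img / gain[:, :, None, None, None]
        out.append(img.reshape(-1, raw.n_coils))
    return np.concatenate(out, axis=0)


def noise_covariance(noise_samples: np.ndarray) -> np.ndarray:
    """Hermitian coil covariance of (n_samples, n_coil) complex noise."""
    n = noise_samples.shape[0]
    return noise_samples.conj().T @ noise_samples / n


def wsvd_combine(per_coil: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Whitened-SVD rank-1 coil combination per voxel.

    ``per_coil``: (nx, ny, nz, fa, coil).  Each voxel's coil×FA matrix is
    whitened by the inverse matrix square root of the noise covariance and
    replaced by its principal temporal component scaled by the principal
    singular value, rescaled so the voxel's combined energy matches the
    original (unwhitened) data energy; the phase convention makes the
    dominant coil weight real-positive.  The temporal *shape* is invariant
    to invertible coil recombination with correspondingly transformed
    covariance; the amplitude follows the original data units.  Returns
    (nx, ny, nz, fa).
    """
    nx, ny, nzz, n_fa, n_coil = per_coil.shape
    cov = np.asarray(cov, dtype=complex)
    evals, evecs = np.linalg.eigh(cov)
    if np.any(evals <= 0) or evals.min() / evals.max() < 1e-12:
        raise np.linalg.LinAlgError(
            "noise covariance is singular; regularise it (e.g. add a small "
            "multiple of the identity) before combining"
        )
    w_inv_sqrt = ((evecs / np.sqrt(evals)) @ evecs.conj().T).astype(
        np.result_type(per_coil.dtype, np.complex64)
    )
    X = per_coil.reshape(-1, n_fa, n_coil) @ w_inv_sqrt.T  # whitened
    # principal coil vector from the coil-space covariance of each voxel
    R = np.matmul(X.conj().transpose(0, 2, 1), X)
    rvals, rvecs = np.linalg.eigh(R)
    u = rvecs[:, :, -1]  # (nvox, coil) principal coil weights
    dom = np.argmax(np.abs(u), axis=1)
    phase = u[np.arange(u.shape[0]), dom]
    phase = np.where(np.abs(phase) > 0, phase / np.abs(phase), 1.0)
    u = u * np.conj(phase)[:, None]
    combined = np.matmul(X, u[:, :, None])[:, :, 0]  # = s₁·(principal temporal comp)
    # restore original data units per voxel
    orig = np.linalg.norm(per_coil.reshape(-1, n_fa * n_coil), axis=1)
    whit = np.linalg.norm(X.reshape(-1, n_fa * n_coil), axis=1)
    kappa = np.divide(orig, whit, out=np.zeros_like(orig), where=whit > 0)
    combined *= kappa[:, None]
    return combined.reshape(nx, ny, nzz, n_fa)


def mppca_denoise(series: np.ndarray, return_info: bool = False):
    """Marchenko-Pastur PCA denoising of a complex image series.

    The series (nx, ny, nz, fa) is flattened to an (n_voxels, 2·fa) real
    matrix by concatenating real and imaginary parts along the FA dimension;
    singular values consistent with the Marchenko-Pastur bulk of pure noise
    are nulled and the series is rebuilt.
    """
    x = np.asarray(series)
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    shape = x.shape
    n_fa = shape[-1]
    X = x.reshape(-1, n_fa)
    nvox = X.shape[0]
    if nvox < 2:
        raise ValueError("need at least 2 voxels for MP-PCA")
    M = np.concatenate([X.real, X.imag], axis=1).astype(np.float64)  # (nvox, 2·fa)
    n, m = M.shape
    if n < m:
        raise ValueError("MP-PCA expects at least as many voxels as FA components")
    # eigendecomposition of the (m × m) Gram matrix is much cheaper than a
    # full SVD of the tall matrix and gives the identical spectrum
    G = M.T @ M
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1]
    s = np.sqrt(np.clip(evals[order], 0.0, None))
    V = evecs[:, order]
    vals = s**2 / n  # descending
    # Veraart-style bulk detection: keep the smallest p for which the
    # remaining spectrum is consistent with pure noise
    p_keep = m
    sigma2 = 0.0
    for p in range(m):
        tail = vals[p:]
        sig_mean = tail.mean()
        sig_range = (vals[p] - vals[-1]) / (4.0 * math.sqrt((m - p) / n))
        if sig_range <= sig_mean:
            p_keep = p
            sigma2 = sig_mean
            break
    Vk = V[:, :p_keep]
    D = (M @ Vk) @ Vk.T
    out = (D[:, :n_fa] + 1j * D[:, n_fa:]).reshape(shape)
    if return_info:
        return out, {"rank": p_keep, "sigma2": sigma2}
    return out


def reconstruct(raw: RawKSpace, config: ReconConfig | None = None) -> ImageSeries:
    """Full chain: average → DCF → gridding → WSVD → (MP-PCA) → images.

    Also emits the bSSFP-type anatomical magnitude images: the mean
    magnitude over all PCr-carrier FA indices (first and third 200-blocks)
    and over all ATP-carrier indices.
    """
    cfg = config or ReconConfig()
    stage = "density compensation"
    try:
        weights = voronoi_dcf(raw.trajectory)
        if cfg.hanning:
            weights = apply_hanning(weights, raw.trajectory)
        stage = "gridding"
        op = GriddingOperator(
            raw.trajectory,
            matrix=cfg.matrix,
            oversampling=cfg.oversampling,
            width=cfg.kernel_width,
        )
        avg = raw.data.mean(axis=4)
        per_coil = grid_and_fft(
            avg, raw.trajectory, weights, matrix=cfg.matrix, nz=cfg.nz, operator=op
        )
        stage = "noise estimation"
        if raw.n_averages >= 2:
            noise = estimate_noise(raw, weights, operator=op, fa_stride=cfg.noise_fa_stride)
            cov = noise_covariance(noise)
            scale = np.mean(np.abs(np.diag(cov)))
            if scale == 0 or not np.all(np.isfinite(cov)):
                cov = np.eye(raw.n_coils)
            else:
                cov = cov + 1e-6 * scale * np.eye(raw.n_coils)
        else:
            cov = np.eye(raw.n_coils)
        stage = "coil combination"
        combined = wsvd_combine(per_coil, cov)
        stage = "denoising"
        if cfg.denoise:
            combined = mppca_denoise(combined)
    except Exception as exc:
        raise RuntimeError(f"reconstruction failed during {stage}: {exc}") from exc

    n_fa = combined.shape[-1]
    half = n_fa // 4
    pcr_idx = np.r_[0:half, 2 * half : 3 * half]
    atp_idx = np.r_[half : 2 * half, 3 * half : 4 * half]
    return ImageSeries(
        data=combined,
        fov=raw.fov,
        pcr_image=np.abs(combined[..., pcr_idx]).mean(axis=-1),
        atp_image=np.abs(combined[..., atp_idx]).mean(axis=-1),
        per_coil=per_coil,
        noise_cov=cov,
    )
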