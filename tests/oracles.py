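"""Independent reference implementations used only by the test suite.

These share no propagation, geometry or clustering code with the package:
the spin-dynamics oracles integrate the Bloch-McConnell ODE with explicit
first-order stepping (plain Euler at nanosecond steps, or Euler with exact
per-pool precession splitting at microsecond steps), the Voronoi oracle
builds each cell directly as an intersection of half-planes, the
conditioning oracle re-executes the phasing/concatenation recipe
step by step, and the cluster oracle is a literal flood fill.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


# ----------------------------------------------------------------------
# Bloch-McConnell integrators
# ----------------------------------------------------------------------


@njit(cache=True)
def euler_free(A, b, m, dt, duration):
    """Plain explicit Euler for dm/dt = A m + b."""
    n_steps = int(round(duration / dt))
    out = m.copy()
    for _ in range(n_steps):
        out = out + dt * (A @ out + b)
    return out


@njit(cache=True)
def euler_split_free(omega, r1, r2, m0, K, m, dt, duration):
    """Euler with exact per-pool precession: rotation applied analytically
    each step, relaxation + exchange stepped first order.

    omega: (P,) rad/s; r1, r2: (P,) 1/s; m0: (P,); K: (P, P) exchange
    (K[i, j] = rate j→i off-diagonal, diagonal balances); m: (3P,).
    """
    P = omega.size
    n_steps = int(round(duration / dt))
    out = m.copy()
    for _ in range(n_steps):
        # relaxation + exchange (slow part), first-order step
        d = np.zeros(3 * P)
        for p in range(P):
            d[3 * p] += -r2[p] * out[3 * p]
            d[3 * p + 1] += -r2[p] * out[3 * p + 1]
            d[3 * p + 2] += r1[p] * (m0[p] - out[3 * p + 2])
            for q in range(P):
                if K[p, q] != 0.0:
                    for c in range(3):
                        d[3 * p + c] += K[p, q] * out[3 * q + c]
        out = out + dt * d
        # exact precession for this step
        for p in range(P):
            ca = math.cos(omega[p] * dt)
            sa = math.sin(omega[p] * dt)
            x, y = out[3 * p], out[3 * p + 1]
            out[3 * p] = ca * x - sa * y
            out[3 * p + 1] = sa * x + ca * y
    return out


def generator_arrays(params):
    """(omega, r1, r2, m0, K) arrays of a SpinSystemParams-like object."""
    m0, t1, t2, ppm = params.pools()
    omega = 2.0 * np.pi * (ppm * params.larmor_hz_per_ppm + params.delta_b0)
    return omega, 1.0 / t1, 1.0 / t2, m0, params.exchange_matrix()


def dense_generator(params):
    """Full (A, b) of the flattened Bloch-McConnell ODE, built independently."""
    omega, r1, r2, m0, K = generator_arrays(params)
    P = omega.size
    A = np.zeros((3 * P, 3 * P))
    b = np.zeros(3 * P)
    for p in range(P):
        A[3 * p, 3 * p] = -r2[p]
        A[3 * p + 1, 3 * p + 1] = -r2[p]
        A[3 * p, 3 * p + 1] = -omega[p]
        A[3 * p + 1, 3 * p] = omega[p]
        A[3 * p + 2, 3 * p + 2] = -r1[p]
        b[3 * p + 2] = r1[p] * m0[p]
        for q in range(P):
            if K[p, q] != 0.0:
                for c in range(3):
                    A[3 * p + c, 3 * q + c] += K[p, q]
    return A, b


def _axis_rotation(alpha, phase):
    """3×3 rotation about the transverse axis at azimuth ``phase``."""
    from scipy.spatial.transform import Rotation

    axis = np.array([math.cos(phase), math.sin(phase), 0.0])
    return Rotation.from_rotvec(alpha * axis).as_matrix()


def euler_evolution(params, schedule, dt=1e-6):
    """Full 800-sample evolution by the splitting integrator.

    Walks the schedule's event list with its own interpreter: rotations via
    scipy Rotation, preparation efficiencies on Mz, crushers zeroing
    transverse components, sampling at pulse end + Te with receiver phase
    matching the RF phase and the active carrier.
    """
    from cki.spin_model import gaussian_profile

    cfg = schedule.config
    omega, r1, r2, m0, K = generator_arrays(params)
    P = omega.size
    larmor = params.larmor_hz_per_ppm
    m = np.zeros(3 * P)
    m[2::3] = m0
    samples = np.zeros(schedule.n_excitations, dtype=complex)

    def evolve(mm, duration):
        if duration <= 0:
            return mm
        return euler_split_free(omega, r1, r2, m0, K, mm, dt, duration)

    i = 0
    for ev in schedule.events:
        kind = ev.pulse.kind
        if kind == "inversion":
            eps2 = np.asarray(ev.pulse.shape["efficiencies"], dtype=float)
            eps = np.concatenate(
                [eps2, np.full(P - 2, float(ev.pulse.shape.get("pi_efficiency", 1.0)))]
            )
            half = ev.pulse.duration / 2.0
            m = evolve(m, half)
            m[2::3] *= eps
            m = evolve(m, half + cfg.post_inv_delay + cfg.crusher_duration)
            m[0::3] = 0.0
            m[1::3] = 0.0
        elif kind == "excitation":
            carrier_ppm = ev.pulse.carrier_offset
            fc = carrier_ppm * larmor
            block_start = ev.meta["block_start"]
            half = cfg.pulse_duration / 2.0
            m = evolve(m, half)
            phase = math.radians(ev.pulse.rf_phase) + 2.0 * math.pi * fc * (
                ev.time + half - block_start
            )
            ppm = params.pools()[3]
            for p in range(P):
                off = ppm[p] * larmor + params.delta_b0 - fc
                alpha = math.radians(ev.pulse.nominal_flip) * float(
                    gaussian_profile(off, ev.pulse.shape["fwhm_hz"])
                )
                R = _axis_rotation(alpha, phase)
                m[3 * p : 3 * p + 3] = R @ m[3 * p : 3 * p + 3]
            m = evolve(m, half)
            te_eff = ev.meta["te"]
            m = evolve(m, te_eff)
            t_samp = ev.time + cfg.pulse_duration + te_eff
            demod = np.exp(
                -1j
                * (
                    2.0 * math.pi * fc * (t_samp - block_start)
                    + math.radians(ev.pulse.rf_phase)
                )
            )
            sig = sum(m[3 * p] + 1j * m[3 * p + 1] for p in range(P))
            samples[i] = sig * demod
            m = evolve(m, ev.meta["tr"] - cfg.pulse_duration - te_eff)
            i += 1
        elif kind == "delay" and ev.meta.get("role") == "block_pause":
            m = evolve(m, ev.pulse.duration)
    return samples


# ----------------------------------------------------------------------
# geometry / conditioning / clustering oracles
# ----------------------------------------------------------------------


def halfplane_voronoi_areas(points: np.ndarray, disc) -> np.ndarray:
    """Voronoi cell areas by direct half-plane intersection with the disc.

    For every site the cell is built by intersecting the clip disc with the
    bisector half-planes against all other sites — no Voronoi diagram.
    """
    import shapely.geometry as geom

    n = points.shape[0]
    bound = disc.bounds
    big = 4.0 * max(abs(b) for b in bound) + 10.0
    areas = np.empty(n)
    for i in range(n):
        cell = disc
        pi = points[i]
        for j in range(n):
            if j == i:
                continue
            pj = points[j]
            mid = 0.5 * (pi + pj)
            d = pj - pi
            norm = math.hypot(d[0], d[1])
            if norm == 0:
                continue
            d = d / norm
            t = np.array([-d[1], d[0]])
            # rectangle on pi's side of the bisector
            corners = [
                mid + big * t,
                mid - big * t,
                mid - big * t - big * d,
                mid + big * t - big * d,
            ]
            cell = cell.intersection(geom.Polygon(corners))
            if cell.is_empty:
                break
        areas[i] = cell.area
    return areas


def conditioning_oracle(samples, target, x):
    """Literal re-execution of the phasing/concatenation recipe."""
    samples = np.asarray(samples)
    pcr = samples[target == "PCr"]
    atp = samples[target != "PCr"]
    odd_pcr = samples[(target == "PCr") & (x % 2 == 1)]
    phi_pcr = np.angle(np.mean(odd_pcr))
    phi_atp = np.angle(np.mean(atp))
    pcr = pcr * np.exp(-1j * phi_pcr)
    atp = atp * np.exp(-1j * phi_atp)
    vec = np.concatenate([pcr.real, pcr.imag, atp.real])
    return vec / np.linalg.norm(vec)


def flood_fill_clusters(mask: np.ndarray, connectivity: int = 6):
    """Connected components of a 3-D boolean mask by explicit flood fill."""
    if connectivity == 6:
        neigh = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    else:
        neigh = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
    visited = np.zeros_like(mask, dtype=bool)
    comps = []
    for idx in np.argwhere(mask):
        idx = tuple(idx)
        if visited[idx]:
            continue
        stack = [idx]
        visited[idx] = True
        comp = []
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for d in neigh:
                nb = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                if all(0 <= nb[a] < mask.shape[a] for a in range(3)):
                    if mask[nb] and not visited[nb]:
                        visited[nb] = True
                        stack.append(nb)
        comps.append(sorted(comp))
    return comps
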