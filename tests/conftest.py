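"""Shared fixtures: schedules, dictionaries and phantom datasets.

The heavier dictionaries are session-scoped so that the acceptance-style
experiments (Monte-Carlo precision, bias sweeps, end-to-end recovery)
reuse them instead of regenerating per test.
"""

from __future__ import annotations

import numpy as np
import pytest

from cki import dictionary as dct
from cki import phantom as ph
from cki import recon, sequence
from cki.spin_model import SpinSystemParams

# operating point used across the precision/bias experiments: typical human
# gray-matter values with the T1 value that is on-grid by construction
OPERATING_POINT = SpinSystemParams(k_ck=0.3, cr=1.25, t1_pcr=4.5, delta_b0=0.0)

# per-real-component raw-noise SD for the default phantom at 4 averages:
# yields in-vivo-plausible matched SNR (~29 dB) and voxelwise kCK scatter of
# a few percent, comparable to the reported intrasession reproducibility
REALISTIC_NOISE_SIGMA = 10.0


@pytest.fixture(scope="session")
def schedule():
    return sequence.build_schedule()


@pytest.fixture(scope="session")
def short_schedule():
    """Reduced pattern (20 excitations per block) for fast unit tests."""
    return sequence.build_schedule(sequence.SequenceConfig(n_per_block=20))


@pytest.fixture(scope="session")
def selfmatch_dictionary(schedule):
    """Coarse 4-D grid (≤ 5000 atoms) for exhaustive self-match checks."""
    grid = dct.ParameterGrid(
        k_ck=np.round(np.arange(0.10, 0.5001, 0.05), 4),
        cr=np.round(np.arange(0.8, 1.8001, 0.2), 4),
        t1_pcr=np.round(np.arange(2.5, 6.5001, 0.5), 4),
        delta_b0=np.round(np.arange(-6.0, 6.001, 1.5), 4),
    )
    assert grid.size <= 5000
    return dct.generate_dictionary(grid, schedule)


@pytest.fixture(scope="session")
def mc_dictionary(schedule):
    """Wide grid for the noise Monte-Carlo (covers several SDs of error)."""
    grid = dct.ParameterGrid(
        k_ck=np.round(np.arange(0.10, 0.5001, 0.01), 4),
        cr=np.round(np.arange(0.8, 1.8001, 0.05), 4),
        t1_pcr=np.round(np.arange(2.5, 6.5001, 0.25), 4),
        delta_b0=np.arange(-6.0, 6.001, 2.0),
    )
    return dct.generate_dictionary(grid, schedule)


@pytest.fixture(scope="session")
def bias_dictionary(schedule):
    """Locally refined grid so quantization does not dominate bias estimates."""
    grid = dct.ParameterGrid(
        k_ck=np.round(np.arange(0.25, 0.4001, 0.0025), 4),
        cr=np.round(np.arange(1.05, 1.4501, 0.0125), 4),
        t1_pcr=np.round(np.arange(3.5, 5.5001, 0.1), 4),
        delta_b0=np.arange(-2.0, 2.001, 1.0),
    )
    return dct.generate_dictionary(grid, schedule)


@pytest.fixture(scope="session")
def phantom_dictionary(schedule):
    """Grid containing the phantom tissue values exactly (kCK 0.28/0.30,
    Cr 1.23/1.27, T1PCr 4.00/4.50/4.67 are all on-grid)."""
    grid = dct.ParameterGrid(
        k_ck=np.round(np.arange(0.24, 0.3601, 0.01), 4),
        cr=np.round(np.arange(0.95, 1.5501, 0.04), 4),
        t1_pcr=np.round(np.arange(3.82, 5.3601, 0.17), 4),
        delta_b0=np.arange(-6.0, 6.001, 2.0),
    )
    return dct.generate_dictionary(grid, schedule)


@pytest.fixture(scope="session")
def fcki_dictionary(schedule):
    """kCK-dense grid with T1PCr fixed at 4.5 s for the functional analysis."""
    grid = dct.ParameterGrid(
        k_ck=np.round(np.arange(0.15, 0.4501, 0.005), 4),
        cr=np.round(np.arange(1.0, 1.6001, 0.05), 4),
        t1_pcr=np.array([4.5]),
        delta_b0=np.arange(-6.0, 6.001, 2.0),
    )
    return dct.generate_dictionary(grid, schedule)


@pytest.fixture(scope="session")
def default_trajectory():
    return recon.design_spiral()


@pytest.fixture(scope="session")
def full_coverage_trajectory():
    return recon.design_spiral(n_points=3000, coverage=1.0)


@pytest.fixture(scope="session")
def mild_b0_geometry():
    """Default 3-D phantom geometry with a mild (well-shimmed) ΔB0 field."""
    return ph.PhantomGeometry(b0_amplitude_hz=5.0, b0_frontal_hz=4.0)


@pytest.fixture(scope="session")
def exact_geometry():
    """z-invariant, zero-jitter geometry: exactly invertible forward model."""
    return ph.PhantomGeometry(
        z_invariant=True,
        jitter_sd={"k_ck": 0.0, "cr": 0.0, "t1_pcr": 0.0},
        b0_amplitude_hz=5.0,
        b0_frontal_hz=4.0,
    )


@pytest.fixture(scope="session")
def exact_pipeline(schedule, exact_geometry, full_coverage_trajectory):
    """Noiseless exactly-invertible dataset reconstructed once for all
    end-to-end recovery checks (ΔB0 snapped to the 2 Hz analysis grid so the
    nearest-grid tuple is unambiguous)."""
    phm = ph.make_phantom(seed=1, geometry=exact_geometry)
    phm.delta_b0[:] = 2.0 * np.round(phm.delta_b0 / 2.0)
    coil = ph.make_coil_model(n_coils=2, shape=phm.shape)
    raw = ph.forward_simulate(
        phm, schedule, coil, full_coverage_trajectory,
        n_averages=2, noise_sigma=0.0, seed=0,
    )
    series = recon.reconstruct(raw, recon.ReconConfig(denoise=False, hanning=False))
    return {"phantom": phm, "raw": raw, "series": series}


@pytest.fixture(scope="session")
def fcki_activation_result(schedule, mild_b0_geometry, default_trajectory, fcki_dictionary):
    """Seeded realistic-noise functional experiment with a 15% occipital
    activation, analysed once for the cluster/Dice checks."""
    from cki import analysis

    rest_ph = ph.make_phantom(seed=2, geometry=mild_b0_geometry)
    stim_ph = ph.inject_activation(rest_ph, relative_increase=0.15)
    coil = ph.make_coil_model(n_coils=4, shape=rest_ph.shape)
    rest = ph.forward_simulate(
        rest_ph, schedule, coil, default_trajectory, n_averages=4,
        noise_sigma=REALISTIC_NOISE_SIGMA, seed=31,
    )
    stim = ph.forward_simulate(
        stim_ph, schedule, coil, default_trajectory, n_averages=4,
        noise_sigma=REALISTIC_NOISE_SIGMA, seed=32,
    )
    diff, *_ = analysis.fcki_map(
        rest, stim, fcki_dictionary, schedule, mask=rest_ph.brain_mask
    )
    return {"phantom": rest_ph, "diff": diff}
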