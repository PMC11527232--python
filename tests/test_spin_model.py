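"""Bloch-McConnell propagation against closed forms and Euler oracles."""

import math

import numpy as np
import pytest

from cki import spin_model as sm
from cki.sequence import PulseSpec, SequenceConfig, build_schedule
from cki.spin_model import (
    SpinState,
    SpinSystemParams,
    ThreePoolParams,
    apply_prep,
    apply_rf,
    equilibrium_state,
    free_evolve,
    gaussian_profile,
    simulate_evolution,
    simulate_evolution_batch,
    simulate_three_pool,
)

from oracles import (
    dense_generator,
    euler_evolution,
    euler_free,
    euler_split_free,
    generator_arrays,
)

P0 = SpinSystemParams(k_ck=0.3, cr=1.25, t1_pcr=4.5, delta_b0=5.0)


def test_inversion_recovery_closed_form():
    """With exchange off, inverted PCr recovers as cr·(1 − 2e^(−t/T1))."""
    p = SpinSystemParams(k_ck=0.0, cr=1.25, t1_pcr=4.5)
    state = equilibrium_state(p)
    state.m[2] *= -1.0
    for t in (0.05, 0.5, 2.0):
        out = free_evolve(state, p, t)
        assert out.m[2] == pytest.approx(p.cr * (1 - 2 * math.exp(-t / p.t1_pcr)), rel=1e-12)
        assert out.m[5] == pytest.approx(1.0, rel=1e-12)


def test_equilibrium_is_fixed_point():
    eq = equilibrium_state(P0)
    out = free_evolve(eq, P0, 1.234)
    np.testing.assert_allclose(out.m, eq.m, atol=1e-12)


def test_free_evolve_against_plain_euler():
    """Matrix exponential vs straightforward explicit Euler (1st-order convergence)."""
    rng = np.random.default_rng(42)
    A, b = dense_generator(P0)
    m0 = rng.standard_normal(6)
    ref = free_evolve(SpinState(m0.copy()), P0, 0.01982).m
    errs = []
    for dt in (1e-7, 1e-8):
        m = euler_free(A, b, m0.copy(), dt, 0.01982)
        errs.append(np.linalg.norm(m - ref) / np.linalg.norm(ref))
    assert errs[1] < 2e-4
    # first-order convergence towards the matrix-exponential solution
    assert errs[0] / errs[1] == pytest.approx(10.0, rel=0.2)


def test_free_evolve_against_split_euler_100_draws():
    """Propagator ≡ fine-step Euler (exact-precession splitting) on random draws."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        p = SpinSystemParams(
            k_ck=rng.uniform(0.0, 0.6),
            cr=rng.uniform(0.5, 6.0),
            t1_pcr=rng.uniform(2.0, 7.0),
            delta_b0=rng.uniform(-25.0, 25.0),
        )
        m0 = rng.standard_normal(6)
        duration = rng.uniform(1e-3, 50e-3)
        duration = round(duration / 1e-6) * 1e-6
        ref = free_evolve(SpinState(m0.copy()), p, duration).m
        om, r1, r2, m0p, K = generator_arrays(p)
        m = euler_split_free(om, r1, r2, m0p, K, m0.copy(), 1e-6, duration)
        assert np.linalg.norm(m - ref) / np.linalg.norm(ref) <= 1e-4


def test_free_evolve_validates_inputs():
    with pytest.raises(ValueError):
        free_evolve(equilibrium_state(P0), P0, -1.0)
    with pytest.raises(ValueError):
        bad = SpinSystemParams(k_ck=-0.1, cr=1.0, t1_pcr=1.0)
        free_evolve(equilibrium_state(P0), bad, 0.1)


def test_rf_on_resonance_90():
    p = SpinSystemParams(k_ck=0.0, cr=1.0, t1_pcr=4.5, delta_b0=0.0)
    pulse = PulseSpec(
        "excitation", 0.01, nominal_flip=90.0, rf_phase=0.0, carrier_offset=0.0,
        shape={"fwhm_hz": 170.0},
    )
    out = apply_rf(equilibrium_state(p), pulse, p)
    assert out.m[2] == pytest.approx(0.0, abs=1e-12)  # PCr Mz → 0
    assert abs(out.transverse(0)) == pytest.approx(1.0, rel=1e-12)


def test_rf_profile_attenuation_at_atp_offset():
    """A 304 Hz off-carrier pool sees ~1.4e-4 of the nominal flip."""
    off = 2.52 * sm.LARMOR_HZ_PER_PPM
    g = float(gaussian_profile(off, 170.0))
    assert g == pytest.approx(1.403e-4, rel=1e-3)
    p = SpinSystemParams(k_ck=0.0, cr=1.0, t1_pcr=4.5, delta_b0=0.0)
    pulse = PulseSpec(
        "excitation", 0.01, nominal_flip=35.0, rf_phase=0.0, carrier_offset=0.0,
        shape={"fwhm_hz": 170.0},
    )
    out = apply_rf(equilibrium_state(p), pulse, p)
    expected = math.sin(math.radians(35.0) * g)
    assert abs(out.transverse(1)) == pytest.approx(expected, rel=1e-9)


def test_hard_pulse_mode_matches_instant_on_resonance():
    """Piecewise-constant decomposition of the shaped pulse: same flip within 1%."""
    p = SpinSystemParams(k_ck=0.0, cr=1.0, t1_pcr=1e6, delta_b0=0.0, t1_atp=1e6,
                         t2_pcr=1e6, t2_atp=1e6)
    pulse = PulseSpec(
        "excitation", 0.01, nominal_flip=35.0, rf_phase=0.0, carrier_offset=0.0,
        shape={"fwhm_hz": 170.0},
    )
    inst = apply_rf(equilibrium_state(p), pulse, p)
    hard = apply_rf(equilibrium_state(p), pulse, p, mode="hard", n_segments=400)
    a_inst = math.atan2(abs(inst.transverse(0)), inst.m[2])
    a_hard = math.atan2(abs(hard.transverse(0)), hard.m[2])
    assert a_hard == pytest.approx(a_inst, rel=0.01)


def test_rf_rejects_bad_flip():
    p = P0
    pulse = PulseSpec("excitation", 0.01, nominal_flip=10.0, shape={"fwhm_hz": 170.0})
    with pytest.raises(ValueError):
        apply_rf(equilibrium_state(p), PulseSpec("delay", 0.01), p)


def test_prep_inversion_and_identity():
    p = SpinSystemParams(k_ck=0.0, cr=1.25, t1_pcr=4.5)
    prep = PulseSpec("inversion", 1e-9, shape={"efficiencies": (-1.0, 1.0)})
    out = apply_prep(
        equilibrium_state(p), prep, p, post_delay=1e-9, crusher_duration=1e-9,
        timing="start",
    )
    assert out.m[2] == pytest.approx(-p.cr, rel=1e-6)
    assert out.m[5] == pytest.approx(1.0, rel=1e-6)
    assert abs(out.transverse(0)) == 0.0
    # identity preparation = free evolution over the full window
    prep50 = PulseSpec("inversion", 0.04, shape={"efficiencies": (1.0, 1.0)})
    ident = apply_prep(equilibrium_state(P0), prep50, P0)
    ref = free_evolve(equilibrium_state(P0), P0, 0.05)
    ref.m[0::3] = 0.0
    ref.m[1::3] = 0.0
    np.testing.assert_allclose(ident.m, ref.m, atol=1e-12)


def test_prep_double_inversion_against_euler():
    p = SpinSystemParams(k_ck=0.3, cr=1.25, t1_pcr=4.5)
    prep = PulseSpec("inversion", 0.04, shape={"efficiencies": (-1.0, -1.0)})
    out = apply_prep(equilibrium_state(p), prep, p, timing="mid")
    om, r1, r2, m0p, K = generator_arrays(p)
    m = equilibrium_state(p).m
    m = euler_split_free(om, r1, r2, m0p, K, m, 1e-6, 0.02)
    m[2::3] *= -1.0
    m = euler_split_free(om, r1, r2, m0p, K, m, 1e-6, 0.03)
    m[0::3] = 0.0
    m[1::3] = 0.0
    np.testing.assert_allclose(out.m, m, atol=1e-6)


def test_prep_rejects_bad_efficiency():
    prep = PulseSpec("inversion", 0.04, shape={"efficiencies": (-1.5, 1.0)})
    with pytest.raises(ValueError):
        apply_prep(equilibrium_state(P0), prep, P0)


def test_simulation_deterministic(short_schedule):
    a = simulate_evolution(P0, short_schedule)
    b = simulate_evolution(P0, short_schedule)
    np.testing.assert_array_equal(a.samples, b.samples)


def test_atp_contamination_of_pcr_samples_below_one_percent(schedule):
    """With exchange off, the non-excited pool adds < 1% to the targeted signal."""
    base = SpinSystemParams(k_ck=0.0, cr=1.25, t1_pcr=4.5, delta_b0=0.0)
    dead_atp = SpinSystemParams(
        k_ck=0.0, cr=1.25, t1_pcr=4.5, delta_b0=0.0, t2_atp=1e-6
    )
    full = simulate_evolution(base, schedule).samples
    pcr_only = simulate_evolution(dead_atp, schedule).samples
    pcr_mask = schedule.pcr_mask
    contamination = np.abs(full[pcr_mask] - pcr_only[pcr_mask])
    assert contamination.max() / np.abs(pcr_only[pcr_mask]).max() < 0.01


def test_full_evolution_against_euler_oracle(schedule):
    """End-to-end 800-sample evolution reproduced by the independent integrator."""
    p = SpinSystemParams(k_ck=0.30, cr=1.27, t1_pcr=4.67, delta_b0=0.0)
    sim = simulate_evolution(p, schedule).samples
    orc = euler_evolution(p, schedule, dt=1e-6)
    rel_rms = np.linalg.norm(sim - orc) / np.linalg.norm(sim)
    assert rel_rms <= 1e-4


def test_batch_equals_scalar_loop(schedule):
    rng = np.random.default_rng(3)
    k = rng.uniform(0.1, 0.5, 3)
    c = rng.uniform(0.8, 1.8, 3)
    t1 = rng.uniform(3.0, 6.0, 3)
    b0 = rng.uniform(-10, 10, 3)
    batch = simulate_evolution_batch(k, c, t1, b0, schedule)
    for i in range(3):
        scalar = simulate_evolution(
            SpinSystemParams(k[i], c[i], t1[i], b0[i]), schedule
        ).samples
        np.testing.assert_allclose(batch[i], scalar, rtol=2e-10, atol=1e-12)


def test_three_pool_degenerates_to_two_pool(schedule):
    p3 = ThreePoolParams(k_ck=0.3, cr=1.25, t1_pcr=4.5, delta_b0=0.0, k_atp=0.0)
    three = simulate_three_pool(p3, schedule).samples
    two = simulate_evolution(p3.two_pool(), schedule).samples
    np.testing.assert_allclose(three, two, atol=1e-10)


def test_three_pool_against_euler_oracle(schedule):
    p3 = ThreePoolParams(k_ck=0.3, cr=1.25, t1_pcr=4.5, delta_b0=0.0, k_atp=0.2)
    sim = simulate_three_pool(p3, schedule).samples
    orc = euler_evolution(p3, schedule, dt=1e-6)
    assert np.linalg.norm(sim - orc) / np.linalg.norm(sim) <= 1e-4


def test_norm_conservation_without_relaxation(short_schedule):
    """T1, T2 → ∞, no exchange: each pool's |M| is invariant under any events."""
    p = SpinSystemParams(
        k_ck=0.0, cr=1.25, t1_pcr=1e9, delta_b0=5.0, t1_atp=1e9, t2_pcr=1e9, t2_atp=1e9
    )
    state = equilibrium_state(p)
    cfg = short_schedule.config
    for ev in short_schedule.events:
        if ev.pulse.kind == "excitation":
            state = free_evolve(state, p, cfg.pulse_duration / 2)
            state = apply_rf(state, ev.pulse, p)
            state = free_evolve(state, p, ev.meta["tr"] - cfg.pulse_duration / 2)
    for pool, m0 in ((0, p.cr), (1, 1.0)):
        assert np.linalg.norm(state.pool(pool)) == pytest.approx(m0, rel=1e-9)


def test_total_longitudinal_relaxes_to_equilibrium():
    rng = np.random.default_rng(11)
    state = SpinState(rng.standard_normal(6))
    out = free_evolve(state, P0, 60.0)
    assert out.m[2] + out.m[5] == pytest.approx(P0.cr + 1.0, rel=1e-6)
    np.testing.assert_allclose([out.m[0], out.m[1], out.m[3], out.m[4]], 0.0, atol=1e-8)


def test_exchange_symmetry_under_pool_swap():
    """Relabelling pools with cr → 1/cr and swapped constants permutes the dynamics."""
    p = SpinSystemParams(k_ck=0.3, cr=1.25, t1_pcr=4.5, delta_b0=5.0)
    swapped = SpinSystemParams(
        k_ck=p.k_rev,  # forward rate of the relabelled first pool
        cr=1.0 / p.cr,
        t1_pcr=p.t1_atp,
        delta_b0=p.delta_b0,
        t1_atp=p.t1_pcr,
        t2_pcr=p.t2_atp,
        t2_atp=p.t2_pcr,
        pcr_ppm=p.atp_ppm,
        atp_ppm=p.pcr_ppm,
    )
    assert swapped.k_rev == pytest.approx(p.k_ck)
    rng = np.random.default_rng(5)
    m = rng.standard_normal(6)
    perm = [3, 4, 5, 0, 1, 2]
    out = free_evolve(SpinState(m.copy()), p, 0.05).m
    # swapped system works in units of the other pool's M0: scale by cr
    out_sw = free_evolve(SpinState((m[perm] / p.cr).copy()), swapped, 0.05).m
    np.testing.assert_allclose(out_sw * p.cr, out[perm], rtol=1e-9, atol=1e-12)
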