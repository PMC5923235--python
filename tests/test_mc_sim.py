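"""Unit and property tests for the diffusion-dimerisation simulator."""

import math

import numpy as np
import pytest
from scipy import stats

from dimerdyn import mc_sim

from conftest import DT_COARSE, K_OFF, K_ON, make_config


# ---------------------------------------------------------------------------
# time step


def test_default_timestep_half_radius_rule():
    # rms displacement sqrt(4 D dT) equals half the receptor radius
    dt = mc_sim.default_timestep(1.63, 0.0025)
    assert dt == pytest.approx(2.40e-7, rel=5e-3)
    assert math.sqrt(4 * 1.63 * dt) == pytest.approx(0.0025 / 2)


def test_default_timestep_scaling_and_errors():
    d1 = mc_sim.default_timestep(1.0, 0.002)
    assert mc_sim.default_timestep(4.0, 0.002) == pytest.approx(d1 / 4)
    with pytest.raises(ValueError):
        mc_sim.default_timestep(1.0, 0.0)
    with pytest.raises(ValueError):
        mc_sim.default_timestep(-1.0, 0.002)


def test_config_rejects_too_coarse_timestep():
    with pytest.raises(ValueError, match="too coarse"):
        make_config(n_particles=10, density=1.0, p_collision=0.1,
                    duration=0.001, dT=10 * DT_COARSE)


# ---------------------------------------------------------------------------
# single elementary step (numpy reference)


def test_step_displacements_gaussian_with_correct_variance(rng):
    # Eq. for the diffusive propagator: per-axis variance 2 D dT
    cfg = make_config(n_particles=500, density=0.005, p_collision=0.0,
                      k_off=0.0, duration=1.0, seed=1)
    ens = mc_sim.ParticleEnsemble.initial_monomers(cfg, rng)
    steps = []
    prev = ens.positions.copy()
    for _ in range(200):
        ens = mc_sim.advance_ensemble(ens, cfg, rng)
        d = ens.positions - prev
        L = cfg.box_side
        d -= L * np.round(d / L)
        steps.append(d.copy())
        prev = ens.positions.copy()
    dx = np.concatenate([s[:, 0] for s in steps])
    assert dx.size == 100_000
    var_expected = 2 * cfg.D_mon * cfg.dT
    assert dx.var() == pytest.approx(var_expected, rel=0.02)
    # normality of the per-axis displacement distribution
    _, p = stats.normaltest(dx[::10])
    assert p > 1e-3


def test_contact_pair_dimerises_at_p1(rng):
    cfg = make_config(n_particles=2, density=0.02, p_collision=1.0,
                      k_off=0.0, duration=1.0, seed=2)
    pos = np.array([[5.0, 5.0], [5.0, 5.0 + 0.8 * cfg.collision_diameter]])
    ens = mc_sim.ParticleEnsemble(
        pos, np.zeros(2, np.int8),
        np.array([[0, -1], [1, -1]], dtype=np.int64), 0.0, cfg.box_side)
    out = mc_sim.advance_ensemble(ens, cfg, rng)
    assert out.species.tolist() == [1]
    assert out.n_receptors == 2
    assert set(out.protomer_ids[0]) == {0, 1}


def test_dissociation_probability_per_step():
    # 1 - exp(-k_off dT) with k_off*dT = 0.01
    assert 1 - math.exp(-0.01) == pytest.approx(0.00995, abs=5e-6)
    cfg = make_config(n_particles=2000, density=0.02, p_collision=0.0,
                      k_off=0.01 / DT_COARSE, duration=1.0, seed=3)
    rng = np.random.default_rng(0)
    n = cfg.n_particles // 2
    pos = rng.uniform(0, cfg.box_side, size=(n, 2))
    ids = np.column_stack([np.arange(n), np.arange(n) + n]).astype(np.int64)
    ens = mc_sim.ParticleEnsemble(pos, np.ones(n, np.int8), ids, 0.0,
                                  cfg.box_side)
    out = mc_sim.advance_ensemble(ens, cfg, rng)
    n_diss = int(np.sum(out.species == 0)) // 2
    # binomial(1000, 0.00995): mean 9.95, sd ~3.1
    assert 1 <= n_diss <= 25
    assert out.n_receptors == 2 * n


def test_receptor_conservation_and_wrapping_along_trajectory(rng):
    cfg = make_config(n_particles=60, density=3.0, p_collision=0.05,
                      k_off=50.0, duration=1.0, seed=4)
    ens = mc_sim.ParticleEnsemble.initial_monomers(cfg, rng)
    for _ in range(300):
        ens = mc_sim.advance_ensemble(ens, cfg, rng)
        ens.validate()  # positions in box, id bookkeeping intact
        assert ens.n_receptors == 60


# ---------------------------------------------------------------------------
# full runs


def test_no_collision_probability_means_no_dimers():
    cfg = make_config(n_particles=50, density=2.0, p_collision=0.0,
                      duration=0.02, seed=5)
    trace = mc_sim.run_simulation(cfg)
    assert np.all(trace.dimer_count == 0)
    assert np.all(trace.n_receptors == 50)


def test_p1_no_dissociation_all_dimerise():
    cfg = make_config(n_particles=40, density=50.0, p_collision=1.0,
                      k_off=0.0, duration=1.5, seed=6)
    trace = mc_sim.run_simulation(cfg)
    assert trace.dimer_count[-1] == 20
    assert trace.monomer_count[-1] == 0


def test_trace_conservation_invariant():
    cfg = make_config(n_particles=100, density=100.0, p_collision=0.002,
                      duration=0.3, seed=7)
    trace = mc_sim.run_simulation(cfg)
    assert np.all(trace.n_receptors == 100)
    assert np.all(trace.monomer_count >= 0)
    assert np.all(trace.dimer_count >= 0)
    assert np.all(np.diff(trace.collision_events) >= 0)


# ---------------------------------------------------------------------------
# dimer_fraction


def _trace(mono, dim):
    mono = np.asarray(mono)
    dim = np.asarray(dim)
    t = np.arange(mono.size) * 0.01
    return mc_sim.SimulationTrace(t, mono, dim, np.zeros_like(mono))


def test_dimer_fraction_trivial_cases():
    f, _ = mc_sim.dimer_fraction(_trace([10] * 50, [0] * 50), burn_in=0)
    assert f == 0.0
    f, _ = mc_sim.dimer_fraction(_trace([0] * 50, [5] * 50), burn_in=0)
    assert f == 1.0
    # alternating 50/50 monomer-receptor / dimer-receptor split
    mono = np.tile([10, 0], 25)
    dim = np.tile([0, 5], 25)
    f, _ = mc_sim.dimer_fraction(_trace(mono, dim), burn_in=0)
    assert f == pytest.approx(0.5)


def test_dimer_fraction_empty_after_burn_in():
    with pytest.raises(ValueError):
        mc_sim.dimer_fraction(_trace([1, 1], [0, 0]), burn_in=2)


# ---------------------------------------------------------------------------
# mass action oracle


def test_mass_action_printed_equilibrium():
    res = mc_sim.mass_action_equilibrium(K_ON, K_OFF, 0.43)
    assert res.dimer_receptor_fraction == pytest.approx(0.098, abs=5e-4)
    assert res.K_d == pytest.approx(K_OFF / K_ON)
    # conservation: M + 2 D = rho
    assert res.monomer_density + 2 * res.dimer_density == pytest.approx(0.43)


def test_mass_action_high_density_and_edge_cases():
    res = mc_sim.mass_action_equilibrium(K_ON, K_OFF, 1000.0)
    assert res.dimer_receptor_fraction == pytest.approx(0.942, abs=1e-3)
    assert mc_sim.mass_action_equilibrium(0.0, K_OFF, 5.0).dimer_receptor_fraction == 0
    with pytest.raises(ValueError):
        mc_sim.mass_action_equilibrium(-0.1, K_OFF, 1.0)
    with pytest.raises(ValueError):
        mc_sim.mass_action_equilibrium(K_ON, 0.0, 1.0)


def test_mass_action_Kd_consistency():
    res = mc_sim.mass_action_equilibrium(0.2, 0.7, 12.0)
    assert (res.monomer_density ** 2 / res.dimer_density
            == pytest.approx(res.K_d, rel=1e-9))


# ---------------------------------------------------------------------------
# Gillespie oracle


def test_gillespie_no_association():
    tr = mc_sim.gillespie_well_mixed(0.0, K_OFF, 1.0, 100.0, 5.0, seed=0)
    assert np.all(tr.dimer_count == 0)


def test_gillespie_matches_mass_action():
    rho, area = 10.0, 30.0
    tr = mc_sim.gillespie_well_mixed(K_ON, K_OFF, rho, area, 60.0, seed=1)
    f, se = mc_sim.dimer_fraction(tr, time_weighted=True)
    expected = mc_sim.mass_action_equilibrium(K_ON, K_OFF, rho)
    # finite-size correction is O(1/N); allow it inside 3 SE + 1/N
    assert abs(f - expected.dimer_receptor_fraction) < 3 * se + 1.0 / (rho * area)


def test_gillespie_intensive_in_area():
    f1, se1 = mc_sim.dimer_fraction(
        mc_sim.gillespie_well_mixed(K_ON, K_OFF, 20.0, 20.0, 40.0, seed=2),
        time_weighted=True)
    f2, se2 = mc_sim.dimer_fraction(
        mc_sim.gillespie_well_mixed(K_ON, K_OFF, 20.0, 40.0, 40.0, seed=3),
        time_weighted=True)
    assert abs(f1 - f2) < 3 * math.hypot(se1, se2) + 0.01


def test_gillespie_argument_errors():
    with pytest.raises(ValueError):
        mc_sim.gillespie_well_mixed(K_ON, K_OFF, 1.0, 100.0, -1.0)
    with pytest.raises(ValueError):
        mc_sim.gillespie_well_mixed(K_ON, K_OFF, 0.001, 100.0, 1.0)


# ---------------------------------------------------------------------------
# calibration contracts (cheap paths only; the full calibration is
# exercised by the session fixture in the acceptance tests)


def test_calibration_zero_target():
    cfg = make_config(n_particles=50, density=5.0, p_collision=0.0,
                      k_off=0.0, duration=0.1, seed=0)
    res = mc_sim.calibrate_collision_probability(0.0, cfg)
    assert res.p_collision == 0.0
    with pytest.raises(ValueError):
        mc_sim.calibrate_collision_probability(-1.0, cfg)


def test_kernel_and_reference_step_agree_on_association_rate(rng):
    """The numba kernel and the numpy single-step implementation realise
    the same association kinetics (irreversible, dilute)."""
    cfg = make_config(n_particles=150, density=20.0, p_collision=0.05,
                      k_off=0.0, duration=0.002, seed=11,
                      record_interval=0.002)
    # kernel, several seeds
    kernel_events = []
    for s in range(6):
        tr = mc_sim.run_simulation(
            mc_sim.SimulationConfig(**{**cfg.__dict__, "seed": s}))
        kernel_events.append(tr.collision_events[-1])
    # reference stepper over the same number of elementary steps
    n_steps = int(round(cfg.duration / cfg.dT))
    ref_events = []
    for s in range(3):
        r = np.random.default_rng(100 + s)
        ens = mc_sim.ParticleEnsemble.initial_monomers(cfg, r)
        n0 = ens.positions.shape[0]
        for _ in range(n_steps):
            ens = mc_sim.advance_ensemble(ens, cfg, r)
        ref_events.append(n0 - ens.positions.shape[0])
    km, ks = np.mean(kernel_events), np.std(kernel_events, ddof=1)
    rm, rs = np.mean(ref_events), np.std(ref_events, ddof=1)
    se = math.hypot(ks / math.sqrt(len(kernel_events)),
                    rs / math.sqrt(len(ref_events)))
    assert abs(km - rm) < 3.5 * se + 2.0
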