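"""Tests for track-based kinetics: MSD, diffusion fits, rate derivations."""

import math

import numpy as np
import pandas as pd
import pytest

from dimerdyn import kinetics, synthetic
from dimerdyn.kinetics import TrackTable


def _table(rows, fi=0.030):
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    df["intensity"] = 1.0
    df["channel"] = "donor"
    return TrackTable(df, fi)


# ---------------------------------------------------------------------------
# MSD


def test_msd_ballistic_track_closed_form():
    # straight line with speed v: MSD(tau) = (v tau)^2
    v = 2.0  # um/s
    fi = 0.030
    rows = [(0, f, v * f * fi, 0.0) for f in range(20)]
    curve = kinetics.msd_curve(_table(rows), max_lag=5)
    for lag_s, m in zip(curve.lags, curve.msd):
        assert m == pytest.approx((v * lag_s) ** 2, rel=1e-12)


def test_msd_stationary_tracks_zero():
    rows = [(t, f, 1.0 * t, 2.0) for t in range(3) for f in range(10)]
    curve = kinetics.msd_curve(_table(rows), max_lag=4)
    assert np.allclose(curve.msd, 0.0)


def test_msd_weights_are_pair_counts():
    rows = [(0, f, 0.1 * f, 0.0) for f in range(10)]
    rows += [(1, f, 0.2 * f, 0.0) for f in range(5)]
    curve = kinetics.msd_curve(_table(rows), max_lag=2)
    assert curve.n_pairs[0] == (10 - 1) + (5 - 1)
    assert curve.n_tracks[0] == 2


def test_msd_empty_and_too_short():
    with pytest.raises(ValueError):
        kinetics.msd_curve(_table([]))


# ---------------------------------------------------------------------------
# diffusion fits


def test_fit_diffusion_exact_line():
    lags = np.arange(1, 6) * 0.03
    curve = kinetics.MSDCurve(lags, 4 * 2.0 * lags, np.zeros(5),
                              np.full(5, np.nan), np.full(5, 10),
                              np.full(5, 100))
    fit = kinetics.fit_diffusion(curve, n_fit_lags=4)
    assert fit.D == pytest.approx(2.0, rel=1e-12)
    assert not fit.negative


def test_fit_diffusion_recovers_generator_truth():
    tracks, _ = synthetic.gen_brownian_tracks(D=1.27, n_tracks=3000, seed=4)
    curve = kinetics.msd_curve(tracks, max_lag=8)
    fit = kinetics.fit_diffusion(curve, n_fit_lags=4)
    assert fit.ci95[0] < 1.27 < fit.ci95[1]
    assert fit.D == pytest.approx(1.27, rel=0.05)


def test_fit_diffusion_unbiased_over_replicates():
    ests = []
    for s in range(50):
        tracks, _ = synthetic.gen_brownian_tracks(D=1.63, n_tracks=150,
                                                  seed=2000 + s)
        curve = kinetics.msd_curve(tracks, max_lag=6)
        ests.append(kinetics.fit_diffusion(curve, n_fit_lags=4).D)
    assert np.mean(ests) == pytest.approx(1.63, rel=0.02)


def test_fit_diffusion_localisation_noise_intercept():
    sigma_loc = 0.04
    tracks, _ = synthetic.gen_brownian_tracks(D=1.0, n_tracks=4000,
                                              loc_noise=sigma_loc,
                                              mean_track_length=20, seed=5)
    curve = kinetics.msd_curve(tracks, max_lag=6)
    fit = kinetics.fit_diffusion(curve, n_fit_lags=5, with_offset=True)
    # measured MSD gains a constant 4*sigma_loc^2 (uncorrelated noise adds
    # 2*sigma^2 per coordinate and per end point)
    assert fit.intercept == pytest.approx(4 * sigma_loc ** 2, rel=0.25)


def test_msd_intercept_near_zero_without_noise():
    tracks, _ = synthetic.gen_brownian_tracks(D=1.63, n_tracks=3000, seed=6)
    curve = kinetics.msd_curve(tracks, max_lag=6)
    fit = kinetics.fit_diffusion(curve, n_fit_lags=5, with_offset=True)
    se = (fit.ci95[1] - fit.ci95[0]) / 3.92
    # intercept consistent with zero at the scale of the first-lag MSD
    assert abs(fit.intercept) < 0.05 * curve.msd[0] + 2 * se


# ---------------------------------------------------------------------------
# diffusion comparison


def test_compare_diffusion_identical():
    z, p, ratio = kinetics.compare_diffusion(1.5, (1.45, 1.55), 1.5,
                                             (1.45, 1.55))
    assert z == 0.0
    assert p == pytest.approx(1.0)
    assert ratio == pytest.approx(1.0)


def test_compare_diffusion_measured_coefficients():
    # monomer vs dimer diffusivities with their reported 95% CIs
    z, p, ratio = kinetics.compare_diffusion(
        1.63, (1.609, 1.647), 1.27, (1.222, 1.317),
        r1=0.0025, characteristic_length=0.020)
    assert z == pytest.approx(-13.8, abs=0.15)
    assert p < 1e-10
    assert ratio == pytest.approx(1.4, abs=0.05)


def test_saffman_delbruck_solvable_range():
    with pytest.raises(ValueError):
        kinetics.saffman_delbruck_radius_ratio(0.8, 0.02, 0.02)


# ---------------------------------------------------------------------------
# Hardt collision frequency


def test_hardt_frequency_value_and_properties():
    f = kinetics.hardt_collision_frequency(0.43, 2 * 1.63, 0.005)
    assert f == pytest.approx(0.43, abs=0.01)
    # linear in D_rel
    f2 = kinetics.hardt_collision_frequency(0.43, 4 * 1.63, 0.005)
    assert f2 == pytest.approx(2 * f, rel=1e-12)
    # vanishes with density
    assert kinetics.hardt_collision_frequency(1e-6, 3.26, 0.005) < 1e-5
    with pytest.raises(ValueError):
        kinetics.hardt_collision_frequency(1e8, 3.26, 0.005)  # b <= a


# ---------------------------------------------------------------------------
# formation-rate extrapolation


def test_constant_rate_recovers_empirical_mean():
    # lambda ~ 0: fitted amplitude equals total events/(area*total time)
    area, T, n_win = 50.0, 6.0, 10
    rng = np.random.default_rng(0)
    events = rng.uniform(0, T, size=600)
    (A, ci), (lam, _) = kinetics.extrapolate_formation_rate(
        events, [T] * n_win, area, bin_width=0.5)
    empirical = events.size / (n_win * area * T)
    assert A == pytest.approx(empirical, rel=0.15)
    assert abs(lam) < 0.15


def test_exponential_decay_recovery_within_ci():
    rate0, lam, area = 0.02, 0.5, 100.0
    hits = 0
    for s in range(10):
        events, _ = synthetic.gen_formation_events(rate0, lam, area, 19, 6.0,
                                                   seed=s)
        (A, ci), _ = kinetics.extrapolate_formation_rate(events, [6.0] * 19,
                                                         area)
        if ci[0] <= rate0 <= ci[1]:
            hits += 1
    assert hits >= 8  # 95% CI should cover the truth in most replicates


def test_extrapolate_errors():
    with pytest.raises(ValueError):
        kinetics.extrapolate_formation_rate([], [6.0], 100.0)
    with pytest.raises(ValueError):
        kinetics.extrapolate_formation_rate([0.1, 0.2], [6.0], 100.0,
                                            bin_width=6.0)


# ---------------------------------------------------------------------------
# labelling correction and derived constants


def test_labelling_correction_cases():
    assert kinetics.visible_pair_fraction(0.5, 0.5) == pytest.approx(0.5)
    assert kinetics.correct_for_labelling(1.0, 0.5, 0.5) == pytest.approx(2.0)
    # droplet labelling ratio 100:405:45
    f_d, f_a = 100 / 550, 405 / 550
    assert kinetics.visible_pair_fraction(f_d, f_a) == pytest.approx(0.268,
                                                                     abs=5e-4)
    assert kinetics.correct_for_labelling(0.0, f_d, f_a) == 0.0
    with pytest.raises(ValueError):
        kinetics.correct_for_labelling(1.0, 0.0, 0.5)


def test_derive_rate_constants_paths():
    rs = kinetics.derive_rate_constants(equilibrium=(0.098, 0.43))
    assert rs.K_d == pytest.approx(7.1, abs=0.05)
    rs = kinetics.derive_rate_constants(k_off=0.58, equilibrium=(0.098, 0.43))
    assert rs.t_half == pytest.approx(1.2, abs=0.05)
    assert rs.k_on == pytest.approx(0.58 / 7.14, rel=0.01)
    rs = kinetics.derive_rate_constants(k_off=math.log(2))
    assert rs.t_half == pytest.approx(1.0, rel=1e-12)
    with pytest.raises(ValueError):
        kinetics.derive_rate_constants()
    with pytest.raises(ValueError, match="inconsistent"):
        kinetics.derive_rate_constants(k_on=0.081, k_off=0.58,
                                       equilibrium=(0.5, 0.43))


def test_rate_constant_round_trip():
    from dimerdyn import mc_sim
    res = mc_sim.mass_action_equilibrium(0.081, 0.58, 7.7)
    rs = kinetics.derive_rate_constants(
        equilibrium=(res.dimer_receptor_fraction, 7.7))
    assert rs.K_d == pytest.approx(0.58 / 0.081, rel=1e-6)
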