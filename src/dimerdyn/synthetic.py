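"""Synthetic-data generators.

Every analysis stage in this package can be exercised without microscopy
data: these generators produce track tables, two-channel dimerisation
"movies", two-state FRET intensity traces, per-site efficiency vectors
and DEER-style distance distributions with the statistical structure the
corresponding experiments exhibit.  Each generator returns a
SyntheticTruth carrying the exact parameters (and seed) used, so
round-trip tests can assert against the generating truth without ever
letting the estimators see it.

Defaults mirror the experimental conditions: monomer diffusivity
1.63 um^2/s, 30 ms frames, donor:acceptor:unlabelled = 100:405:45,
single-step photobleaching with exponential lifetimes, lognormal spot
intensities, and two interconverting FRET states.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import mc_sim
from .interface_fit import (DistanceDistribution, EfficiencyVector,
                            ModelMatrix, SITE_LABELS_DEFAULT)
from .kinetics import FRAME_INTERVAL_DEFAULT, TrackTable

__all__ = [
    "SyntheticTruth",
    "LABELLING_DEFAULT",
    "gen_brownian_tracks",
    "gen_dimerisation_movie",
    "gen_formation_events",
    "gen_fret_intensity_traces",
    "gen_interface_dataset",
    "gen_deer_dataset",
]

# donor : acceptor : unlabelled receptor proportions in the droplet
LABELLING_DEFAULT = (100 / 550, 405 / 550, 45 / 550)


@dataclass
class SyntheticTruth:
    """Generator parameters serialised next to every synthetic dataset."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)

    def write_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        with open(path, "w") as fh:
            json.dump({"generator": self.generator, "seed": self.seed,
                       "params": self.params}, fh, indent=2, default=default)


def gen_brownian_tracks(D: float = 1.63, n_tracks: int = 500,
                        frame_interval: float = FRAME_INTERVAL_DEFAULT,
                        mean_track_length: float = 12.0,
                        max_frames: int = 200, loc_noise: float = 0.0,
                        intensity_logmean: float = math.log(300.0),
                        intensity_logsd: float = 0.4,
                        channel: str = "donor", seed: int = 0):
    """Independent 2D Brownian tracks with bleach-limited lengths.

    Per-axis steps are N(0, 2*D*dt); measured positions add Gaussian
    localisation noise of sd ``loc_noise``.  Track lengths (frames) are
    geometric with the given mean, emulating single-step photobleaching,
    truncated at ``max_frames``.
    """
    rng = np.random.default_rng(seed)
    p = 1.0 / max(mean_track_length, 1.0)
    lengths = np.minimum(rng.geometric(p, size=n_tracks), max_frames)
    lengths = np.maximum(lengths, 2)
    sd = math.sqrt(2.0 * D * frame_interval) if D > 0 else 0.0
    rows = []
    for tid, L in enumerate(lengths):
        start = rng.uniform(0.0, 20.0, size=2)
        steps = rng.normal(0.0, sd, size=(L - 1, 2)) if sd > 0 else np.zeros((L - 1, 2))
        xy = np.vstack([start, start + np.cumsum(steps, axis=0)])
        if loc_noise > 0:
            xy = xy + rng.normal(0.0, loc_noise, size=xy.shape)
        inten = rng.lognormal(intensity_logmean, intensity_logsd)
        for f in range(L):
            rows.append((tid, f, xy[f, 0], xy[f, 1], inten, channel))
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um",
                                     "intensity", "channel"])
    truth = SyntheticTruth("brownian_tracks", seed, {
        "D": D, "frame_interval": frame_interval,
        "mean_track_length": mean_track_length, "loc_noise": loc_noise,
        "n_tracks": n_tracks,
    })
    return TrackTable(df, frame_interval), truth


def gen_dimerisation_movie(config: mc_sim.SimulationConfig,
                           labelling: tuple = LABELLING_DEFAULT,
                           bleach_rates: tuple = (0.5, 0.5),
                           frame_interval: float = FRAME_INTERVAL_DEFAULT,
                           seed: int = 0):
    """Two-channel single-molecule movie from the particle simulator.

    Runs the diffusion-dimerisation Monte Carlo, assigns each receptor a
    donor/acceptor/unlabelled identity with the given proportions, draws
    exponential photobleaching lifetimes per fluorophore (clocks start at
    illumination), and derives: donor-channel tracks (every particle
    carrying an unbleached donor) and acceptor-channel tracks
    (FRET-visible donor-acceptor dimers with both dyes alive).  New
    acceptor-track appearance times are recorded as formation events.

    Returns (donor TrackTable, acceptor TrackTable, SyntheticTruth); the
    truth carries the visible formation-event times.
    """
    if abs(sum(labelling) - 1.0) > 1e-9:
        raise ValueError("labelling fractions must sum to 1")
    rng = np.random.default_rng(seed)
    cfg = replace(config, seed=int(rng.integers(2**31 - 1)))
    n_events_cap = 50 * config.n_particles
    trace, snaps, events = mc_sim._run_kernel(cfg,
                                              snapshot_interval=frame_interval,
                                              event_capacity=n_events_cap)
    n_rec = config.n_particles
    label = rng.choice(3, size=n_rec, p=list(labelling))  # 0=D, 1=A, 2=none
    lam_d, lam_a = bleach_rates
    bleach_t = np.full(n_rec, np.inf)
    donors = label == 0
    acceptors = label == 1
    if lam_d > 0:
        bleach_t[donors] = rng.exponential(1.0 / lam_d, donors.sum())
    if lam_a > 0:
        bleach_t[acceptors] = rng.exponential(1.0 / lam_a, acceptors.sum())

    times = snaps["times"]
    d_rows, a_rows = [], []
    pair_track_id = {}
    next_a_tid = 0
    for fi, t in enumerate(times):
        npart = snaps["n_particles"][fi]
        for i in range(npart):
            typ = snaps["species"][fi, i]
            pa = snaps["protomer_a"][fi, i]
            pb = snaps["protomer_b"][fi, i]
            x = snaps["x"][fi, i]
            y = snaps["y"][fi, i]
            members = (pa,) if typ == 0 else (pa, pb)
            for m in members:
                if label[m] == 0 and bleach_t[m] > t:
                    d_rows.append((int(m), fi, x, y, 1.0, "donor"))
            if typ == 1:
                lm, lb = label[pa], label[pb]
                if {lm, lb} == {0, 1} and bleach_t[pa] > t and bleach_t[pb] > t:
                    key = (min(pa, pb), max(pa, pb))
                    if key not in pair_track_id:
                        pair_track_id[key] = next_a_tid
                        next_a_tid += 1
                    a_rows.append((pair_track_id[key], fi, x, y, 1.0,
                                   "acceptor"))
    cols = ["track_id", "frame", "x_um", "y_um", "intensity", "channel"]
    donor_tt = TrackTable(pd.DataFrame(d_rows, columns=cols), frame_interval)
    acceptor_tt = TrackTable(pd.DataFrame(a_rows, columns=cols),
                             frame_interval)

    # FRET-visible formation events from the exact event log
    vis_times = []
    for t, pa, pb in zip(events["time"], events["protomer_a"],
                         events["protomer_b"]):
        if ({label[pa], label[pb]} == {0, 1}
                and bleach_t[pa] > t and bleach_t[pb] > t):
            vis_times.append(float(t))
    truth = SyntheticTruth("dimerisation_movie", seed, {
        "config": {k: getattr(config, k) for k in
                   ("n_particles", "density", "p_collision", "k_off",
                    "D_mon", "D_dim", "duration", "dT")},
        "labelling": tuple(labelling), "bleach_rates": tuple(bleach_rates),
        "frame_interval": frame_interval,
        "visible_formation_times": vis_times,
        "all_formation_times": [float(t) for t in events["time"]],
        "events_truncated": bool(events["truncated"]),
    })
    return donor_tt, acceptor_tt, truth


def gen_formation_events(rate0: float, decay: float, area: float,
                         n_windows: int, window_duration: float,
                         seed: int = 0):
    """Dimer-formation event times under photobleaching decay.

    Events in each observation window follow an inhomogeneous Poisson
    process with areal rate rate0 * exp(-decay * t); returns the pooled
    event times (s since each window's illumination start) and the truth.
    Emulates the per-video appearance of new FRET-dimer trajectories.
    """
    rng = np.random.default_rng(seed)
    T, lam = window_duration, decay
    if lam > 0:
        mean_per_window = rate0 * area * (1.0 - math.exp(-lam * T)) / lam
    else:
        mean_per_window = rate0 * area * T
    times = []
    for _ in range(n_windows):
        n = rng.poisson(mean_per_window)
        u = rng.uniform(size=n)
        if lam > 0:
            # inverse CDF of the truncated exponential intensity
            t = -np.log(1.0 - u * (1.0 - math.exp(-lam * T))) / lam
        else:
            t = u * T
        times.extend(t.tolist())
    truth = SyntheticTruth("formation_events", seed, {
        "rate0": rate0, "decay": decay, "area": area,
        "n_windows": n_windows, "window_duration": window_duration,
    })
    return np.sort(np.asarray(times)), truth


def gen_fret_intensity_traces(n_traces: int = 40, n_frames: int = 100,
                              state_rates: tuple = (2.0, 10.0),
                              E_states: tuple = (0.4, 0.95),
                              total_intensity_logmean: float = math.log(400.0),
                              total_intensity_logsd: float = 0.3,
                              bleach_rate: float = 0.0,
                              noise_scale: float = 0.05,
                              frame_interval: float = FRAME_INTERVAL_DEFAULT,
                              start_state: str = "stationary",
                              seed: int = 0):
    """Two-state anti-correlated donor/acceptor intensity traces.

    Per trace: a lognormal total intensity, a two-state continuous-time
    Markov FRET-state path (low->high rate, high->low rate) sampled at
    the frame interval, donor = (1-E)*total and acceptor = E*total plus
    Gaussian noise with sd noise_scale*sqrt(signal) (shot-like), and
    single-step bleach truncation with the given rate.

    Returns (DataFrame[trace_id, frame, donor, acceptor], truth with the
    exact state paths).
    """
    k_lh, k_hl = state_rates
    e_lo, e_hi = E_states
    if not (0 < e_lo < 1 and 0 < e_hi < 1):
        raise ValueError("FRET states must be inside (0, 1)")
    rng = np.random.default_rng(seed)
    dt = frame_interval
    ksum = k_lh + k_hl
    if ksum > 0:
        decay = math.exp(-ksum * dt)
        p_ll = (k_hl + k_lh * decay) / ksum
        p_hh = (k_lh + k_hl * decay) / ksum
        pi_h = k_lh / ksum
    else:
        p_ll = p_hh = 1.0
        pi_h = 0.0
    rows = []
    paths = []
    for tid in range(n_traces):
        total = rng.lognormal(total_intensity_logmean, total_intensity_logsd)
        L = n_frames
        if bleach_rate > 0:
            L = min(L, max(2, int(np.ceil(
                rng.exponential(1.0 / bleach_rate) / dt))))
        if start_state == "stationary":
            s = 1 if rng.random() < pi_h else 0
        elif start_state == "low":
            s = 0
        elif start_state == "high":
            s = 1
        else:
            raise ValueError("start_state must be stationary|low|high")
        path = np.empty(L, dtype=np.int8)
        for f in range(L):
            path[f] = s
            stay = p_hh if s == 1 else p_ll
            if rng.random() >= stay:
                s = 1 - s
        e = np.where(path == 1, e_hi, e_lo)
        don = (1.0 - e) * total
        acc = e * total
        don_n = don + rng.normal(0.0, noise_scale * np.sqrt(don))
        acc_n = acc + rng.normal(0.0, noise_scale * np.sqrt(acc))
        paths.append(path)
        for f in range(L):
            rows.append((tid, f, don_n[f], acc_n[f]))
    df = pd.DataFrame(rows, columns=["trace_id", "frame", "donor", "acceptor"])
    truth = SyntheticTruth("fret_intensity_traces", seed, {
        "state_rates": state_rates, "E_states": E_states,
        "total_intensity_logmean": total_intensity_logmean,
        "total_intensity_logsd": total_intensity_logsd,
        "bleach_rate": bleach_rate, "noise_scale": noise_scale,
        "frame_interval": frame_interval,
        "state_paths": [p.tolist() for p in paths],
        "p_stay": (p_ll, p_hh),
    })
    return df, truth


def gen_interface_dataset(m_models: int = 4,
                          site_labels: Sequence[str] = SITE_LABELS_DEFAULT,
                          true_subset: tuple = (0, 1),
                          true_coefficients: tuple = (0.8, 0.2),
                          noise_sd: float = 0.05, seed: int = 0,
                          max_condition: float = 30.0):
    """Model matrix plus a noisy experimental efficiency vector.

    Model efficiency columns are drawn uniformly on (0.1, 0.95) (the
    realistic span for inter-label distances of roughly 2-9 nm at
    R0 = 7 nm) and redrawn until the matrix is well conditioned; the
    experimental vector is the true convex combination plus iid Gaussian
    noise.
    """
    c = np.asarray(true_coefficients, dtype=float)
    if len(true_subset) != c.size or abs(c.sum() - 1.0) > 1e-9 or np.any(c < 0):
        raise ValueError("true coefficients must lie on the simplex and "
                         "match the subset")
    rng = np.random.default_rng(seed)
    n_sites = len(site_labels)
    for attempt in range(100):
        M = rng.uniform(0.1, 0.95, size=(n_sites, m_models))
        if np.linalg.cond(M) < max_condition:
            break
    else:
        raise RuntimeError("could not draw a well-conditioned model matrix")
    names = tuple(f"model_{i}" for i in range(m_models))
    y = M[:, list(true_subset)] @ c + rng.normal(0.0, noise_sd, size=n_sites)
    models = ModelMatrix(tuple(site_labels), names, M,
                         provenance="synthetic uniform(0.1, 0.95) columns")
    exp = EfficiencyVector(tuple(site_labels), y, label="synthetic")
    truth = SyntheticTruth("interface_dataset", seed, {
        "m_models": m_models, "true_subset": tuple(true_subset),
        "true_coefficients": c.tolist(), "noise_sd": noise_sd,
        "matrix": M, "condition_number": float(np.linalg.cond(M)),
        "redraws": attempt,
    })
    return models, exp, truth


def gen_deer_dataset(component_means: Sequence[float] = (3.0, 5.5),
                     component_sds: Sequence[float] = (0.35, 0.5),
                     weights: Sequence[float] = (0.6, 0.4),
                     r_grid: Optional[np.ndarray] = None,
                     noise_sd: float = 0.0, seed: int = 0):
    """Gaussian-mixture distance distributions on a common r grid.

    Returns (experimental DistanceDistribution = the weighted mixture
    plus optional grid noise, list of single-component model
    distributions, truth).
    """
    w = np.asarray(weights, dtype=float)
    if abs(w.sum() - 1.0) > 1e-9 or np.any(w < 0):
        raise ValueError("weights must lie on the simplex")
    if r_grid is None:
        r_grid = np.arange(1.5, 8.0 + 1e-9, 0.02)
    rng = np.random.default_rng(seed)
    comps = []
    for i, (m, s) in enumerate(zip(component_means, component_sds)):
        dens = np.exp(-0.5 * ((r_grid - m) / s) ** 2) / (s * math.sqrt(2 * math.pi))
        comps.append(DistanceDistribution(r_grid, dens,
                                          f"component_{i}").normalised())
    mix = np.sum([wi * c.density for wi, c in zip(w, comps)], axis=0)
    if noise_sd > 0:
        mix = np.clip(mix + rng.normal(0.0, noise_sd, size=mix.size), 0.0,
                      None)
    exp = DistanceDistribution(r_grid, mix, "synthetic DEER").normalised()
    truth = SyntheticTruth("deer_dataset", seed, {
        "component_means": list(component_means),
        "component_sds": list(component_sds),
        "weights": w.tolist(), "noise_sd": noise_sd,
    })
    return exp, comps, truth
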