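"""Kinetic-constant estimation from single-particle track tables.

Covers the analysis chain from raw trajectories to rate constants:
mean-squared-displacement curves and diffusion-coefficient fits, z-test
comparison of diffusivities with a Saffman-Delbrueck radius ratio, the
Hardt mean-capture-time estimate of the monomer-monomer collision
frequency, photobleaching-corrected extrapolation of the dimer-formation
rate to the start of illumination, the labelling-ratio correction from
FRET-visible to total dimer formation, and the derived equilibrium
constants (K_d, half-life).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "TrackTable",
    "MSDCurve",
    "DiffusionFit",
    "RateSet",
    "FRAME_INTERVAL_DEFAULT",
    "MIN_TRACK_LENGTH",
    "msd_curve",
    "fit_diffusion",
    "compare_diffusion",
    "saffman_delbruck_radius_ratio",
    "hardt_collision_frequency",
    "extrapolate_formation_rate",
    "correct_for_labelling",
    "visible_pair_fraction",
    "derive_rate_constants",
]

FRAME_INTERVAL_DEFAULT = 0.030  # s
MIN_TRACK_LENGTH = 3  # frames; shorter tracks are discarded as spurious

EULER_GAMMA = 0.5772156649015329


@dataclass
class TrackTable:
    """Single-particle trajectories, one row per localisation.

    ``data`` columns: track_id, frame, x_um, y_um, intensity, channel.
    Frames are 0-based and strictly increasing within a track.
    """

    data: pd.DataFrame
    frame_interval: float = FRAME_INTERVAL_DEFAULT

    REQUIRED = ("track_id", "frame", "x_um", "y_um")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"track table missing columns: {missing}")

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def groupby_track(self):
        return self.data.groupby("track_id", sort=True)

    def validate(self) -> None:
        for tid, g in self.groupby_track():
            fr = g["frame"].to_numpy()
            if np.any(np.diff(fr) <= 0):
                raise ValueError(f"track {tid}: frames not strictly increasing")
            if fr.size < MIN_TRACK_LENGTH:
                raise ValueError(f"track {tid}: shorter than "
                                 f"{MIN_TRACK_LENGTH} frames")


@dataclass
class MSDCurve:
    """Track-weighted mean squared displacement versus lag time."""

    lags: np.ndarray  # s
    msd: np.ndarray  # um^2, weighted mean over tracks
    weighted_sd: np.ndarray  # um^2
    sem: np.ndarray  # um^2
    n_tracks: np.ndarray  # tracks contributing per lag
    n_pairs: np.ndarray  # displacement pairs per lag (the weights)
    # per-track data (lag -> (track ids, per-track msd, pair counts)),
    # kept for track-resampling confidence intervals
    track_stats: Optional[dict] = None


@dataclass
class DiffusionFit:
    D: float  # um^2/s
    ci95: tuple  # (lo, hi)
    intercept: Optional[float] = None  # um^2 (4*sigma_loc^2) when fitted
    negative: bool = False  # warning flag: fitted D < 0


@dataclass
class RateSet:
    """Kinetic constants of the monomer-dimer equilibrium (um, s units)."""

    k_on: Optional[float] = None  # um^2/s, second-order
    k_on_ci: Optional[tuple] = None
    k_off: Optional[float] = None  # 1/s
    k_off_ci: Optional[tuple] = None
    K_d: Optional[float] = None  # um^-2
    t_half: Optional[float] = None  # s
    areal_formation_rate: Optional[float] = None  # um^-2 s^-1
    p_collision: Optional[float] = None
    collision_frequency: Optional[float] = None  # um^-2 s^-1
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# diffusion


def msd_curve(tracks: TrackTable, max_lag: int = 10) -> MSDCurve:
    """Weighted-average MSD over all tracks for lags 1..max_lag frames.

    Per track and lag, the MSD is the mean of all overlapping squared
    displacements; tracks are combined with weights equal to the number
    of displacement pairs each contributes, and the per-lag spread is the
    weighted standard deviation across tracks with a matching standard
    error.
    """
    if tracks.data.empty:
        raise ValueError("empty track table")
    per_track = {}  # lag -> ([track ids], [msd per track], [weights])
    for tid, g in tracks.groupby_track():
        fr = g["frame"].to_numpy()
        xy = g[["x_um", "y_um"]].to_numpy()
        if fr.size < 2:
            continue
        idx = {f: i for i, f in enumerate(fr)}
        for lag in range(1, max_lag + 1):
            pairs = [(i, idx[f + lag]) for i, f in enumerate(fr)
                     if f + lag in idx]
            if not pairs:
                continue
            a = np.array([p[0] for p in pairs])
            b = np.array([p[1] for p in pairs])
            sq = np.sum((xy[b] - xy[a]) ** 2, axis=1)
            per_track.setdefault(lag, ([], [], []))
            per_track[lag][0].append(tid)
            per_track[lag][1].append(sq.mean())
            per_track[lag][2].append(sq.size)
    if not per_track:
        raise ValueError("no displacement pairs (tracks too short?)")
    track_stats = {
        lag: (np.asarray(v[0]), np.asarray(v[1], dtype=float),
              np.asarray(v[2], dtype=float))
        for lag, v in per_track.items()}
    lags, msds, wsds, sems, ntr, npr = [], [], [], [], [], []
    for lag in sorted(per_track):
        vals = np.asarray(per_track[lag][1])
        w = np.asarray(per_track[lag][2], dtype=float)
        mean = np.average(vals, weights=w)
        if vals.size > 1:
            var = np.average((vals - mean) ** 2, weights=w)
            neff = w.sum() ** 2 / np.sum(w ** 2)  # effective track count
            wsd = math.sqrt(var)
            sem = wsd / math.sqrt(max(neff - 1.0, 1.0))
        else:
            wsd, sem = 0.0, float("nan")
        lags.append(lag * tracks.frame_interval)
        msds.append(mean)
        wsds.append(wsd)
        sems.append(sem)
        ntr.append(vals.size)
        npr.append(w.sum())
    return MSDCurve(np.asarray(lags), np.asarray(msds), np.asarray(wsds),
                    np.asarray(sems), np.asarray(ntr), np.asarray(npr),
                    track_stats=track_stats)


def _lin_fit(tau, y, with_offset):
    if with_offset:
        X = np.column_stack([4.0 * tau, np.ones_like(tau)])
    else:
        X = 4.0 * tau[:, None]
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit_diffusion(curve: MSDCurve, n_fit_lags: int = 4,
                  with_offset: bool = False, n_boot: int = 300,
                  seed: int = 0) -> DiffusionFit:
    """Linear fit of MSD = 4*D*tau (+ optional intercept 4*sigma_loc^2).

    The point estimate is a least-squares line through the first
    ``n_fit_lags`` points of the weighted-average MSD curve.  Because
    MSD values at different lags share displacement pairs and are
    strongly correlated, the 95% CI resamples whole tracks (percentile
    bootstrap over the per-track MSDs) rather than trusting the per-lag
    standard errors; when the curve carries no per-track data the CI
    falls back to the (anti-conservative) weighted-fit covariance.
    """
    if n_fit_lags < 2:
        raise ValueError("need at least two lags to fit")
    n = min(n_fit_lags, curve.lags.size)
    tau = curve.lags[:n]
    y = curve.msd[:n]
    beta = _lin_fit(tau, y, with_offset)
    D = float(beta[0])
    intercept = float(beta[1]) if with_offset else None

    if curve.track_stats:
        lags_used = sorted(curve.track_stats)[:n]
        ids = sorted({int(t) for lag in lags_used
                      for t in curve.track_stats[lag][0]})
        pos = {t: i for i, t in enumerate(ids)}
        m = len(ids)
        # per-lag dense vectors aligned on the union of track ids
        V = np.zeros((n, m))
        W = np.zeros((n, m))
        for li, lag in enumerate(lags_used):
            tid, val, wgt = curve.track_stats[lag]
            for t, v, w in zip(tid, val, wgt):
                V[li, pos[int(t)]] = v * w
                W[li, pos[int(t)]] = w
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            cnt = np.bincount(rng.integers(0, m, size=m), minlength=m)
            denom = W @ cnt
            if np.any(denom == 0):
                boots[b] = np.nan
                continue
            msd_b = (V @ cnt) / denom
            boots[b] = _lin_fit(tau, msd_b, with_offset)[0]
        boots = boots[np.isfinite(boots)]
        lo, hi = np.percentile(boots, [2.5, 97.5])
        return DiffusionFit(D, (float(lo), float(hi)), intercept=intercept,
                            negative=D < 0)

    # fallback: weighted-fit covariance from per-lag standard errors
    sem = curve.sem[:n]
    w = None
    if np.all(np.isfinite(sem)) and np.all(sem > 0):
        w = 1.0 / sem
    X = (np.column_stack([4.0 * tau, np.ones_like(tau)]) if with_offset
         else 4.0 * tau[:, None])
    Xw = X * w[:, None] if w is not None else X
    yw = y * w if w is not None else y
    beta_w, res, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    dof = max(n - X.shape[1], 1)
    s2 = (float(res[0]) if res.size
          else float(np.sum((yw - Xw @ beta_w) ** 2))) / dof
    cov = s2 * np.linalg.inv(Xw.T @ Xw)
    se_D = math.sqrt(max(cov[0, 0], 0.0))
    tcrit = stats.t.ppf(0.975, dof)
    D = float(beta_w[0])
    return DiffusionFit(D, (D - tcrit * se_D, D + tcrit * se_D),
                        intercept=float(beta_w[1]) if with_offset else None,
                        negative=D < 0)


def saffman_delbruck_radius_ratio(D_ratio: float, r1: float,
                                  characteristic_length: float) -> float:
    """Radius ratio r2/r1 implied by a diffusivity ratio D2/D1.

    Uses the Saffman-Delbrueck logarithmic size dependence
    D ~ ln(L/r) - gamma with Euler's gamma; L is the hydrodynamic
    characteristic length, which must be supplied explicitly.
    """
    if D_ratio <= 0 or r1 <= 0 or characteristic_length <= 0:
        raise ValueError("all arguments must be positive")
    base = math.log(characteristic_length / r1) - EULER_GAMMA
    if base <= 0:
        raise ValueError("characteristic length too small for r1: "
                         "ln(L/r1) - gamma <= 0")
    target = D_ratio * base  # = ln(L/r2) - gamma
    r2 = characteristic_length * math.exp(-(target + EULER_GAMMA))
    if r2 <= 0 or not math.isfinite(r2):
        raise ValueError("diffusivity ratio outside the solvable range "
                         f"for L={characteristic_length}")
    return r2 / r1


def compare_diffusion(D1: float, ci1: Sequence[float], D2: float,
                      ci2: Sequence[float], r1: float = 0.0025,
                      characteristic_length: float = 0.020):
    """Two-sided z-test of D2 vs D1 plus the Saffman-Delbrueck radius ratio.

    The 95% CIs are treated as normal intervals (SE = width / 3.92).
    Returns (z, p_two_sided, radius_ratio).
    """
    se1 = (ci1[1] - ci1[0]) / 3.92
    se2 = (ci2[1] - ci2[0]) / 3.92
    if se1 <= 0 or se2 <= 0:
        raise ValueError("confidence intervals must have positive width")
    z = (D2 - D1) / math.hypot(se1, se2)
    p = 2.0 * stats.norm.sf(abs(z))
    ratio = saffman_delbruck_radius_ratio(D2 / D1, r1, characteristic_length)
    return z, p, ratio


# ---------------------------------------------------------------------------
# collision frequency and formation rate


def hardt_collision_frequency(density: float, D_rel: float,
                              contact_radius: float) -> float:
    """Mean monomer-monomer collision frequency (um^-2 s^-1), dilute 2D.

    Mean capture time tau = b^2 * (ln(b/a) - 3/4) / (2*D_rel) with
    b = (pi*density)^(-1/2) the radius of the average free area per
    particle and a the contact radius; the pairwise collision frequency
    per unit area is density / (2*tau) (each collision shared by two
    particles).
    """
    if density <= 0 or D_rel <= 0 or contact_radius <= 0:
        raise ValueError("all arguments must be positive")
    b = 1.0 / math.sqrt(math.pi * density)
    if b <= contact_radius:
        raise ValueError("density too high for the dilute capture formula "
                         f"(b={b:g} <= a={contact_radius:g})")
    tau = b * b * (math.log(b / contact_radius) - 0.75) / (2.0 * D_rel)
    if tau <= 0:
        raise ValueError("non-positive capture time; contact radius too "
                         "large for this density")
    return density / (2.0 * tau)


def extrapolate_formation_rate(event_times: Sequence[float],
                               observation_windows: Sequence[float],
                               area: float, bin_width: float = 0.5):
    """Dimer-formation rate at illumination start, photobleaching-corrected.

    ``event_times`` are new-dimer appearance times (s since illumination
    start, pooled over videos); ``observation_windows`` the per-video
    durations.  Events are binned, converted to areal rates using the
    number of videos still observing each bin, and fitted with
    rate(t) = A*exp(-lambda*t) by least squares weighted with the Poisson
    counting error of each bin (sqrt(max(count, 1))), which keeps the
    fit efficient and its covariance honest for count data.
    Returns ((A, A_ci95), (lam, lam_ci95)).
    """
    t = np.asarray(event_times, dtype=float)
    if t.size == 0:
        raise ValueError("no events supplied")
    windows = np.asarray(observation_windows, dtype=float)
    if windows.size == 0 or area <= 0:
        raise ValueError("need observation windows and a positive area")
    t_max = windows.max()
    edges = np.arange(0.0, t_max + bin_width * 0.999, bin_width)
    if edges.size < 3:
        raise ValueError("observation too short for the bin width")
    counts, _ = np.histogram(t, bins=edges)
    mid = 0.5 * (edges[:-1] + edges[1:])
    n_obs = np.array([(windows >= e).sum() for e in edges[1:]])
    valid = n_obs > 0
    if counts[valid].sum() == 0:
        raise ValueError("no events inside the observation windows")
    rates = counts[valid] / (n_obs[valid] * area * bin_width)
    sigma = np.sqrt(np.maximum(counts[valid], 1.0)) / (n_obs[valid] * area
                                                       * bin_width)
    mid = mid[valid]
    if np.count_nonzero(counts[valid]) < 2:
        raise ValueError("all events in a single bin; cannot fit a decay")

    def model(tt, A, lam):
        return A * np.exp(-lam * tt)

    A0 = max(rates[0], rates.mean())
    popt, pcov = optimize.curve_fit(model, mid, rates, p0=[A0, 0.5],
                                    sigma=sigma, absolute_sigma=False,
                                    maxfev=10000)
    se = np.sqrt(np.diag(pcov))
    dof = max(mid.size - 2, 1)
    tcrit = stats.t.ppf(0.975, dof)
    A, lam = popt
    return ((float(A), (float(A - tcrit * se[0]), float(A + tcrit * se[0]))),
            (float(lam), (float(lam - tcrit * se[1]),
                          float(lam + tcrit * se[1]))))


def visible_pair_fraction(f_donor: float, f_acceptor: float) -> float:
    """Fraction of dimers that are FRET-visible donor-acceptor pairs."""
    if f_donor < 0 or f_acceptor < 0 or f_donor + f_acceptor > 1 + 1e-12:
        raise ValueError("labelling fractions must be non-negative and sum "
                         "to at most 1")
    return 2.0 * f_donor * f_acceptor


def correct_for_labelling(observed_rate: float, f_donor: float,
                          f_acceptor: float) -> float:
    """Total dimer-formation rate from the FRET-visible rate.

    Only donor-acceptor dimers produce an acceptor-channel FRET spot; with
    random association their fraction is 2*f_D*f_A, so the total rate is
    the observed rate divided by that visibility.
    """
    vis = visible_pair_fraction(f_donor, f_acceptor)
    if vis <= 0:
        raise ValueError("zero visible fraction: need both donor- and "
                         "acceptor-labelled receptors")
    return observed_rate / vis


def derive_rate_constants(k_on: Optional[float] = None,
                          k_off: Optional[float] = None,
                          equilibrium: Optional[tuple] = None) -> RateSet:
    """Equilibrium/kinetic constants from one sufficient input combination.

    Either rates (k_on and/or k_off) or an equilibrium composition
    ``(dimer_receptor_fraction, total_density)``; supplying both rates
    and an inconsistent equilibrium raises.  K_d = M^2/D (um^-2),
    t_half = ln2/k_off.
    """
    rs = RateSet(k_on=k_on, k_off=k_off)
    K_eq = None
    if equilibrium is not None:
        frac, rho = equilibrium
        if not 0 <= frac <= 1 or rho <= 0:
            raise ValueError("equilibrium must be (fraction in [0,1], "
                             "positive density)")
        if frac > 0:
            d = frac * rho / 2.0
            m = rho - 2.0 * d
            K_eq = m * m / d
    if k_on is not None and k_off is not None:
        if k_on <= 0:
            raise ValueError("k_on must be positive to derive K_d")
        rs.K_d = k_off / k_on
        if K_eq is not None and not math.isclose(rs.K_d, K_eq, rel_tol=0.05):
            raise ValueError(
                f"over-specified and inconsistent: k_off/k_on = {rs.K_d:g} "
                f"but the equilibrium composition gives K_d = {K_eq:g}")
    elif K_eq is not None:
        rs.K_d = K_eq
        if k_on is not None:
            rs.k_off = k_on * K_eq
        elif k_off is not None:
            rs.k_on = k_off / K_eq
    elif k_on is None and k_off is None:
        raise ValueError("supply rates and/or an equilibrium composition")
    if rs.k_off is not None and rs.k_off > 0:
        rs.t_half = math.log(2.0) / rs.k_off
    return rs
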