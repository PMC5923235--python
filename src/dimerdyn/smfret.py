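"""Single-molecule FRET intensity analytics.

Single-molecule spot intensities are well described by lognormal
distributions, and a dimer interconverting between FRET configurations
produces a mixture of lognormal intensity states in the acceptor channel.
This module provides: expectation-maximisation fits of Gaussian mixtures
to log-intensities with a bootstrap BIC model comparison (how many
intensity states are supported?), construction of a conservative
high-state threshold from the fitted low-state component, dwell-time
segmentation with initial/mid/final classification and survival curves,
and per-frame FRET efficiency traces with a high-efficiency fraction.

The 1D EM is implemented here because its initialisation (quantile
split), restart policy and convergence rule are part of the analysis
definition; an independent library implementation is used as a
cross-check in the test-suite, not as the engine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "LogMixtureModel",
    "ThresholdSpec",
    "DwellRecord",
    "MixtureSelection",
    "fit_log_mixture",
    "fit_log_intensity_mixture",
    "high_state_threshold",
    "segment_dwells",
    "survival_curve",
    "dwell_rate_estimate",
    "frame_fret_efficiency",
]


@dataclass
class LogMixtureModel:
    """Gaussian mixture in log-intensity space (= lognormal mixture)."""

    n_components: int
    weights: np.ndarray
    means: np.ndarray  # log-intensity
    sds: np.ndarray  # log-intensity
    log_likelihood: float
    bic: float  # 2*lnL - p*ln(n); higher = more probable
    n_obs: int
    converged: bool = True
    ll_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def component_order(self):
        return np.argsort(self.means)


@dataclass
class ThresholdSpec:
    """Intensity above which the low state is improbable (tail_prob)."""

    threshold: float  # camera counts
    tail_prob: float
    low_component: tuple  # (log-mean, log-sd)


@dataclass
class DwellRecord:
    state: str  # high|low
    duration: float  # s
    position_class: str  # initial|mid|final|whole
    censored: bool


@dataclass
class MixtureSelection:
    """Per-k fits on the full data plus the bootstrap BIC comparison."""

    models: dict  # k -> LogMixtureModel
    k_range: tuple
    boot_delta_bic: np.ndarray  # (n_boot, len(k_range)); <= 0 by construction
    boot_best_k: np.ndarray  # (n_boot,)

    @property
    def best_k(self) -> int:
        return max(self.models, key=lambda k: self.models[k].bic)

    def best_k_fraction(self, k: int) -> float:
        return float(np.mean(self.boot_best_k == k))


# ---------------------------------------------------------------------------
# EM


def _em_once(z: np.ndarray, mu0, sd0, w0, max_iter: int, tol: float):
    n = z.size
    mu = mu0.copy()
    sd = sd0.copy()
    w = w0.copy()
    ll_old = -np.inf
    history = []
    resp = np.empty((n, mu.size))
    for it in range(max_iter):
        # E step in log space for stability
        logp = (np.log(w)[None, :] - 0.5 * math.log(2 * math.pi)
                - np.log(sd)[None, :]
                - 0.5 * ((z[:, None] - mu[None, :]) / sd[None, :]) ** 2)
        m = logp.max(axis=1, keepdims=True)
        pe = np.exp(logp - m)
        s = pe.sum(axis=1, keepdims=True)
        ll = float(np.sum(np.log(s)) + m.sum())
        history.append(ll)
        resp = pe / s
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp * z[:, None]).sum(axis=0) / nk
        var = (resp * (z[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, 1e-12))
        if ll - ll_old <= tol * max(abs(ll), 1.0) and it > 0:
            return mu, sd, w, ll, True, np.asarray(history)
        ll_old = ll
    return mu, sd, w, ll, False, np.asarray(history)


def fit_log_mixture(intensities: Sequence[float], n_components: int,
                    n_restarts: int = 10, max_iter: int = 500,
                    tol: float = 1e-8,
                    rng: Optional[np.random.Generator] = None) -> LogMixtureModel:
    """EM fit of a ``n_components`` Gaussian mixture to log-intensities.

    Initialisation splits the sorted log data into quantile blocks; the
    additional restarts perturb that initialisation.  The reported BIC is
    2*lnL - p*ln(n) with p = 3k - 1 free parameters (higher = more
    probable model).
    """
    x = np.asarray(intensities, dtype=float)
    if np.any(x <= 0):
        raise ValueError("intensities must be positive for log-space fits")
    z = np.log(x)
    k = n_components
    if np.unique(z).size < k:
        raise ValueError("fewer unique values than mixture components")
    rng = rng or np.random.default_rng(0)
    zs = np.sort(z)
    blocks = np.array_split(zs, k)
    mu0 = np.array([b.mean() for b in blocks])
    sd0 = np.array([max(b.std(), 1e-6 + 1e-3 * zs.std()) for b in blocks])
    w0 = np.array([b.size / z.size for b in blocks])

    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            mu_i, sd_i, w_i = mu0, sd0, w0
        else:
            jit = rng.normal(scale=0.25 * max(zs.std(), 1e-6), size=k)
            mu_i = mu0 + jit
            sd_i = sd0 * np.exp(rng.normal(scale=0.2, size=k))
            w_i = np.full(k, 1.0 / k)
        mu_f, sd_f, w_f, ll, conv, hist = _em_once(z, mu_i, sd_i, w_i,
                                                   max_iter, tol)
        if best is None or ll > best[3]:
            best = (mu_f, sd_f, w_f, ll, conv, hist)
    mu_f, sd_f, w_f, ll, conv, hist = best
    order = np.argsort(mu_f)
    p = 3 * k - 1
    bic = 2.0 * ll - p * math.log(z.size)
    return LogMixtureModel(k, w_f[order], mu_f[order], sd_f[order], ll, bic,
                           z.size, conv, hist)


def fit_log_intensity_mixture(intensities: Sequence[float],
                              k_range: Sequence[int] = (1, 2, 3, 4),
                              n_boot: int = 1000, boot_size: int = 1000,
                              seed: int = 0, n_restarts: int = 10,
                              boot_restarts: int = 2) -> MixtureSelection:
    """Mixture-order selection by bootstrap BIC on log intensities.

    Fits each candidate component count to the full sample, then redraws
    ``n_boot`` bootstrap samples of ``boot_size`` (with replacement),
    refits every k and records the BIC differences to the per-replicate
    best model (delta BIC <= 0; 0 marks the winning k).
    """
    x = np.asarray(intensities, dtype=float)
    if boot_size > x.size:
        raise ValueError("boot_size cannot exceed the sample size")
    rng = np.random.default_rng(seed)
    k_range = tuple(k_range)
    models = {k: fit_log_mixture(x, k, n_restarts=n_restarts, rng=rng)
              for k in k_range}
    delta = np.empty((n_boot, len(k_range)))
    best_k = np.empty(n_boot, dtype=int)
    for b in range(n_boot):
        xb = x[rng.integers(0, x.size, size=boot_size)]
        bics = np.array([
            fit_log_mixture(xb, k, n_restarts=boot_restarts, rng=rng).bic
            for k in k_range])
        delta[b] = bics - bics.max()
        best_k[b] = k_range[int(np.argmax(bics))]
    return MixtureSelection(models, k_range, delta, best_k)


# ---------------------------------------------------------------------------
# thresholding and dwell times


def high_state_threshold(low_component: tuple,
                         tail_prob: float = 0.01) -> ThresholdSpec:
    """Conservative high-state intensity threshold.

    The (1 - tail_prob) quantile of the fitted low-state lognormal:
    exp(mu + z_{1-tail_prob} * sd).  Intensities above it have less than
    ``tail_prob`` probability of belonging to the low state.
    """
    mu, sd = low_component
    if sd < 0:
        raise ValueError("log-sd must be non-negative")
    if not 0.0 < tail_prob < 0.5:
        raise ValueError("tail_prob must be in (0, 0.5)")
    thr = math.exp(mu + stats.norm.ppf(1.0 - tail_prob) * sd)
    return ThresholdSpec(thr, tail_prob, (mu, sd))


def segment_dwells(trace: Sequence[float], threshold: float,
                   frame_interval: float = 0.030):
    """Binarise an intensity trace and extract state dwells.

    Contiguous runs above (high) or at/below (low) the threshold become
    dwells; dwells touching the trajectory start/end are classed
    ``initial``/``final`` (their true duration is right/left-censored by
    the observation window), interior ones ``mid``.  A run spanning the
    whole trajectory is flagged censored and excluded from survival
    estimation.  Returns (dwells, survival) where survival maps
    (state, class) to an empirical survival curve over the uncensored
    dwells of that class.
    """
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    if x.size < 3:
        raise ValueError("trace shorter than three frames")
    hi = x > threshold
    # run-length encode
    change = np.flatnonzero(np.diff(hi.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [x.size]])
    dwells = []
    for s, e in zip(starts, ends):
        state = "high" if hi[s] else "low"
        if s == 0 and e == x.size:
            cls, cens = "whole", True
        elif s == 0:
            cls, cens = "initial", False
        elif e == x.size:
            cls, cens = "final", False
        else:
            cls, cens = "mid", False
        dwells.append(DwellRecord(state, (e - s) * frame_interval, cls, cens))
    survival = {}
    for state in ("low", "high"):
        for cls in ("initial", "mid", "final"):
            durs = np.array([d.duration for d in dwells
                             if d.state == state and d.position_class == cls
                             and not d.censored])
            if durs.size:
                survival[(state, cls)] = survival_curve(durs)
    return dwells, survival


def survival_curve(durations: Sequence[float]):
    """Empirical survival S(t) = P(T > t); starts at 1, non-increasing."""
    d = np.sort(np.asarray(durations, dtype=float))
    if d.size == 0:
        raise ValueError("no durations")
    tu = np.unique(d)
    surv = np.array([(d > t).mean() for t in tu])
    return np.concatenate([[0.0], tu]), np.concatenate([[1.0], surv])


def dwell_rate_estimate(dwells: Sequence[DwellRecord], state: str,
                        frame_interval: float = 0.030,
                        position_class: str = "mid") -> float:
    """Exit rate (1/s) of a state from its mean uncensored dwell length.

    Observed dwell frame counts of a memoryless state are geometric with
    per-frame survival q; inverting the geometric mean,
    rate = -ln(1 - 1/mean_frames) / frame_interval, which removes the
    plus-half-frame discretisation bias of the naive mean duration.
    """
    durs = [d.duration for d in dwells
            if d.state == state and d.position_class == position_class
            and not d.censored]
    if not durs:
        raise ValueError(f"no uncensored {position_class} dwells in state "
                         f"{state!r}")
    mean_frames = np.mean(durs) / frame_interval
    if mean_frames <= 1.0:
        raise ValueError("mean dwell of one frame: rate beyond the frame "
                         "rate, cannot invert")
    return -math.log(1.0 - 1.0 / mean_frames) / frame_interval


# ---------------------------------------------------------------------------
# per-frame FRET


def frame_fret_efficiency(donor: Sequence[float], acceptor: Sequence[float],
                          gamma: float = 1.0, cutoff: float = 0.9,
                          bin_width: float = 0.02):
    """Per-frame FRET efficiency E_t = I_A / (I_A + gamma*I_D).

    Frames with non-positive total intensity are excluded and counted.
    Returns a dict with the efficiency series, histogram (over [0, 1]),
    the fraction of valid frames above ``cutoff``, and the exclusion
    count.
    """
    ia = np.asarray(acceptor, dtype=float)
    idn = np.asarray(donor, dtype=float)
    if ia.shape != idn.shape:
        raise ValueError("donor and acceptor series must be aligned")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    tot = ia + gamma * idn
    valid = tot > 0
    e = np.full(ia.shape, np.nan)
    e[valid] = ia[valid] / tot[valid]
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    ev = e[valid]
    hist, _ = np.histogram(np.clip(ev, 0.0, 1.0), bins=edges)
    frac = float(np.mean(ev > cutoff)) if ev.size else float("nan")
    return {
        "efficiency": e,
        "hist_edges": edges,
        "hist_counts": hist,
        "fraction_above_cutoff": frac,
        "cutoff": cutoff,
        "n_excluded": int(np.count_nonzero(~valid)),
    }
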