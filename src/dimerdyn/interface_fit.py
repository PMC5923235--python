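"""Dimer-interface combination fitting.

A receptor dimer that explores several metastable interfaces produces
per-site FRET efficiencies (and DEER distance distributions) that are
mixtures of the single-interface predictions.  This module fits
experimental per-site efficiency vectors, or experimental distance
distributions, as convex combinations sum_i c_i * M_i of structural-model
predictions (c_i >= 0, sum c_i = 1), enumerates all non-empty model
subsets, ranks them by AIC, and compares conditions with a nested F-test.

The simplex-constrained least squares is solved exactly by enumerating
supports: the optimum lies on a face of the simplex, where it solves the
equality-constrained normal equations with the inactive coefficients
strictly positive; with at most seven models the enumeration is cheap and
reproducible to machine precision.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .ensemble_fret import efficiency_distance_conversion

__all__ = [
    "EfficiencyVector",
    "ModelMatrix",
    "CombinationFit",
    "DistanceDistribution",
    "model_efficiency_vector",
    "simplex_lstsq",
    "fit_combination",
    "enumerate_subsets",
    "nested_f_test",
    "fit_deer_combination",
]

SITE_LABELS_DEFAULT = ("TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7", "H8")


@dataclass
class EfficiencyVector:
    """Per-labelling-site FRET efficiencies (experimental or predicted)."""

    site_labels: tuple
    values: np.ndarray
    sems: Optional[np.ndarray] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.site_labels) != self.values.size:
            raise ValueError("site_labels and values must match")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("efficiencies must be finite")
        if self.sems is not None:
            self.sems = np.asarray(self.sems, dtype=float)


@dataclass
class ModelMatrix:
    """Columns of per-site efficiencies predicted by each dimer model."""

    site_labels: tuple
    model_names: tuple
    matrix: np.ndarray  # (n_sites, n_models)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.site_labels), len(self.model_names)):
            raise ValueError("matrix shape must be (n_sites, n_models)")

    def columns(self, subset: Sequence[str]) -> np.ndarray:
        idx = [self.model_names.index(m) for m in subset]
        return self.matrix[:, idx]


@dataclass
class CombinationFit:
    subset: tuple  # model names
    coefficients: np.ndarray  # on the simplex
    rss: float
    aic: float
    aicc: float
    n_points: int
    delta_aic: Optional[float] = None
    non_identifiable: bool = False


@dataclass
class DistanceDistribution:
    """Probability density over inter-label distance (nm)."""

    r_grid: np.ndarray  # nm, ascending
    density: np.ndarray  # 1/nm
    label: Optional[str] = None

    def __post_init__(self) -> None:
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.r_grid.shape != self.density.shape:
            raise ValueError("grid and density must match")
        if np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r grid must be strictly increasing")
        if np.any(self.density < -1e-12):
            raise ValueError("density must be non-negative")

    def normalised(self) -> "DistanceDistribution":
        z = np.trapezoid(self.density, self.r_grid)
        if z <= 0:
            raise ValueError("cannot normalise a zero distribution")
        return DistanceDistribution(self.r_grid, self.density / z, self.label)

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.r_grid))


def model_efficiency_vector(distance_samples: dict, R0: float = 7.0,
                            site_labels: Sequence[str] = SITE_LABELS_DEFAULT,
                            per_frame: bool = True,
                            label: Optional[str] = None) -> EfficiencyVector:
    """Per-site efficiencies from per-site distance samples (nm).

    FRET averages over conformations, so the default is the mean of the
    per-frame efficiencies E(R) = R0^6/(R0^6 + R^6); ``per_frame=False``
    instead evaluates E at the mean distance.
    """
    vals = []
    for site in site_labels:
        r = np.asarray(distance_samples[site], dtype=float)
        if r.size == 0:
            raise ValueError(f"no distance samples for site {site}")
        if np.any(r <= 0):
            raise ValueError(f"non-positive distances for site {site}")
        if per_frame:
            e = R0 ** 6 / (R0 ** 6 + r ** 6)
            vals.append(float(e.mean()))
        else:
            vals.append(efficiency_distance_conversion(
                float(r.mean()), "to_efficiency", R0))
    return EfficiencyVector(tuple(site_labels), np.asarray(vals), label=label)


# ---------------------------------------------------------------------------
# simplex-constrained least squares


def simplex_lstsq(A: np.ndarray, y: np.ndarray, tol: float = 1e-10):
    """Minimise ||y - A c||^2 subject to c >= 0 and sum(c) = 1.

    Exact support enumeration; returns (c, rss, singular_flag).
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = A.shape
    best_c, best_rss = None, np.inf
    singular = False
    for r in range(1, m + 1):
        for sup in itertools.combinations(range(m), r):
            As = A[:, sup]
            G = As.T @ As
            K = np.zeros((r + 1, r + 1))
            K[:r, :r] = G
            K[:r, r] = 1.0
            K[r, :r] = 1.0
            rhs = np.concatenate([As.T @ y, [1.0]])
            try:
                sol = np.linalg.solve(K, rhs)
            except np.linalg.LinAlgError:
                singular = True
                sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
            c_s = sol[:r]
            if np.any(c_s < -tol):
                continue
            c_s = np.clip(c_s, 0.0, None)
            s = c_s.sum()
            if s <= 0:
                continue
            c_s = c_s / s
            resid = y - As @ c_s
            rss = float(resid @ resid)
            if rss < best_rss - 1e-15 or best_c is None:
                best_rss = rss
                best_c = np.zeros(m)
                best_c[list(sup)] = c_s
    return best_c, best_rss, singular


def _aic(rss: float, n: int, k: int):
    if rss <= 1e-30:
        return -math.inf, -math.inf
    aic = n * math.log(rss / n) + 2.0 * k
    if n - k - 1 > 0:
        aicc = aic + 2.0 * k * (k + 1) / (n - k - 1)
    else:
        aicc = math.inf
    return aic, aicc


def fit_combination(experimental: EfficiencyVector, models: ModelMatrix,
                    subset: Optional[Sequence[str]] = None,
                    weights: Optional[np.ndarray] = None) -> CombinationFit:
    """Best convex combination of a model subset for one efficiency vector.

    Unweighted residual sum of squares by default; pass per-site
    ``weights`` (e.g. 1/sem) for a weighted variant.  AIC uses
    k = (subset size - 1) + 1 free parameters (simplex coefficients plus
    the residual variance).
    """
    if subset is None:
        subset = models.model_names
    subset = tuple(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    if experimental.site_labels != models.site_labels:
        raise ValueError("site labels of data and models do not align")
    A = models.columns(subset)
    y = experimental.values
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        A = A * w[:, None]
        y = y * w
    # duplicated identical model columns are non-identifiable
    dup = False
    for i in range(A.shape[1]):
        for j in range(i + 1, A.shape[1]):
            if np.allclose(A[:, i], A[:, j], atol=1e-12):
                dup = True
    c, rss, singular = simplex_lstsq(A, y)
    n = y.size
    k = len(subset)  # (len(subset)-1 coefficients) + residual variance
    aic, aicc = _aic(rss, n, k)
    return CombinationFit(subset, c, rss, aic, aicc, n,
                          non_identifiable=dup or singular)


def enumerate_subsets(experimental: EfficiencyVector,
                      models: ModelMatrix,
                      weights: Optional[np.ndarray] = None,
                      use_aicc: bool = False):
    """Fit every non-empty model subset (2^m - 1 fits), ranked by AIC.

    Returns the list sorted best-first with ``delta_aic`` filled in
    relative to the best subset.  ``use_aicc`` ranks by the small-sample
    corrected criterion instead (relevant with eight sites and up to
    seven models).
    """
    names = models.model_names
    fits = []
    for r in range(1, len(names) + 1):
        for sub in itertools.combinations(names, r):
            fits.append(fit_combination(experimental, models, sub, weights))
    key = (lambda f: f.aicc) if use_aicc else (lambda f: f.aic)
    fits.sort(key=key)
    best = key(fits[0])
    for f in fits:
        f.delta_aic = key(f) - best
    return fits


def nested_f_test(fit_pooled: CombinationFit,
                  fits_separate: Sequence[CombinationFit]):
    """F-test of separate per-condition fits against a pooled fit.

    The pooled fit constrains both conditions to one coefficient set; the
    separate fits free them.  F = ((RSS_p - RSS_s)/dk) / (RSS_s/(n - k_s))
    with n the pooled number of points and parameter counts equal to the
    free simplex coefficients (subset size - 1) of each fit.
    Returns (F, p, df).
    """
    for f in fits_separate:
        if f.subset != fit_pooled.subset:
            raise ValueError("pooled and separate fits must share the "
                             "model subset")
    rss_s = sum(f.rss for f in fits_separate)
    k_s = sum(len(f.subset) - 1 for f in fits_separate)
    n = sum(f.n_points for f in fits_separate)
    if n != fit_pooled.n_points:
        raise ValueError("pooled fit must cover the union of the "
                         "condition data")
    dk = k_s - (len(fit_pooled.subset) - 1)
    if dk <= 0:
        raise ValueError("separate fits add no parameters (dk = 0)")
    dof2 = n - k_s
    if dof2 <= 0:
        raise ValueError("not enough points for the residual degrees of "
                         "freedom")
    if rss_s <= 1e-30:
        return math.inf, 0.0, (dk, dof2)
    F = ((fit_pooled.rss - rss_s) / dk) / (rss_s / dof2)
    F = max(F, 0.0)
    p = float(stats.f.sf(F, dk, dof2))
    return float(F), p, (dk, dof2)


def fit_deer_combination(experimental: DistanceDistribution,
                         model_dists: Sequence[DistanceDistribution],
                         subset: Optional[Sequence[int]] = None,
                         r_window: tuple = (1.5, 8.0),
                         grid_step: float = 0.05):
    """Convex-combination fit of model distance distributions to DEER data.

    All distributions are linearly interpolated onto a common grid inside
    ``r_window`` (distances beyond ~8 nm are unreliable in the
    experiment, short ones unphysical), renormalised, and fitted with the
    same simplex-constrained least squares; AIC uses n = grid size.
    Returns (CombinationFit, combined DistanceDistribution).
    """
    if subset is None:
        subset = list(range(len(model_dists)))
    chosen = [model_dists[i] for i in subset]
    lo = max([experimental.r_grid[0]] + [d.r_grid[0] for d in chosen])
    hi = min([experimental.r_grid[-1]] + [d.r_grid[-1] for d in chosen])
    lo = max(lo, r_window[0])
    hi = min(hi, r_window[1])
    if hi - lo <= 2 * grid_step:
        raise ValueError("distance ranges do not overlap inside the "
                         "fit window")
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)

    def on_grid(d: DistanceDistribution) -> np.ndarray:
        y = np.interp(grid, d.r_grid, d.density)
        z = np.trapezoid(y, grid)
        if z <= 0:
            raise ValueError(f"distribution {d.label!r} vanishes on the "
                             "fit window")
        return y / z

    y_exp = on_grid(experimental)
    A = np.column_stack([on_grid(d) for d in chosen])
    c, rss, singular = simplex_lstsq(A, y_exp)
    n = grid.size
    k = len(chosen)
    aic, aicc = _aic(rss, n, k)
    names = tuple(d.label or f"model_{i}" for i, d in zip(subset, chosen))
    fit = CombinationFit(names, c, rss, aic, aicc, n,
                         non_identifiable=singular)
    combined = DistanceDistribution(grid, A @ c, "combined").normalised()
    return fit, combined
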