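"""Tests for simplex-constrained interface combination fitting."""

import numpy as np
import pytest

from dimerdyn import interface_fit as ifit
from dimerdyn import synthetic


def test_model_efficiency_vector_examples():
    sites = ("TM1", "TM2")
    ev = ifit.model_efficiency_vector({"TM1": [7.0], "TM2": [7.0, 7.0]},
                                      R0=7.0, site_labels=sites)
    assert ev.values == pytest.approx([0.5, 0.5])
    ev = ifit.model_efficiency_vector({"TM1": [4.6], "TM2": [7.0]},
                                      R0=7.0, site_labels=sites)
    assert ev.values[0] == pytest.approx(0.926, abs=1e-3)
    with pytest.raises(ValueError):
        ifit.model_efficiency_vector({"TM1": [-1.0], "TM2": [7.0]},
                                     site_labels=sites)


def test_per_frame_averaging_differs_from_mean_distance():
    sites = ("TM1",)
    samples = {"TM1": [3.0, 9.0]}
    per_frame = ifit.model_efficiency_vector(samples, site_labels=sites)
    of_mean = ifit.model_efficiency_vector(samples, site_labels=sites,
                                           per_frame=False)
    # FRET averages efficiencies over conformations; a wide conformational
    # spread gives a lower mean efficiency than the efficiency of the mean
    # distance (the far conformer contributes almost nothing)
    assert per_frame.values[0] < of_mean.values[0]


def test_exact_single_model_recovery():
    models, exp, truth = synthetic.gen_interface_dataset(
        m_models=3, true_subset=(2,), true_coefficients=(1.0,),
        noise_sd=0.0, seed=0)
    fit = ifit.fit_combination(exp, models)
    assert fit.rss == pytest.approx(0.0, abs=1e-20)
    assert fit.coefficients[2] == pytest.approx(1.0, abs=1e-9)


def test_noise_free_mixture_recovered_to_machine_precision():
    models, exp, truth = synthetic.gen_interface_dataset(
        m_models=4, true_subset=(0, 1), true_coefficients=(0.65, 0.35),
        noise_sd=0.0, seed=1)
    fit = ifit.fit_combination(exp, models, ("model_0", "model_1"))
    assert fit.coefficients[:2] == pytest.approx([0.65, 0.35], abs=1e-6)


def test_simplex_constraints_always_hold():
    for s in range(10):
        models, exp, _ = synthetic.gen_interface_dataset(noise_sd=0.1,
                                                         seed=100 + s)
        fit = ifit.fit_combination(exp, models)
        assert np.all(fit.coefficients >= -1e-12)
        assert fit.coefficients.sum() == pytest.approx(1.0, abs=1e-9)


def test_noisy_recovery_within_tolerance():
    errs = []
    for s in range(30):
        models, exp, truth = synthetic.gen_interface_dataset(
            m_models=2, true_subset=(0, 1), true_coefficients=(0.8, 0.2),
            noise_sd=0.05, seed=300 + s)
        fit = ifit.fit_combination(exp, models)
        errs.append(abs(fit.coefficients[0] - 0.8))
    # +-0.15 is ~3 sd of the estimator at this noise level: expect it as
    # a typical-case bound, not a worst-case one
    assert np.mean(np.asarray(errs) < 0.15) >= 0.9
    assert np.median(errs) < 0.08


def test_duplicate_models_flagged():
    sites = tuple("s" + str(i) for i in range(4))
    col = np.array([0.2, 0.5, 0.7, 0.9])
    models = ifit.ModelMatrix(sites, ("a", "b"),
                              np.column_stack([col, col]))
    exp = ifit.EfficiencyVector(sites, col)
    fit = ifit.fit_combination(exp, models)
    assert fit.non_identifiable
    assert fit.rss == pytest.approx(0.0, abs=1e-18)


def test_enumerate_subsets_counts_and_ranking():
    models, exp, _ = synthetic.gen_interface_dataset(m_models=7, seed=2)
    fits = ifit.enumerate_subsets(exp, models)
    assert len(fits) == 127  # all non-empty subsets of seven models
    assert fits[0].delta_aic == 0.0
    assert all(f.delta_aic >= 0 for f in fits)
    models1, exp1, _ = synthetic.gen_interface_dataset(
        m_models=1, true_subset=(0,), true_coefficients=(1.0,), seed=3)
    assert len(ifit.enumerate_subsets(exp1, models1)) == 1


def test_rss_never_increases_with_nested_subsets():
    models, exp, _ = synthetic.gen_interface_dataset(m_models=4,
                                                     noise_sd=0.08, seed=4)
    fits = {f.subset: f.rss for f in ifit.enumerate_subsets(exp, models)}
    for sub, rss in fits.items():
        for sup, rss_sup in fits.items():
            if set(sub) < set(sup):
                assert rss_sup <= rss + 1e-12


def test_fit_invariant_under_site_reordering():
    models, exp, _ = synthetic.gen_interface_dataset(m_models=3,
                                                     noise_sd=0.05, seed=5)
    fit = ifit.fit_combination(exp, models)
    perm = np.array([3, 1, 7, 0, 6, 2, 5, 4])
    sites_p = tuple(models.site_labels[i] for i in perm)
    models_p = ifit.ModelMatrix(sites_p, models.model_names,
                                models.matrix[perm])
    exp_p = ifit.EfficiencyVector(sites_p, exp.values[perm])
    fit_p = ifit.fit_combination(exp_p, models_p)
    assert fit_p.coefficients == pytest.approx(fit.coefficients, abs=1e-9)
    assert fit_p.rss == pytest.approx(fit.rss, rel=1e-9)


# ---------------------------------------------------------------------------
# F-test


def test_f_test_identical_conditions():
    models, exp, _ = synthetic.gen_interface_dataset(noise_sd=0.05, seed=6)
    sub = ("model_0", "model_1")
    # pooled = both conditions stacked; identical data twice
    sites2 = tuple(s + sfx for sfx in ("_a", "_b") for s in models.site_labels)
    A2 = np.vstack([models.matrix, models.matrix])
    models2 = ifit.ModelMatrix(sites2, models.model_names, A2)
    exp2 = ifit.EfficiencyVector(sites2, np.concatenate([exp.values,
                                                         exp.values]))
    pooled = ifit.fit_combination(exp2, models2, sub)
    sep = [ifit.fit_combination(exp, models, sub),
           ifit.fit_combination(exp, models, sub)]
    F, p, df = ifit.nested_f_test(pooled, sep)
    assert F == pytest.approx(0.0, abs=1e-6)
    assert p == pytest.approx(1.0, abs=1e-6)


def test_f_test_detects_coefficient_shift():
    detected = 0
    reps = 12
    for s in range(reps):
        rng = np.random.default_rng(700 + s)
        M = rng.uniform(0.1, 0.95, size=(8, 2))
        ya = M @ np.array([0.8, 0.2]) + rng.normal(0, 0.02, 8)
        yb = M @ np.array([0.7, 0.3]) + rng.normal(0, 0.02, 8)
        sites = tuple(f"s{i}" for i in range(8))
        models = ifit.ModelMatrix(sites, ("a", "b"), M)
        sites2 = tuple(f"s{i}{c}" for c in "ab" for i in range(8))
        models2 = ifit.ModelMatrix(sites2, ("a", "b"), np.vstack([M, M]))
        pooled = ifit.fit_combination(
            ifit.EfficiencyVector(sites2, np.concatenate([ya, yb])), models2)
        sep = [ifit.fit_combination(ifit.EfficiencyVector(sites, ya), models),
               ifit.fit_combination(ifit.EfficiencyVector(sites, yb), models)]
        F, p, _ = ifit.nested_f_test(pooled, sep)
        if p < 0.05:
            detected += 1
    assert detected > reps / 2


def test_f_test_degenerate_dk():
    models, exp, _ = synthetic.gen_interface_dataset(noise_sd=0.05, seed=8)
    fit = ifit.fit_combination(exp, models, ("model_0",))
    with pytest.raises(ValueError):
        ifit.nested_f_test(fit, [fit])


# ---------------------------------------------------------------------------
# DEER


def test_deer_exact_and_mixture_recovery():
    exp, comps, truth = synthetic.gen_deer_dataset(weights=(1.0, 0.0), seed=9)
    fit, combined = ifit.fit_deer_combination(comps[0], comps)
    assert fit.coefficients[0] == pytest.approx(1.0, abs=1e-6)
    assert fit.rss == pytest.approx(0.0, abs=1e-12)

    exp, comps, _ = synthetic.gen_deer_dataset(weights=(0.6, 0.4), seed=10)
    fit, combined = ifit.fit_deer_combination(exp, comps, grid_step=0.05)
    assert fit.coefficients == pytest.approx([0.6, 0.4], abs=0.05)
    assert combined.integral() == pytest.approx(1.0, abs=1e-6)


def test_deer_non_overlapping_ranges_error():
    a = ifit.DistanceDistribution(np.linspace(1.6, 2.4, 30),
                                  np.ones(30), "a").normalised()
    b = ifit.DistanceDistribution(np.linspace(6.0, 7.5, 30),
                                  np.ones(30), "b").normalised()
    with pytest.raises(ValueError):
        ifit.fit_deer_combination(a, [b])


def test_deer_aic_identifies_generating_subset():
    hits = 0
    for s in range(20):
        rng = np.random.default_rng(1100 + s)
        exp, comps, _ = synthetic.gen_deer_dataset(
            component_means=(2.8, 4.5, 6.2), component_sds=(0.3, 0.4, 0.5),
            weights=(0.6, 0.4, 0.0), noise_sd=0.002, seed=1100 + s)
        best, best_fit = None, None
        import itertools
        for r in range(1, 4):
            for sub in itertools.combinations(range(3), r):
                fit, _ = ifit.fit_deer_combination(exp, comps, subset=sub)
                if best is None or fit.aic < best:
                    best, best_fit = fit.aic, fit
        # components below 1% weight are reported absent
        got = {n for n, c in zip(best_fit.subset, best_fit.coefficients)
               if c > 0.01}
        if got == {"component_0", "component_1"}:
            hits += 1
    assert hits >= 16
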