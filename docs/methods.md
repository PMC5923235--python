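# Methods

`dimerdyn` models the monomer–dimer dynamics of a membrane receptor
(the neurotensin receptor NTS1 is the motivating system) and implements
the quantitative analyses that surround such an experiment: a particle
reaction–diffusion simulator, kinetics estimation from single-particle
tracks, ensemble-FRET corrections, single-molecule FRET analytics, and
convex combination fitting of dimer-interface models.  This note records
the models, their assumptions, the numerical choices, and what the
synthetic data do and do not emulate.

## Reaction–diffusion Monte Carlo (`mc_sim`)

**Model.** Receptors are point particles with a collision radius
r = 2.5 nm diffusing by Brownian motion on a periodic square membrane
patch.  Monomers move with D_mon = 1.63 µm²/s, dimers with
D_dim = 1.27 µm²/s (the measured single-particle values).  On every
elementary time step each monomer pair whose minimum-image separation is
at or below the collision diameter (2r = 5 nm) undergoes an independent
Bernoulli trial with probability `p_collision`; success replaces the two
monomers with one dimer at the pair midpoint.  Dimers keep the
identities of their two protomers, dissociate as a first-order process
(per-step probability 1 − exp(−k_off·dT)) into two monomers placed just
outside contact (separation 2r·(1+10⁻⁵), random orientation), and never
grow into higher-order oligomers.

**Time step.** The default elementary step follows the half-radius rule
dT = r²/(16·D_mon) ≈ 2.4·10⁻⁷ s (rms planar displacement = r/2).  A
coarser user-set step is accepted up to dT = (2r)²/(16·D_mon) ≈
9.6·10⁻⁷ s, the point at which the rms step equals half the collision
diameter; beyond that encounters would be skipped over.  Production
runs in the tests and the acceptance script use this coarsest admissible
step.

**Temporal coarse-graining.** Sub-microsecond steps over tens of
simulated seconds are made affordable by merging elementary steps when
nothing can react: if the smallest monomer–monomer gap is g, up to
k ∝ (g/5σ₁)² elementary steps are taken as a single Gaussian jump
(variance 2·D·k·dT per axis — exact for free diffusion, since Gaussian
increments compose).  The factor 5σ₁ makes the probability that the
closest pair covers its gap within one jump ≈ e^(−12.5) ≈ 4·10⁻⁶.
Whenever a pair is near contact, or any reaction fired, the simulator
falls back to elementary steps, so encounter statistics, Bernoulli
trials per step of overlap, and post-dissociation re-capture are always
resolved at the elementary scale.  Jumps are additionally capped so that
the expected number of dissociations per jump stays ≤ 0.2, and they
never cross recording boundaries.  Dimer displacements are deferred and
composed lazily (dimers take no part in pair logic), which is likewise
exact.  A vectorised single-step reference implementation
(`advance_ensemble`) realises the same elementary dynamics without any
coarse-graining and is compared against the kernel statistically in the
tests.

**Pair search.** Linked-cell grid with cell size ≥ collision diameter
(≤ 48×48 cells), minimum-image distances; boxes narrower than four
collision diameters fall back to an all-pairs scan.  Colliding pairs are
resolved closest-first and each monomer joins at most one new dimer per
step.

**Calibration.** Because trials occur on *every step of overlap*, the
effective second-order association constant depends on both p and dT;
in the reaction-limited regime k_on ≈ p·π(2r)²/(2·dT), which for
k_on = 0.081 µm²/s gives p ≈ 2·10⁻³ per overlap step (the per-*encounter*
acceptance probability implied is far higher — of order the reported
~20% collision efficiency — an encounter comprises many overlap steps
and re-crossings).  `calibrate_collision_probability` therefore measures
the simulator's own encounter statistics: a non-reactive run counts
overlap trials to set p₀, short irreversible runs at a dilute
calibration density (5 µm⁻², 300 particles) measure the realised k_on by
monomer-loss fitting (1/[M] vs t), and bisection refines p until the
measurement is within a stated tolerance (default 10%) of the target.
In this regime the effective k_on is density-independent (overlap
occupancy π(2r)²ρ ≪ 1 up to 10³ µm⁻²), which is why one calibration
serves the whole density sweep; the detailed-balance tests verify
agreement with the mass-action and Gillespie oracles across
0.43–100 µm⁻² within statistical error.

**Oracles.** `mass_action_equilibrium` solves M + 2D = ρ with
k_on·M² = k_off·D in closed form; `gillespie_well_mixed` is an exact
stochastic simulation of A + A ⇌ A₂ with association propensity
k_on·M(M−1)/area.  Both are implementation-independent of the particle
kernel.

**Problem sizes.** Equilibrium dimer fractions are measured with
100 particles (density 0.43 µm⁻², ~30–40 s simulated, 10 s burn-in,
3 seeds) and 300 particles (10³ µm⁻², 3 s simulated, 1 s burn-in,
3 seeds); block averaging (15 blocks) supplies standard errors that
respect autocorrelation.  Burn-ins were set from the slowest relaxation
rate of the reversible dimerisation (≈ k_off + 4·k_on·M ≈ 0.7 s⁻¹ at
0.43 µm⁻², i.e. ≥ 7 relaxation times).  The automatic
`equilibrium_start_index` (rolling-mean plateau detection) is a
convenience heuristic; quantitative runs state their burn-in explicitly.

## Track kinetics (`kinetics`)

MSD curves weight each track by its displacement-pair count per lag
(the natural inverse-variance weight when the per-pair variance is
homogeneous).  D is fitted as a least-squares line MSD = 4Dτ over the
first lags (default 4, roughly the first quarter of the computed curve);
an optional intercept absorbs static localisation noise (4σ_loc²).
Because MSD values at different lags share displacements and are
strongly correlated, the 95% CI resamples whole tracks (percentile
bootstrap, 300 replicates) instead of trusting per-lag standard errors
— the per-lag-covariance CI under-covers noticeably and is kept only as
a fallback.

Monomer/dimer diffusivities are compared with a two-sided z-test on the
reported 95% CIs (SE = width/3.92), and the Saffman–Delbrück
log-size law D ∝ ln(L/r) − γ converts the diffusivity ratio into an
effective radius ratio.  The hydrodynamic characteristic length L is not
identifiable from a single ratio and must be supplied; L = 20 nm (a
typical membrane/water viscosity length scale) reproduces the reported
~1.4-fold radius increase and is the default in `compare_diffusion`.

The dilute-membrane collision frequency uses the mean-capture-time
result τ = b²(ln(b/a) − 3/4)/(2·D_rel) with b = (πρ)^(−1/2) and
a = contact radius, reported as ρ/(2τ) collisions per µm² per s
(pairwise).  With D_rel = D₁+D₂ = 3.26 µm²/s at 0.43 µm⁻² this gives
0.43 µm⁻² s⁻¹, within ×1.5 of the reported ~0.31 whose exact
computation is not published; the variant used here is fixed and
documented rather than tuned.

The photobleaching correction bins new-dimer appearance times (0.5 s
bins), converts to areal rates using the number of videos still
observing each bin, and fits A·exp(−λt) by Poisson-weighted least
squares (per-bin σ = √max(count,1) scaled to rate units).  Weighting
matters: on the synthetic generator the unweighted fit shows 27%
sampling sd on A and 82% CI coverage, the weighted fit 19% and 95%.
Even so, at the reference experiment size (19 six-second videos on
~100 µm², ≈80 visible events) a single extrapolated rate carries ~19%
sampling noise — recovery is therefore asserted through CI coverage,
not point equality.  The labelling correction divides by the
FRET-visible pair fraction 2·f_D·f_A (0.268 for the 100:405:45
donor:acceptor:unlabelled ratio); the factor is configurable.

## Ensemble FRET (`ensemble_fret`)

Labelling efficiency, donor-signal reconstruction, the
donor-to-acceptor ratio r_DA and the stoichiometry correction
E_cor = E_app·(1+r_DA)/r_DA are implemented exactly as the standard
bulk-FRET correction chain for randomly associating donor-/
acceptor-labelled protein.  The apparent-efficiency estimator is
deliberately pluggable; the built-in one is donor quenching
(E_app = 1 − F_DA/F_D over a configurable donor band), since the exact
published estimator is not reproducible from the main text.  E_cor can
legitimately exceed 1 when E_app and the donor excess push the corrected
value past unity within noise; values are reported uncorrected.

Distance conversion uses E = R₀⁶/(R₀⁶+R⁶) with R₀ = 7.0 nm for the
A488–A555 pair and κ² = 2/3 assumed (not estimable here).  Apo vs
agonist comparisons use a Bayesian two-mean model — normal likelihood,
flat priors, giving Student-t posteriors evaluated by Monte Carlo — a
deliberate simplification of the full BEST model (no outlier-robust t
likelihood, no shared-variance hierarchy); posterior probabilities agree
with the reference values to within a few hundredths on the
well-determined rows.  The packaged per-site table (`TABLE1`) is the
printed experimental summary (mean ± SEM, n per condition); the sign
convention for ΔE_cor is apo − agonist, the only one consistent with
all printed rows.

## Single-molecule FRET (`smfret`)

Spot intensities are modelled as lognormal mixtures; EM runs on log
intensities with quantile-split initialisation, 10 restarts
(perturbed), and convergence at relative log-likelihood change < 10⁻⁸.
The 1D EM is implemented in-package because its initialisation and
restart policy are part of the analysis definition; the test-suite
cross-checks it against an independent library implementation.  Model
order is compared by BIC = 2·lnL − (3k−1)·ln n (higher = more probable)
with a bootstrap (resample, refit all k, record ΔBIC to the
per-replicate best).  The published 166.5-count threshold is not
recomputable (the underlying fit parameters are unpublished); the
*construction* — the (1−tail_prob) quantile of the fitted low-state
lognormal, tail_prob = 0.01 — is what the package provides.

Dwell segmentation binarises at a threshold; runs touching the
trajectory start/end are classed initial/final (right/left-censored by
the observation window and kept out of none of the reporting, but
whole-trajectory runs are censored and excluded from survival
estimation).  Rates are estimated from mid-dwells by inverting the
geometric run-length mean (rate = −ln(1 − 1/mean_frames)/Δt), which
removes the half-frame discretisation bias.  A known limitation: at
30 ms frames, brief excursions shorter than a frame are missed, which
lengthens the apparent dwells of the *opposite* state — for a
low↔high process at 2 s⁻¹/10 s⁻¹ the high-state rate is recovered to a
few percent while the low-state exit rate is biased low by ~15%; tests
assert against the exact discretised-chain expectation, not the
continuous-time value.

Per-frame efficiency is E_t = I_A/(I_A + γ·I_D) with γ = 1 by default
(raw counts); frames with non-positive total are excluded and counted.

## Interface combination fitting (`interface_fit`)

Experimental per-site efficiency vectors (8 sites, TM1–TM7 and H8) are
fitted as convex combinations Σcᵢ·Mᵢ of model-predicted vectors
(cᵢ ≥ 0, Σcᵢ = 1).  The constrained least squares is solved *exactly*
by support enumeration (the optimum lies on a simplex face where it
solves the equality-constrained normal equations); with ≤ 7 models this
is cheap, deterministic and reproducible to machine precision.  Model
predictions average per-frame efficiencies E(R) over conformational
ensembles (FRET averages efficiency, not distance); efficiency-of-mean-
distance is available as an option.  Fits are unweighted by default
with an SEM-weighted variant available.

All 2^m − 1 subsets are ranked by AIC = n·ln(RSS/n) + 2k with
k = (subset size − 1) + 1 (free simplex coefficients plus the residual
variance); only ΔAIC ranks are meaningful and the convention is fixed.
AICc is also computed and can rank instead — relevant at n = 8.  A
detection limit worth knowing: with a minor component at weight 0.2 and
per-site noise sd 0.05, the generating pair is identified in ~95% of
replicates when it competes only against its own subsets, but in
78–87% when 3–4 candidate models are offered (the weak component is
dropped or swapped) — this is an information limit of the data size,
not of the solver.  The condition comparison uses a nested F-test with
mean-parameter counts (subset size − 1 per fit).

DEER distance distributions are interpolated onto a common grid inside
a configurable window (default 1.5–8 nm, outside which the experiment
is unreliable), renormalised, and fitted with the same simplex solver;
the combined distribution is renormalised to unit integral.

## Synthetic data (`synthetic`)

Generators emulate: Brownian tracks at the measured diffusivities
sampled at 30 ms with geometric (bleach-limited) track lengths;
two-channel dimerisation movies driven by the particle simulator with
multinomial 100:405:45 label assignment and exponential single-step
photobleaching per fluorophore; formation-event streams with
exponentially decaying areal rate; two-state anti-correlated
donor/acceptor traces (lognormal total intensity, exact discretised
two-state Markov paths, Gaussian shot-like noise with sd ∝ √signal);
random well-conditioned model matrices with efficiencies on (0.1, 0.95)
— the realistic span for 2–9 nm inter-label distances at R₀ = 7 nm —
and Gaussian-mixture distance distributions.  Every generator emits a
`SyntheticTruth` (all parameters + seed, JSON-serialisable); identical
seeds give identical outputs.

What the synthetic data do **not** emulate: pixel-level images and
point-spread functions, spot-detection/tracking errors (mislinking, gap
closing), illumination inhomogeneity (a per-position gain hook exists
but no estimator), camera-specific noise (read noise, EM gain
statistics), anomalous or confined diffusion, and membrane curvature.
Passing round-trip tests therefore demonstrates estimator correctness
under the generating model, not robustness to those real-data effects.

## Known limitations

- Effective simulator kinetics depend on dT through the per-overlap-step
  trial semantics; always calibrate p for the dT in use.
- The Bayesian two-mean comparison is a simplification of BEST; extreme
  posterior probabilities may differ beyond ±0.02 from the full model.
- The low-FRET-state exit rate from 30 ms dwell analysis is biased by
  missed sub-frame events (see above).
- The Saffman–Delbrück characteristic length L must be supplied; radius
  ratios scale with that choice.
- Subset identification by AIC degrades for minor components near the
  noise floor (see interface fitting above).
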