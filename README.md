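# dimerdyn

Quantitative machinery for studying transient dimerisation of membrane
receptors — motivated by single-molecule and ensemble FRET experiments
on the neurotensin receptor NTS1 in model membranes, where dimers turn
out to be short-lived (half-life ~1 s), concentration-dependent, and to
explore several interfaces ("rolling interface" behaviour).

The package is aimed at researchers analysing single-particle tracking
/ smFRET data of membrane-protein oligomerisation, and provides:

- **`mc_sim`** — a lattice-free 2D reaction–diffusion Monte Carlo:
  Brownian point receptors on a periodic membrane patch, Bernoulli
  dimerisation trials for monomer pairs at contact, first-order
  dissociation.  Comes with exact well-mixed oracles (mass action,
  Gillespie) and a routine that calibrates the per-step collision
  probability to a target association constant k_on (µm² s⁻¹).
- **`kinetics`** — MSD curves and diffusion fits from track tables
  (TrackMate exports accepted), z-test + Saffman–Delbrück comparison of
  diffusivities, the Hardt dilute-membrane collision frequency,
  photobleaching-corrected extrapolation of dimer-formation rates, the
  labelling-ratio correction, and derived constants
  (K_d = k_off/k_on = M²/D, t½ = ln2/k_off).
- **`ensemble_fret`** — labelling efficiency from absorbances, the
  donor-to-acceptor-ratio correction E_cor = E_app·(1+r_DA)/r_DA,
  Förster efficiency↔distance conversion (R₀ = 7.0 nm for A488–A555),
  Savitzky–Golay spectrum preprocessing, and a Bayesian apo-vs-agonist
  comparison per labelling site.
- **`smfret`** — lognormal intensity-mixture fits with bootstrap BIC
  model comparison, conservative high-FRET thresholds, dwell-time
  segmentation with survival curves, per-frame FRET efficiencies.
- **`interface_fit`** — exact simplex-constrained least squares fitting
  experimental per-site FRET efficiencies (or DEER distance
  distributions) as convex combinations of structural dimer-model
  predictions, AIC ranking of all model subsets, nested F-tests.
- **`synthetic`** — generators for all of the above inputs, each
  emitting its generating truth for round-trip validation.

Core model in brief: receptors diffuse with D_mon = 1.63 µm² s⁻¹
(monomer) and D_dim = 1.27 µm² s⁻¹ (dimer); monomers within the 5 nm
collision diameter dimerise stochastically such that the effective
association constant is k_on = 0.081 µm² s⁻¹, and dimers dissociate at
k_off = 0.58 s⁻¹.  Mass action then predicts the dimeric receptor
fraction 2D/ρ from k_on·M² = k_off·D and M + 2D = ρ, giving
K_d = 7.1 µm⁻² — within the physiological receptor-density range, which
is what makes the dimerisation functionally poised.

## Worked example

```python
from dimerdyn import mc_sim

# equilibrium composition at the single-molecule receptor density
eq = mc_sim.mass_action_equilibrium(k_on=0.081, k_off=0.58,
                                    total_density=0.43)
print(f"dimeric receptors: {100*eq.dimer_receptor_fraction:.1f}%  "
      f"K_d = {eq.K_d:.1f} um^-2")

# the same equilibrium from the particle simulator
cal_cfg = mc_sim.SimulationConfig(
    n_particles=300, density=5.0, p_collision=0.0, k_off=0.0,
    duration=1.0, dT=mc_sim.max_allowed_timestep(1.63, 0.005))
cal = mc_sim.calibrate_collision_probability(0.081, cal_cfg, seed=7)
print(f"calibrated p = {cal.p_collision:.2e} "
      f"(measured k_on = {cal.k_on_measured:.3f} um^2/s)")

cfg = mc_sim.SimulationConfig(
    n_particles=100, density=0.43, p_collision=cal.p_collision,
    k_off=0.58, duration=30.0,
    dT=mc_sim.max_allowed_timestep(1.63, 0.005), seed=101)
trace = mc_sim.run_simulation(cfg)
burn = int(round(10.0 / (trace.times[1] - trace.times[0])))  # skip 10 s
frac, se = mc_sim.dimer_fraction(trace, burn_in=burn)
print(f"simulated dimeric receptors: {100*frac:.1f} +- {100*se:.1f}%")
```

prints (the Monte-Carlo line varies within its standard error):

```
dimeric receptors: 9.8%  K_d = 7.2 um^-2
calibrated p = 2.03e-03 (measured k_on = 0.076 um^2/s)
simulated dimeric receptors: 9.8 +- 0.9%
```

That is the headline physics: at ~0.4 receptors/µm² about one receptor
in ten sits in a dimer, while the same rate constants predict ≥86%
dimers at 10³ µm⁻² — reconciling single-molecule (dilute) and ensemble
(dense) observations with one set of rate constants.

A command-line interface mirrors the library
(`dimerdyn simulate|synth|kinetics|fret|smfret|interface-fit|run`),
e.g. `dimerdyn simulate --config sim.yaml --out trace.csv`.

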