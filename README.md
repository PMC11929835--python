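# skintact

Finger-pad skin physiology, tactile friction and perception — a tested,
reusable analysis pipeline.

## The problem

How much of the person-to-person variation in finger-pad friction and tactile
perception can be explained by measurable skin physiology?  In studies of this
kind, a cohort of adults is characterized non-invasively — stratum-corneum
(SC) hydration (corneometer units) and thickness (µm), sweat-gland density and
finger-ridge distance, Meissner-corpuscle (MC) density (mm⁻²), and the
cutometer suction-deformation measures *R0* (total displacement in 2 s), *Ue*
(fast elastic displacement within 0.1 s) and *R2* (elastic recovery fraction)
— and each participant slides a finger over two families of stimuli: hard
plastic plates with self-affine random roughness (RMS roughness *Sq*, Hurst
exponent *H*, small-scale roughness summarized by the RMS curvature) and
elastic rubber plates carrying hexagonal lattices of bendable micropillars
with bending stiffness *F_L/θ = πED⁴/32L²*.

The analysis chain this package implements:

* **Friction extraction** — from a 3-axis force trace sampled at 50 Hz, touch
  is gated where *F_N* exceeds 4× the unloaded-sensor noise, and the trial's
  friction coefficient is the median of *μ = √(F_x² + F_y²)/F_N* over touch
  samples; circling speed is counted by phase-unwrapping the tangential force
  vector.
* **Composite outcomes** — varimax-rotated correlation-matrix PCA (Kaiser
  retention, KMO and Bartlett-sphericity diagnostics, Bartlett WLS scores)
  groups the outcomes into *μ_rough* (mean friction over the six rough
  samples), *μ_fibril* (mean over the four pillar samples with aspect ratio
  > 1) and the perception score *S_perc* = mean(z(pillar-detection rate),
  −z(two-point threshold)).
* **Statistics** — Pearson correlations with the regression t-test,
  percentile bootstrap over resampled pairs, OLS with per-predictor t values,
  Johnson relative weights (a decomposition of R² into non-negative
  per-predictor shares that is exact under correlated predictors), the
  MC×hydration interaction model, and the log-linear fit of MC density
  against age yielding a density half-life.
* **Psychophysics** — triplet roughness-ranking design (10 triplets over 6
  samples, each sample 5×), pairwise scoring against the RMS-curvature order,
  and maximum-likelihood fitting of the Weibull psychometric curve
  *p(x) = 1 − 0.5·exp(−(kx)^d)*, whose 75%-correct point is the
  just-noticeable difference (JND), analytically *(ln 2)^(1/d)/k*.
* **Synthetic cohorts** — a generator that reproduces the study's statistical
  structure (lognormal marginals matched to the reported relative SDs, a
  Gaussian copula for the reported pairwise correlations, MC density halving
  every 19 years of age, friction variance split between physiology, shared
  participant effects and noise), so every stage is testable without any
  external data.

## Worked example

```python
import numpy as np
import skintact as sk

cohort = sk.generate_cohort(sk.CohortConfig(n_participants=60, seed=2))
fit = sk.fit_age_decay(cohort["age"], cohort["MC_density"])
ci = sk.halflife_bootstrap_ci(cohort["age"], cohort["MC_density"],
                              sk.BootstrapConfig(n_resamples=10_000, seed=2))
print(f"MC density: mean {cohort['MC_density'].mean():.1f} / mm^2, "
      f"RSD {100 * sk.relative_sd(cohort['MC_density']):.0f}%")
print(f"half-life {fit.half_life:.1f} y (95% CI {ci[0]:.1f}-{ci[1]:.1f} y)")

mu = sk.generate_friction_coefficients(cohort, sk.FrictionModelConfig(seed=2))
perc = sk.generate_perception_data(cohort, sk.PerceptionModelConfig(seed=2),
                                   n_repetitions=5)
pooled = sk.aggregate_pairwise(perc["pairwise"])
pos = pooled[pooled["rel_diff"] > 0]
w = sk.fit_weibull(pos["rel_diff"], pos["n_success"], pos["n_trials"])
print(f"Weibull k={w.k:.2f}, d={w.d:.2f}, JND={w.jnd:.3f}")

tp = perc["two_point"]["threshold_mm"].replace(np.inf, 9.0)
comp = sk.build_composites(mu, perc["pillar_detection"].mean(axis=1), tp).table
ols = sk.ols_fit(cohort[["SC_hydration", "Ue", "R2", "SC_thickness",
                         "MC_density"]], comp["mu_rough"].to_numpy())
rw = sk.johnson_relative_weights(
    cohort[["SC_hydration", "Ue", "R2", "SC_thickness"]],
    comp["mu_rough"].to_numpy())
print(f"mu_rough: mean {comp['mu_rough'].mean():.2f}, "
      f"R^2 on physiology {ols.r_squared:.2f}")
print("relative weights (% of R^2):",
      {k: round(v, 1) for k, v in rw.rescaled_pct.items()})
```

prints

```
MC density: mean 7.4 / mm^2, RSD 42%
half-life 18.9 y (95% CI 16.7-21.6 y)
Weibull k=5.44, d=2.02, JND=0.153
mu_rough: mean 0.93, R^2 on physiology 0.73
relative weights (% of R^2): {'SC_hydration': 60.8, 'Ue': 19.0, 'R2': 14.8, 'SC_thickness': 5.4}
```

Read: in this 60-participant synthetic cohort, Meissner-corpuscle density
averages 7.4 mm⁻² and varies by 42% between participants, halving roughly
every 19 years of age; simulated roughness comparisons recover a Weber
fraction of ~0.15 (a 15% curvature difference is detected at 75% correct);
and the average friction coefficient on the rough samples is 0.93, with skin
physiology explaining 73% of its between-participant variance, hydration
carrying the largest relative weight.

There is also a command-line interface:

```bash
skintact report --seed 0 --out report/          # full simulate+analyze run
skintact simulate --seed 0 --out tables/        # synthetic tables only
skintact extract-friction trace.csv             # per-trial friction summary
skintact benchmark deposited_table.csv --out bench/
```

`benchmark` runs the analysis stages (PCA diagnostics, decay fit, correlation
matrices) on a user-supplied participant table; column names are matched
through a documented alias map.

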