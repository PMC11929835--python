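# Methods

This note documents the models behind `skintact`, the default parameter
choices and why they were made, the numerical details, and what the synthetic
cohort does and does not emulate.

## Synthetic cohort

### Marginals

All physiological quantities are strictly positive and right-skewed, so every
marginal is lognormal, parameterized by its mean and relative standard
deviation (RSD = SD/mean): for a target (m, c) the log-scale parameters are
σ² = ln(1 + c²) and µ = ln m − σ²/2, which match both moments exactly.  Age
is a truncated normal (mean 34 y, SD 11 y, range 20–70 y), matching the
enrolment profile such studies report.

Default RSDs are the study-reported values: Ue 41%, MC density 40%, R0 31%,
SC hydration 25%, SC thickness 25%, SG density 21%, ridge distance 15%,
R2 9%.  Means are mostly not reported and are set to physiologically
plausible defaults, all configurable: hydration 50 corneometer a.u.,
SC thickness 200 µm (finger pads have an unusually thick stratum corneum),
SG density 5 mm⁻², ridge distance 450 µm, R0 0.15 mm and Ue 0.09 mm (suction
displacements are smaller than the SC thickness), R2 0.62, MC density
7.2 mm⁻² (reported).

### Joint structure

Apart from MC density, the eight variables (age + seven skin parameters) are
coupled through a Gaussian copula.  The target Pearson correlations are the
reported pairwise values (R0–hydration 0.40, R2–thickness 0.39, R2–hydration
0.31, hydration–age −0.31, Ue–hydration 0.49); unspecified pairs default to
zero.  For lognormal–lognormal pairs the normal-scale correlation is
pre-adjusted by the exact Nataf inverse of the lognormal attenuation, so the
realized Pearson correlations match the targets; pairs involving age keep the
raw value (the attenuation through a truncated-normal marginal is
negligible at these magnitudes).  The assembled matrix is repaired to the
nearest positive-semidefinite correlation matrix by eigenvalue clipping
(clip 10⁻⁸) followed by diagonal renormalization.

### Meissner-corpuscle density

MC density is not drawn from the copula but generated mechanistically as

    MC = baseline · 2^(−age / 19 y) · exp(ε),   ε ~ N(0, σ²)

The 19-year half-life is the reported decay constant.  σ = 0.231 was solved
analytically so that the *total* RSD of MC density — age-driven decay plus
noise — equals the reported 40% under the default age distribution; the
baseline is computed from the truncated-normal expectation of the decay
factor so the population mean equals 7.2 mm⁻².  This construction implies
corr(log MC, age) ≈ −0.82, inside the study's bootstrap band for that
correlation, and makes the log-linear age fit recover the half-life without
further calibration.

Sex is assigned with fixed proportions (37 F / 23 M per 60) and only
SG density (F/M ratio 1.10) and ridge distance (0.95) receive a
mean-preserving dimorphism factor — the only sex differences the study
reports.  An optional missingness rate (default 0) blanks cells at random to
emulate incomplete measurement coverage.

## Friction model

Each participant × sample friction coefficient is

    μ_is = m_s · (1 + cv_s · d_is)

with per-sample mean m_s and within-sample RSD cv_s (rough samples: 0.92 and
0.30; pillar samples: means 1.2–2.0 increasing with aspect ratio, cv 0.20).
The standardized deviation d decomposes into a physiology score z (a fixed
linear combination of standardized hydration, Ue, R2 and SC thickness for
the rough class; Ue- and thickness-dominated for the fibrillar class), a
shared participant effect u per class, and per-sample noise:

    d_is = √a·z_i + √b·u_i + √(1−a−b)·ε_is

Given the target R² of the class-mean friction on physiology (0.74 rough,
0.34 fibrillar) and the share of residual variance common to the class's
samples (0.80 rough, 0.42 fibrillar), (a, b) follow in closed form.  These
two shares were chosen so the implied inter-sample correlations land where
the study reports them (≥ 0.94 between rough samples, ≈ 0.55 between
fibrillar ones).  The aspect-ratio-1 pillar samples (100/100, 150/150)
cross-load on both class factors (0.62 rough / 0.45 fibrillar), which is what
makes the outcome PCA reproduce their intermediate loadings.  Negative draws
are prevented by resampling the per-sample noise (truncation affects ≪ 0.1%
of draws at the default cv).

## Force traces

A trial is simulated as idle segments (pure sensor noise) flanking a contact
segment in which the clean normal force oscillates slowly (±0.1 N at 0.15 Hz)
around the 1 N guidance target, and the tangential force vector of magnitude
μ_true·F_N rotates at the circle rate (default 0.4 s⁻¹).  Independent
Gaussian noise (SD 0.01 N) is added per channel.  The paper-family protocols
do not state the sensor's noise model or the normal-force fluctuation
distribution; Gaussian is the default assumption and both scales are
configurable.  With noise off, extraction returns μ_true exactly (closure);
at default noise the extraction bias is below 0.01.

Extraction details: the unloaded-sensor noise, when not supplied, is the SD
of F_N over the leading 1 s idle window (the protocol leaves the sensor
unloaded there); samples at or below the 4×-noise threshold are excluded
entirely, never interpolated; F_N outside 0.8–1.2 N is flagged, not excluded;
cycles are counted by unwrapping the phase of (F_x, F_y) over touch samples
(the summary rounds to whole cycles, the rate uses the raw phase span).
Whether the trial median should run over samples or cycles is not specified
anywhere; the per-sample median is used.

## Surfaces

Micropillar lattices are hexagonal with lattice constant 2D, giving density
1/(2√3 D²) — 180 mm⁻² at D = 40 µm and 12.8 mm⁻² at D = 150 µm (the latter
is usually quoted rounded to 12).  Bending stiffness is the clamped-beam
value πED⁴/(32L²) with E = 1.7 MPa.

Self-affine surfaces are synthesized spectrally: Gaussian random Fourier
amplitudes with |h(q)|² ∝ q^(−2−2H) inside a passband between a
long-wavelength cutoff (default: the grid size) and a short-wavelength cutoff
(default 0.5 mm, the smallest wavelength present on the physical samples),
then rescaled so the measured RMS roughness equals Sq exactly.  RMS curvature
uses central second differences on interior nodes and averages the two axis
directions, sqrt((⟨h_xx²⟩ + ⟨h_yy²⟩)/2); cross-derivatives are excluded.  The
measured curvatures of the six physical rough samples (3.29 … 1.00 mm⁻¹) are
shipped as constants — they are properties of the manufactured sample set,
not reproduction targets.  The label ↔ curvature assignment is conventional
(labels in Table order, curvatures in the printed sorted order).

## Statistics

* Pearson correlations use pairwise deletion; significance is the two-sided
  t-test t = R√((n−2)/(1−R²)), equivalent to the one-predictor regression
  ANOVA.
* The decay fit regresses ln(density) on age; half-life = ln 2/|slope| (any
  log base gives the same half-life).  A non-negative slope reports the
  half-life as undefined rather than negative.
* Bootstrap CIs are percentile intervals over resamples of (x, y) pairs with
  replacement; default 10⁴ resamples (the full-fidelity 10⁶ of the original
  analysis is a flag away, `BootstrapConfig(n_resamples=10**6)`).  A
  vectorized path exists for the half-life CI, which makes the coverage
  simulation in the test suite affordable.
* Sex differences use Welch's unequal-variance t-test.  No multiple-testing
  correction is applied anywhere, matching the raw-p reporting convention of
  the source analyses.

## PCA and composites

The PCA operates on the correlation matrix because the variables carry
heterogeneous units; the Kaiser criterion (eigenvalue > 1) sets the retained
dimension.  Varimax rotation is Kaiser-normalized, converged to 10⁻⁶ within
1000 iterations; each rotated component is sign-fixed so its
largest-|loading| entry is positive, and components are ordered by explained
variance.  Communalities are preserved to 10⁻⁸ under rotation (orthogonal
transform).  Observation scores use Bartlett's weighted-least-squares
estimator with uniquenesses 1 − communality.  KMO and Bartlett's sphericity
test are computed from the correlation matrix and its inverse directly.

Composites follow the loading-threshold rule: μ_rough averages the six rough
samples, μ_fibril the four pillar samples with aspect ratio > 1; the
aspect-ratio-1 samples belong to neither (their loadings straddle the 0.75
threshold).  S_perc is the mean of the z-scored pillar-detection rate and
the negated z-scored two-point threshold — negated because a smaller
two-point distance means higher acuity.  Downstream correlations and
regressions analyze these plain averages; Bartlett scores are computed and
exported but not fed forward.

## Regression and relative weights

OLS is fit with an intercept through statsmodels; Johnson's relative weights
standardize predictors and outcome, take the symmetric square root
Λ = VΔVᵀ of the predictor correlation matrix, regress y on the implied
orthogonal counterparts (β = Λ⁻¹ r_xy) and allocate ε_j = Σ_k λ²_jk β²_k.
Σε equals R² to 10⁻⁸ and reduces to squared zero-order correlations under
orthogonality.  The interaction model centers both variables before forming
their product, which decorrelates the product from the main effects and
leaves the interaction inference shift-invariant.

## Psychophysics

The comparison model is p(x) = 1 − 0.5·exp(−(kx)^d): chance at zero
difference, saturating at 1.  The relative difference between two curvatures
is |c₁ − c₂| / ((c₁ + c₂)/2) by default; the /smaller and /larger conventions
are available, as Weber fractions are quoted under all three in the
literature.  Fitting is binomial maximum likelihood over (log k, log d) with
Nelder-Mead from four starts; all-success/all-failure data are flagged as
boundary fits.  The JND is computed analytically, (ln 2)^(1/d)/k.

A caveat the test suite quantifies: with the six-sample curvature set, only
three pairs fall near the 75% point and the next pairs are nearly saturated,
so the study-scale MLE of the JND is noticeably variable (SD ≈ 0.02) and
slightly biased low (≈ −0.007), driven by occasional runaway shape estimates.
The recovery checks therefore evaluate the median over seeded replicates of
the study-scale design, which is a stable estimate of what the design can
recover; the residual bias is left visible rather than corrected.

The triplet design covers 10 of the 20 possible triples over 6 samples so
that each sample appears exactly 5 times; the search is exhaustive with
count pruning and the presentation order is shuffled per seed.  Triplet
rankings are scored as all 30 within-triplet pairwise comparisons (3 per
triplet, pooled); whether pooled-30 or a per-triplet-unique-pair aggregation
was intended in the original protocol is ambiguous, and the scoring function
accepts any ranking stream, so either aggregation can be computed.

Two-point scoring walks the protocol: distances {0, 2, …, 8} mm first, the
minimal two-point distance is then retested together with 1 mm, and the
retest wins on contradiction (the recorded threshold moves to the next
larger first-pass two-point distance).  Simulated observers use a latent
threshold with Gaussian noise (lapse-free by default).

### Perception links in the generator

A latent tactile-sensitivity score per participant,

    P = 0.63·z(log MC) + 0.27·z(hydration) − 0.29·centered(z·z) + N(0, 0.67²)

drives the two-point threshold (4.0 − 1.3·P mm + noise, clamped to the
protocol range) and the pillar-detection probability
(logit p = 0.8 + 1.5·(log₁₀ k_bend + 3.5) + 1.2·P).  The weights were
calibrated once so the observable S_perc reproduces the study's composite
statistics — R ≈ 0.59 with MC density, main-effects regression R² ≈ 0.40
rising to ≈ 0.47 with the negative MC×hydration interaction — after the
attenuation caused by the coarse observables (six detection booleans, a
discretized threshold).  Pairwise roughness outcomes are Bernoulli draws
from the Weibull model (k = 5.55, d = 2 by default), independent of P; the
study found roughness-ranking success nearly uniform across participants, so
no physiology link is modelled there.

## Pipeline

One global seed derives all stage seeds through `numpy` seed-sequence
spawning (children reduced below 2³¹); identical config + seed reproduces
the report bundle byte-for-byte, and every CSV carries the seed and a config
hash in a comment header.  Stage failures abort with the stage name.  The
trace-closure path (simulate traces → re-extract μ) is off by default — it
multiplies runtime by the trial count and changes μ only within the
extraction noise — and is enabled with `simulate_traces=True` or
`--simulate-traces`.

Benchmark mode reads an external participant table through a case-insensitive
alias map, uses listwise deletion for the PCA and pairwise deletion for
correlations, and reruns the analysis stages only.  Nothing is downloaded;
the user supplies the file.

## Problem sizes in the test suite

Closure checks of population-level statistics use cohorts of 10,000
(marginals, correlations, R² targets, mean friction); recovery checks run at
study scale (56–60 participants) with 20–500 seeded replicates where a single
draw would be dominated by sampling noise; the bootstrap-coverage check uses
500 replicates of 2000 resamples through the vectorized half-life path.

## What the generator does not emulate

* No trial-level friction structure beyond the force-trace model: fatigue,
  order effects and exploration-strategy differences (pressing angle, speed)
  are absent, so the ~25% of friction variance the study attributes to
  unmeasured consistent individual differences is represented by an abstract
  shared participant effect, not a mechanism.
* MC density enters as a scalar; no microscopy images are simulated.
* No contact mechanics: pillar bending, capillary adhesion and viscoelastic
  deformation are summarized by the statistical links, not modelled.
* Cutometer curves are reduced to (R0, Ue, R2); the Ue ⊂ R0 structural
  dependence is not enforced (their correlation defaults to the copula's
  zero), so analyses of R0 − Ue differences are outside the generator's
  faithful range.
* Passing tests therefore demonstrate that the pipeline recovers the
  statistical structure it is pointed at — not that real skin behaves this
  way.
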