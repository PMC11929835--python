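"""Synthetic cohorts, friction outcomes, force traces and perception
responses with the statistical structure of the finger-pad study.

The generator emulates a cohort of healthy adults whose finger-pad skin is
characterized by stratum-corneum hydration and thickness, sweat-gland
density, ridge distance, Meissner-corpuscle (MC) density, and the cutometer
deformation measures R0 (total displacement), Ue (fast elastic component)
and R2 (relative elastic recovery).  Marginals are lognormal (all quantities
are strictly positive and right-skewed), parameterized by mean and relative
SD; the joint structure is a Gaussian copula with a configurable target
correlation matrix (nearest-PSD repaired by eigenvalue clipping).  MC
density is generated from its exponential decay with age - halving every 19
years - times lognormal noise, which also fixes its correlations with the
copula variables through age.

Friction coefficients per participant and sample are built from a latent
physiology score plus a shared participant effect plus per-sample noise,
with the variance split chosen so the population R^2 of the composite
outcomes on physiology and the inter-sample correlations match the study's
reported values.  Force traces and perception responses close the loop with
the extraction and psychophysics modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .friction_extraction import ForceTrace
from .psychophysics import (
    TripletDesign,
    build_triplet_design,
    two_point_threshold,
    weibull_probability,
)
from .surface_models import (
    FIBRIL_SAMPLES,
    PILLAR_SAMPLES,
    ROUGH_SAMPLES,
    ROUGH_SAMPLE_CURVATURE,
    bending_stiffness,
)

__all__ = [
    "CohortConfig",
    "FrictionModelConfig",
    "TrialConfig",
    "PerceptionModelConfig",
    "COPULA_VARIABLES",
    "generate_cohort",
    "generate_friction_coefficients",
    "generate_force_trace",
    "generate_perception_data",
    "nearest_psd_correlation",
    "split_seed",
]

#: Variables entering the Gaussian copula (MC density is driven by age).
COPULA_VARIABLES = (
    "age",
    "SC_hydration",
    "SC_thickness",
    "SG_density",
    "ridge_distance",
    "R0",
    "Ue",
    "R2",
)

_DEFAULT_MEANS = {
    # corneometer a.u.; µm; mm^-2; µm; mm; mm; fraction
    "SC_hydration": 50.0,
    "SC_thickness": 200.0,
    "SG_density": 5.0,
    "ridge_distance": 450.0,
    "R0": 0.15,
    "Ue": 0.09,
    "R2": 0.62,
}

#: Printed relative standard deviations per parameter.
_DEFAULT_RSD = {
    "SC_hydration": 0.25,
    "SC_thickness": 0.25,
    "SG_density": 0.21,
    "ridge_distance": 0.15,
    "R0": 0.31,
    "Ue": 0.41,
    "R2": 0.09,
}

#: Printed pairwise Pearson correlations; unspecified pairs default to zero.
_DEFAULT_CORRELATIONS = {
    ("R0", "SC_hydration"): 0.40,
    ("R2", "SC_thickness"): 0.39,
    ("R2", "SC_hydration"): 0.31,
    ("SC_hydration", "age"): -0.31,
    ("Ue", "SC_hydration"): 0.49,
}


def split_seed(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2^31) from one global seed."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def nearest_psd_correlation(matrix: np.ndarray, clip: float = 1e-8) -> np.ndarray:
    """Nearest positive-semidefinite correlation matrix by eigenvalue
    clipping, renormalized to a unit diagonal."""
    m = np.asarray(matrix, dtype=float)
    m = 0.5 * (m + m.T)
    eigval, eigvec = np.linalg.eigh(m)
    eigval = np.clip(eigval, clip, None)
    repaired = eigvec @ np.diag(eigval) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return repaired


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the synthetic cohort.

    Defaults reproduce the study conditions: 60 participants, ages 20-70
    (truncated normal, mean 34 SD 11), printed relative SDs and pairwise
    correlations, MC density halving every 19 years around a mean of
    7.2 mm^-2.  ``mc_log_noise_sd`` (0.231) is the SD of the lognormal noise
    on MC density, solved so the total MC relative SD equals the printed
    40% on top of the age-driven decay.
    """

    n_participants: int = 60
    seed: int = 0
    age_range: tuple[float, float] = (20.0, 70.0)
    age_mean: float = 34.0
    age_sd: float = 11.0
    marginal_means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    marginal_rsd: dict = field(default_factory=lambda: dict(_DEFAULT_RSD))
    target_correlations: dict = field(
        default_factory=lambda: dict(_DEFAULT_CORRELATIONS)
    )
    mc_mean: float = 7.2
    mc_half_life: float = 19.0
    mc_log_noise_sd: float = 0.231
    female_fraction: float = 37.0 / 60.0
    #: mean-preserving female/male ratio applied to sex-dimorphic parameters
    sex_ratios: dict = field(
        default_factory=lambda: {"SG_density": 1.10, "ridge_distance": 0.95}
    )
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise ValueError("a cohort needs at least 3 participants")
        if any(rsd < 0 for rsd in self.marginal_rsd.values()):
            raise ValueError("relative SDs must be non-negative")
        if self.mc_half_life <= 0:
            raise ValueError("MC half-life must be positive")
        for (a, b), r in self.target_correlations.items():
            if not (-1.0 <= r <= 1.0):
                raise ValueError(f"correlation target ({a},{b})={r} outside [-1,1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must lie in [0, 1)")

    def correlation_matrix(self) -> np.ndarray:
        """Assemble, Nataf-adjust and PSD-repair the copula correlation matrix.

        For lognormal-lognormal pairs the normal-scale correlation is
        pre-adjusted so the resulting Pearson correlation of the lognormal
        marginals matches the target (exact inverse of the lognormal
        correlation attenuation); pairs involving age keep the raw target.
        """
        k = len(COPULA_VARIABLES)
        idx = {v: i for i, v in enumerate(COPULA_VARIABLES)}
        mat = np.eye(k)
        sigmas = {
            v: math.sqrt(math.log(1.0 + self.marginal_rsd[v] ** 2))
            for v in COPULA_VARIABLES
            if v != "age"
        }
        for (a, b), r in self.target_correlations.items():
            if a not in idx or b not in idx:
                raise KeyError(f"unknown correlation variable in ({a}, {b})")
            if r != 0.0 and a != "age" and b != "age":
                sa, sb = sigmas[a], sigmas[b]
                if sa > 0 and sb > 0:
                    arg = 1.0 + r * math.sqrt(
                        math.expm1(sa**2) * math.expm1(sb**2)
                    )
                    r = math.log(arg) / (sa * sb)
            mat[idx[a], idx[b]] = mat[idx[b], idx[a]] = r
        return nearest_psd_correlation(mat)


def _age_distribution(config: CohortConfig) -> sps.rv_continuous:
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    return sps.truncnorm(a, b, loc=config.age_mean, scale=config.age_sd)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a participant table with the configured statistical structure.

    Age and the seven physiological parameters come from a Gaussian copula
    with lognormal marginals matched to mean/relative-SD; MC density is
    baseline * 2^(-age/half_life) * lognormal noise with the baseline set
    analytically so the population mean equals ``mc_mean``.  Deterministic
    under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    corr = config.correlation_matrix()
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(corr.shape[0]))
    z = rng.standard_normal((n, corr.shape[0])) @ chol.T
    u = sps.norm.cdf(z)

    age_dist = _age_distribution(config)
    columns: dict[str, np.ndarray] = {}
    for j, var in enumerate(COPULA_VARIABLES):
        if var == "age":
            columns[var] = age_dist.ppf(u[:, j])
        else:
            mean = config.marginal_means[var]
            rsd = config.marginal_rsd[var]
            sigma2 = math.log(1.0 + rsd**2)
            mu = math.log(mean) - sigma2 / 2.0
            columns[var] = np.exp(mu + math.sqrt(sigma2) * z[:, j])

    # MC density: exponential decay with age times lognormal noise
    lam = math.log(2.0) / config.mc_half_life
    attenuation = age_dist.expect(lambda a: np.exp(-lam * a))
    sigma_mc = config.mc_log_noise_sd
    baseline = config.mc_mean / (attenuation * math.exp(sigma_mc**2 / 2.0))
    noise = rng.normal(0.0, sigma_mc, size=n) if sigma_mc > 0 else np.zeros(n)
    columns["MC_density"] = baseline * np.exp(-lam * columns["age"]) * np.exp(noise)

    # sex assignment with fixed proportions and mean-preserving dimorphism
    n_female = int(round(config.female_fraction * n))
    sex = np.array(["F"] * n_female + ["M"] * (n - n_female))
    rng.shuffle(sex)
    p_f = n_female / n
    for var, ratio in config.sex_ratios.items():
        m_male = 1.0 / (p_f * ratio + (1.0 - p_f))
        factors = np.where(sex == "F", ratio * m_male, m_male)
        columns[var] = columns[var] * factors

    table = pd.DataFrame(
        {
            "participant": [f"P{i + 1:03d}" for i in range(n)],
            "age": columns["age"],
            "sex": sex,
            "SC_hydration": columns["SC_hydration"],
            "SC_thickness": columns["SC_thickness"],
            "SG_density": columns["SG_density"],
            "ridge_distance": columns["ridge_distance"],
            "MC_density": columns["MC_density"],
            "R0": columns["R0"],
            "Ue": columns["Ue"],
            "R2": columns["R2"],
        }
    ).set_index("participant")

    if config.missing_rate > 0:
        numeric = [c for c in table.columns if c not in ("sex", "age")]
        mask = rng.random(size=(n, len(numeric))) < config.missing_rate
        vals = table[numeric].to_numpy()
        vals[mask] = np.nan
        table[numeric] = vals
    return table


# ---------------------------------------------------------------------------
# Friction coefficients

#: Mean friction coefficient per sample.  The six rough plastic samples share
#: the study average 0.92; pillar means rise with aspect ratio from 1.2
#: (100/100) to 2.0 (40/120).
_DEFAULT_MEAN_MU = {
    **{s: 0.92 for s in ROUGH_SAMPLES},
    "100/100": 1.20,
    "150/150": 1.25,
    "100/200": 1.55,
    "150/350": 1.65,
    "100/300": 1.85,
    "40/120": 2.00,
}

_DEFAULT_WITHIN_RSD = {
    **{s: 0.30 for s in ROUGH_SAMPLES},   # printed range 28-33%
    **{s.label: 0.20 for s in PILLAR_SAMPLES},  # printed range 17-22%
}

#: Standardized-physiology weights of the latent friction scores.
_ROUGH_WEIGHTS = {"SC_hydration": 1.0, "SC_thickness": 0.65, "Ue": 0.55, "R2": 0.45}
_FIBRIL_WEIGHTS = {"Ue": 1.0, "SC_thickness": 0.7, "SC_hydration": 0.2, "R2": 0.2}

#: Cross-loadings of the aspect-ratio-1 samples on the (normalized) rough and
#: fibrillar common factors.
_ASPECT1_LOADINGS = (0.62, 0.45)


@dataclass(frozen=True)
class FrictionModelConfig:
    """Variance structure of the per-participant, per-sample friction model.

    ``r2_rough`` / ``r2_fibril`` are the population R^2 of the composite
    outcomes (mean over the class's samples) on the four physiological
    predictors; ``participant_effect_share`` is, per class, the fraction of
    residual variance shared across the class's samples (it controls the
    inter-sample correlations: rough ~0.94, fibrillar ~0.55).
    """

    sample_ids: tuple = tuple(ROUGH_SAMPLES) + tuple(s.label for s in PILLAR_SAMPLES)
    mean_mu: dict = field(default_factory=lambda: dict(_DEFAULT_MEAN_MU))
    within_sample_rsd: dict = field(default_factory=lambda: dict(_DEFAULT_WITHIN_RSD))
    r2_rough: float = 0.74
    r2_fibril: float = 0.34
    participant_effect_share: dict = field(
        default_factory=lambda: {"rough": 0.80, "fibril": 0.42}
    )
    seed: int = 1

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.mean_mu.values()):
            raise ValueError("mean friction coefficients must be positive")
        for r2 in (self.r2_rough, self.r2_fibril):
            if not (0.0 <= r2 < 1.0):
                raise ValueError("R^2 targets must lie in [0, 1)")
        for share in self.participant_effect_share.values():
            if not (0.0 <= share <= 1.0):
                raise ValueError("participant_effect_share must lie in [0, 1]")


def _variance_split(r2: float, share: float, n_samples: int) -> tuple[float, float]:
    """Solve (physiology variance a, shared-effect variance b) such that the
    R^2 of the class mean on physiology equals ``r2`` given that ``share`` of
    the residual (1 - a) is shared across the class's samples."""
    c = share + (1.0 - share) / n_samples
    a = r2 * c / (1.0 - r2 * (1.0 - c))
    b = share * (1.0 - a)
    return a, b


def _latent_score(cohort: pd.DataFrame, weights: dict) -> np.ndarray:
    """Unit-variance linear combination of standardized predictor columns."""
    z = np.column_stack(
        [
            (cohort[c] - cohort[c].mean()).to_numpy() / cohort[c].std(ddof=1)
            for c in weights
        ]
    )
    w = np.array(list(weights.values()))
    score = z @ w
    return score / score.std(ddof=1)


def generate_friction_coefficients(
    cohort: pd.DataFrame, model: FrictionModelConfig = FrictionModelConfig()
) -> pd.DataFrame:
    """True friction coefficients, participants x 12 samples.

    mu = mean_mu * (1 + cv * d) with a standardized deviation d composed of
    the latent physiology score, a shared participant effect per sample
    class, and per-sample noise.  The aspect-ratio-1 pillar samples load on
    both class factors (they behave partly like the rough plastic).  Draws
    with mu <= 0 are resampled (truncation), keeping all coefficients
    positive.
    """
    if cohort.empty:
        raise ValueError("cohort must not be empty")
    rng = np.random.default_rng(model.seed)
    n = len(cohort)

    z_rough = _latent_score(cohort, _ROUGH_WEIGHTS)
    z_fibril = _latent_score(cohort, _FIBRIL_WEIGHTS)

    a_r, b_r = _variance_split(
        model.r2_rough, model.participant_effect_share["rough"], len(ROUGH_SAMPLES)
    )
    a_f, b_f = _variance_split(
        model.r2_fibril, model.participant_effect_share["fibril"], len(FIBRIL_SAMPLES)
    )
    u_rough = rng.standard_normal(n)
    u_fibril = rng.standard_normal(n)
    common_rough = math.sqrt(a_r) * z_rough + math.sqrt(b_r) * u_rough
    common_fibril = math.sqrt(a_f) * z_fibril + math.sqrt(b_f) * u_fibril
    var_cr = a_r + b_r
    var_cf = a_f + b_f

    aspect1 = [s.label for s in PILLAR_SAMPLES if s.aspect_ratio == 1]
    alpha, beta = _ASPECT1_LOADINGS

    mu = {}
    for sample in model.sample_ids:
        if sample in ROUGH_SAMPLES:
            noise_sd = math.sqrt(max(1.0 - var_cr, 0.0))
            common = common_rough
        elif sample in FIBRIL_SAMPLES:
            noise_sd = math.sqrt(max(1.0 - var_cf, 0.0))
            common = common_fibril
        elif sample in aspect1:
            common = (
                alpha * common_rough / math.sqrt(var_cr)
                + beta * common_fibril / math.sqrt(var_cf)
            )
            noise_sd = math.sqrt(max(1.0 - alpha**2 - beta**2, 0.0))
        else:
            raise KeyError(f"unknown sample id {sample!r}")
        cv = model.within_sample_rsd[sample]
        mean = model.mean_mu[sample]
        d = common + noise_sd * rng.standard_normal(n)
        values = mean * (1.0 + cv * d)
        # truncated resampling of the per-sample noise keeps mu positive
        bad = values <= 0
        guard = 0
        while np.any(bad):
            d_new = common[bad] + noise_sd * rng.standard_normal(bad.sum())
            values[bad] = mean * (1.0 + cv * d_new)
            bad = values <= 0
            guard += 1
            if guard > 1000:  # pragma: no cover
                raise RuntimeError("friction truncation failed to converge")
        mu[f"mu_{sample}"] = values

    out = pd.DataFrame(mu, index=cohort.index)
    out.columns = [c.removeprefix("mu_") for c in out.columns]
    return out


# ---------------------------------------------------------------------------
# Force traces


@dataclass(frozen=True)
class TrialConfig:
    """One tactile-exploration trial: circling at ~0.4 circles/s for ~30 s
    under a guided normal force of about 1 N, recorded at 50 Hz with idle
    segments flanking the contact."""

    duration: float = 30.0
    circle_rate: float = 0.4
    fn_target: float = 1.0
    fn_jitter: float = 0.1
    sensor_noise_sd: float = 0.01
    sampling_rate: float = 50.0
    pre_post_idle: float = 2.0
    duration_bounds: tuple[float, float] = (15.4, 69.4)
    circle_rate_bounds: tuple[float, float] = (0.06, 1.21)
    fn_target_bounds: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        lo, hi = self.duration_bounds
        if not (lo <= self.duration <= hi):
            raise ValueError(f"duration must lie within [{lo}, {hi}] s")
        lo, hi = self.circle_rate_bounds
        if not (lo <= self.circle_rate <= hi):
            raise ValueError(f"circle rate must lie within [{lo}, {hi}] 1/s")
        lo, hi = self.fn_target_bounds
        if not (lo <= self.fn_target <= hi):
            raise ValueError(f"normal-force target must lie within [{lo}, {hi}] N")
        if self.duration <= 2.0 * self.pre_post_idle:
            raise ValueError("duration must exceed twice the idle time")


def generate_force_trace(
    mu_true: float, trial: TrialConfig = TrialConfig(), seed: int = 0
) -> ForceTrace:
    """Simulate one trial's 3-axis force trace.

    Idle segments (sensor noise only) flank a contact segment in which the
    clean normal force oscillates slowly around the target and the
    tangential force vector of magnitude mu_true * FN_clean rotates at the
    circle rate.  Independent Gaussian sensor noise is added to each
    channel, so with all noise switched off the extracted friction
    coefficient equals ``mu_true`` exactly.
    """
    if mu_true <= 0:
        raise ValueError("mu_true must be positive")
    rng = np.random.default_rng(seed)
    fs = trial.sampling_rate
    n = int(round(trial.duration * fs))
    t = np.arange(n) / fs
    contact = (t >= trial.pre_post_idle) & (t < trial.duration - trial.pre_post_idle)

    load_phase = rng.uniform(0.0, 2.0 * math.pi)
    circle_phase = rng.uniform(0.0, 2.0 * math.pi)
    fn_clean = np.where(
        contact,
        trial.fn_target
        + trial.fn_jitter * np.sin(2.0 * math.pi * 0.15 * t + load_phase),
        0.0,
    )
    theta = 2.0 * math.pi * trial.circle_rate * t + circle_phase
    ff_clean = mu_true * fn_clean
    fx = np.where(contact, ff_clean * np.cos(theta), 0.0)
    fy = np.where(contact, ff_clean * np.sin(theta), 0.0)

    if trial.sensor_noise_sd > 0:
        fx = fx + rng.normal(0.0, trial.sensor_noise_sd, n)
        fy = fy + rng.normal(0.0, trial.sensor_noise_sd, n)
        fn = fn_clean + rng.normal(0.0, trial.sensor_noise_sd, n)
    else:
        fn = fn_clean
    return ForceTrace(t, fx, fy, fn)


# ---------------------------------------------------------------------------
# Perception responses


@dataclass(frozen=True)
class PerceptionModelConfig:
    """Links from physiology to the three perception channels.

    A latent tactile-sensitivity score per participant,

        P = w_mc * z(log MC) + w_hyd * z(hydration)
            + w_int * centered(z(log MC) * z(hydration)) + noise,

    drives both the two-point threshold (linearly, in mm) and the
    per-sample pillar-detection probability (on the logit scale, together
    with the log bending stiffness of the pillars).  The negative
    interaction weight makes high hydration flatten the MC-density
    dependence of sensitivity.  Pairwise roughness judgements are Bernoulli
    with success probability given by the Weibull psychometric function at
    the pair's relative curvature difference.
    """

    weibull_k: float = 5.55
    weibull_d: float = 2.0
    sensitivity_mc_weight: float = 0.63
    sensitivity_hydration_weight: float = 0.27
    sensitivity_interaction_weight: float = -0.29
    sensitivity_noise_sd: float = 0.67
    #: threshold_mm = intercept + slope * P + noise, clamped to [0.5, 9.5]
    two_point_link: tuple[float, float] = (4.0, -1.3)
    two_point_noise_sd: float = 0.6
    #: logit p = intercept + stiffness_slope*(log10 k_bend + 3.5) + gain * P
    pillar_detect_link: tuple[float, float, float] = (0.8, 1.5, 1.2)
    seed: int = 2

    def __post_init__(self) -> None:
        if self.weibull_k <= 0 or self.weibull_d <= 0:
            raise ValueError("Weibull parameters must be positive")


def _latent_sensitivity(
    cohort: pd.DataFrame, perc: PerceptionModelConfig, rng: np.random.Generator
) -> np.ndarray:
    logmc = np.log(cohort["MC_density"].to_numpy())
    z_mc = (logmc - logmc.mean()) / logmc.std(ddof=1)
    hyd = cohort["SC_hydration"].to_numpy()
    z_h = (hyd - hyd.mean()) / hyd.std(ddof=1)
    inter = z_mc * z_h
    inter = inter - inter.mean()
    score = (
        perc.sensitivity_mc_weight * z_mc
        + perc.sensitivity_hydration_weight * z_h
        + perc.sensitivity_interaction_weight * inter
    )
    if perc.sensitivity_noise_sd > 0:
        score = score + rng.normal(0.0, perc.sensitivity_noise_sd, len(cohort))
    return score


def generate_perception_data(
    cohort: pd.DataFrame,
    perc: PerceptionModelConfig = PerceptionModelConfig(),
    design: TripletDesign | None = None,
    curvature_by_label: dict | None = None,
    n_repetitions: int = 1,
) -> dict:
    """Simulate the three perceptional tasks for every participant.

    Returns a dict with keys ``two_point`` (participant, threshold_mm),
    ``pillar_detection`` (boolean participants x pillar samples),
    ``pairwise`` (per within-triplet pair slot: participant, pair, rel_diff,
    success) and ``latent_sensitivity`` (the latent score, for diagnostics).
    """
    if cohort.empty:
        raise ValueError("cohort must not be empty")
    rng = np.random.default_rng(perc.seed)
    curvatures = dict(
        curvature_by_label if curvature_by_label is not None else ROUGH_SAMPLE_CURVATURE
    )
    if design is None:
        design = build_triplet_design(tuple(curvatures), seed=perc.seed)
    unknown = {lab for tri in design.triplets for lab in tri} - set(curvatures)
    if unknown:
        raise KeyError(f"unknown sample id(s) in design: {sorted(unknown)}")

    latent = _latent_sensitivity(cohort, perc, rng)

    # two-point discrimination: latent threshold + protocol walk
    intercept, slope = perc.two_point_link
    tau = intercept + slope * latent
    if perc.two_point_noise_sd > 0:
        tau = tau + rng.normal(0.0, perc.two_point_noise_sd, len(cohort))
    tau = np.clip(tau, 0.5, 9.5)
    records = []
    for pid, thr in zip(cohort.index, tau):
        rec = two_point_threshold(lambda dist, thr=thr: dist >= thr, participant=pid)
        records.append({"participant": pid, "threshold_mm": rec.threshold_mm})
    two_point = pd.DataFrame(records).set_index("participant")

    # pillar detection: Bernoulli per pillar sample
    a0, a1, gain = perc.pillar_detect_link
    det = {}
    for sample in PILLAR_SAMPLES:
        logit = a0 + a1 * (math.log10(bending_stiffness(sample)) + 3.5) + gain * latent
        p = 1.0 / (1.0 + np.exp(-logit))
        det[sample.label] = rng.random(len(cohort)) < p
    pillar_detection = pd.DataFrame(det, index=cohort.index)

    # pairwise roughness judgements: Bernoulli with Weibull success probability
    pair_table = design.pair_table(curvatures)
    n_pairs = len(pair_table)
    n_part = len(cohort)
    p_success = weibull_probability(
        pair_table["rel_diff"].to_numpy(), perc.weibull_k, perc.weibull_d
    )
    draws = rng.random((n_repetitions * n_part, n_pairs)) < p_success
    pairwise = pd.DataFrame(
        {
            "participant": np.tile(
                np.repeat(cohort.index.to_numpy(), n_pairs), n_repetitions
            ),
            "pair": np.tile(pair_table["pair"].to_numpy(), n_repetitions * n_part),
            "rel_diff": np.tile(
                pair_table["rel_diff"].to_numpy(), n_repetitions * n_part
            ),
            "success": draws.ravel().astype(int),
        }
    )

    return {
        "two_point": two_point,
        "pillar_detection": pillar_detection,
        "pairwise": pairwise,
        "latent_sensitivity": pd.Series(latent, index=cohort.index, name="latent"),
        "design": design,
    }
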