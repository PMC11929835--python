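"""End-to-end orchestration: simulate -> extract -> analyze -> report.

A single global seed deterministically derives the per-stage seeds, every
report table carries the seed and a config hash in its header, and the whole
bundle is byte-reproducible.  Benchmark mode runs the analysis stages on a
user-supplied participant table instead of a simulated cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import components, psychophysics, regression, stats_core, synthetic_data
from .friction_extraction import friction_coefficient

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "run_pipeline",
    "run_benchmark",
    "read_participant_table",
    "load_config",
    "save_config",
    "PREDICTORS",
]

logger = logging.getLogger("skintact")

#: Predictor set of the headline regressions (deformability is represented
#: by its fast component Ue; R0 is dropped as redundant with Ue).
PREDICTORS = ("SC_hydration", "Ue", "R2", "SC_thickness", "MC_density")

#: Accepted aliases when reading external participant tables.
COLUMN_ALIASES = {
    "age": "age",
    "sex": "sex",
    "gender": "sex",
    "sc_hydration": "SC_hydration",
    "hydration": "SC_hydration",
    "sc_thickness": "SC_thickness",
    "thickness": "SC_thickness",
    "sg_density": "SG_density",
    "sweat_gland_density": "SG_density",
    "ridge_distance": "ridge_distance",
    "mc_density": "MC_density",
    "meissner_density": "MC_density",
    "r0": "R0",
    "ue": "Ue",
    "r2": "R2",
    "participant": "participant",
    "id": "participant",
    "subject": "participant",
}

MANDATORY_COLUMNS = ("age", "SC_hydration", "SC_thickness", "MC_density", "Ue", "R2")


@dataclass(frozen=True)
class PipelineConfig:
    cohort: synthetic_data.CohortConfig = field(
        default_factory=synthetic_data.CohortConfig
    )
    friction: synthetic_data.FrictionModelConfig = field(
        default_factory=synthetic_data.FrictionModelConfig
    )
    trials: synthetic_data.TrialConfig = field(default_factory=synthetic_data.TrialConfig)
    perception: synthetic_data.PerceptionModelConfig = field(
        default_factory=synthetic_data.PerceptionModelConfig
    )
    bootstrap: stats_core.BootstrapConfig = field(default_factory=stats_core.BootstrapConfig)
    seed: int = 0
    simulate_traces: bool = False
    output_dir: str | None = None

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Re-derive all sub-config seeds deterministically from one seed."""
        s_cohort, s_friction, s_perc, s_boot, s_trace = synthetic_data.split_seed(seed, 5)
        return dataclasses.replace(
            self,
            seed=seed,
            cohort=dataclasses.replace(self.cohort, seed=s_cohort),
            friction=dataclasses.replace(self.friction, seed=s_friction),
            perception=dataclasses.replace(self.perception, seed=s_perc),
            bootstrap=dataclasses.replace(self.bootstrap, seed=s_boot),
        )

    def config_hash(self) -> str:
        payload = json.dumps(_config_dict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:10]


def _config_dict(config: PipelineConfig) -> dict:
    out = dataclasses.asdict(config)

    def clean(obj):
        if isinstance(obj, dict):
            # tuple keys (correlation pairs) serialize as "a,b"
            return {
                (",".join(k) if isinstance(k, tuple) else str(k)): clean(v)
                for k, v in obj.items()
            }
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return clean(out)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_config_dict(config), fh, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValueError("config file must state an explicit seed")

    def build(cls, data, tuple_fields=()):
        if data is None:
            return cls()
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in data:
                value = data[f.name]
                if f.name in tuple_fields and isinstance(value, list):
                    value = tuple(value)
                kwargs[f.name] = value
        return cls(**kwargs)

    cohort_raw = raw.get("cohort")
    if cohort_raw and "target_correlations" in cohort_raw:
        cohort_raw = dict(cohort_raw)
        cohort_raw["target_correlations"] = {
            tuple(k.split(",")): v
            for k, v in cohort_raw["target_correlations"].items()
        }

    return PipelineConfig(
        cohort=build(synthetic_data.CohortConfig, cohort_raw, ("age_range",)),
        friction=build(
            synthetic_data.FrictionModelConfig, raw.get("friction"), ("sample_ids",)
        ),
        trials=build(
            synthetic_data.TrialConfig,
            raw.get("trials"),
            ("duration_bounds", "circle_rate_bounds", "fn_target_bounds"),
        ),
        perception=build(
            synthetic_data.PerceptionModelConfig,
            raw.get("perception"),
            ("two_point_link", "pillar_detect_link"),
        ),
        bootstrap=build(stats_core.BootstrapConfig, raw.get("bootstrap")),
        seed=int(raw["seed"]),
        simulate_traces=bool(raw.get("simulate_traces", False)),
        output_dir=raw.get("output_dir"),
    )


@dataclass
class ReportBundle:
    cohort: pd.DataFrame
    mu_table: pd.DataFrame
    composites: pd.DataFrame
    distributions: pd.DataFrame
    predictor_correlations: pd.DataFrame
    friction_correlations: pd.DataFrame
    pca_friction_perception: components.FactorAnalysisResult
    pca_physiology: components.FactorAnalysisResult
    regression_table: pd.DataFrame
    relative_weights: pd.DataFrame
    interaction: dict
    psychometric_fit: psychophysics.WeibullFit
    detection_rates: pd.DataFrame
    decay_fit: stats_core.DecayFit
    decay_ci: tuple[float, float]
    seed: int
    config_hash: str
    stage_log: list


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _distribution_table(cohort: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for col in cohort.columns:
        if col == "sex":
            continue
        vals = cohort[col].dropna().to_numpy(dtype=float)
        rows.append(
            {
                "parameter": col,
                "n": len(vals),
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "rsd": stats_core.relative_sd(vals),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def run_pipeline(config: PipelineConfig = PipelineConfig()) -> ReportBundle:
    """Execute the full analysis chain on a simulated cohort.

    Stages: cohort generation, friction coefficients (optionally closed
    through simulated force traces and re-extraction), perception responses,
    descriptive statistics, correlation matrices, the two PCAs, composite
    outcomes, regressions with Johnson relative weights and the MC x
    hydration interaction, psychometric fitting, and the MC-age decay fit
    with a bootstrap CI.  Any stage failure aborts with the stage name.
    """
    config = config.with_seed(config.seed)
    stage_log: list = []

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as err:
            raise StageError(name, err) from err
        elapsed = time.perf_counter() - t0
        n_rows = len(result) if hasattr(result, "__len__") else None
        stage_log.append({"stage": name, "seconds": round(elapsed, 3), "n": n_rows})
        logger.info("stage %-22s %6.2fs n=%s", name, elapsed, n_rows)
        return result

    cohort = stage("generate_cohort", lambda: synthetic_data.generate_cohort(config.cohort))
    mu_table = stage(
        "friction_coefficients",
        lambda: synthetic_data.generate_friction_coefficients(cohort, config.friction),
    )

    if config.simulate_traces:
        def extract_all():
            seeds = synthetic_data.split_seed(config.seed + 1, len(cohort) * len(mu_table.columns))
            out = mu_table.copy()
            k = 0
            for pid in mu_table.index:
                for col in mu_table.columns:
                    trace = synthetic_data.generate_force_trace(
                        mu_table.loc[pid, col], config.trials, seed=seeds[k]
                    )
                    out.loc[pid, col] = friction_coefficient(trace).mu_median
                    k += 1
            return out

        mu_table = stage("trace_extraction", extract_all)

    perception = stage(
        "perception_responses",
        lambda: synthetic_data.generate_perception_data(cohort, config.perception),
    )

    distributions = stage("descriptive_stats", lambda: _distribution_table(cohort))

    predictor_cols = ["age", "SC_hydration", "SC_thickness", "SG_density",
                      "ridge_distance", "MC_density", "R0", "Ue", "R2"]
    predictor_corr = stage(
        "predictor_correlations",
        lambda: stats_core.correlation_matrix(cohort, predictor_cols),
    )
    friction_corr = stage(
        "friction_correlations", lambda: stats_core.correlation_matrix(mu_table)
    )

    detection = stage(
        "detection_rates",
        lambda: psychophysics.detection_probability(perception["pillar_detection"]),
    )
    pillar_rate = perception["pillar_detection"].mean(axis=1)
    two_point = perception["two_point"]["threshold_mm"]
    # participants who never resolved two points enter at the largest distance
    two_point = two_point.replace(np.inf, 9.0)

    def pca_outcomes():
        table = mu_table.copy()
        table.columns = [f"mu_{c}" for c in table.columns]
        table["two_point"] = two_point
        table["pillar_perception"] = pillar_rate
        return components.pca_varimax(table)

    pca_fp = stage("pca_friction_perception", pca_outcomes)
    pca_phys = stage(
        "pca_physiology",
        lambda: components.pca_varimax(
            cohort[["MC_density", "age", "R2", "SC_thickness", "ridge_distance",
                    "SC_hydration", "SG_density", "R0"]]
        ),
    )

    composites = stage(
        "composites",
        lambda: components.build_composites(mu_table, pillar_rate, two_point).table,
    )

    def regressions():
        X = cohort[list(PREDICTORS)]
        rows = {}
        for outcome in ("mu_rough", "mu_fibril", "s_perc"):
            fit = regression.ols_fit(X, composites[outcome].to_numpy())
            rows[outcome] = fit.summary_row(list(PREDICTORS))
        return pd.DataFrame(rows).T

    regression_table = stage("regressions", regressions)

    relative_weights = stage(
        "relative_weights",
        lambda: regression.per_sample_regressions(
            mu_table, cohort[["SC_hydration", "Ue", "R2", "SC_thickness"]]
        ),
    )

    interaction = stage(
        "mc_hydration_interaction",
        lambda: regression.interaction_model(
            np.log(cohort["MC_density"].to_numpy()),
            cohort["SC_hydration"].to_numpy(),
            composites["s_perc"].to_numpy(),
        ),
    )

    def psychometrics():
        pooled = psychophysics.aggregate_pairwise(perception["pairwise"])
        positive = pooled[pooled["rel_diff"] > 0]
        return psychophysics.fit_weibull(
            positive["rel_diff"], positive["n_success"], positive["n_trials"]
        )

    weibull = stage("psychometric_fit", psychometrics)

    decay = stage(
        "mc_age_decay",
        lambda: stats_core.fit_age_decay(cohort["age"], cohort["MC_density"]),
    )
    decay_ci = stage(
        "decay_bootstrap_ci",
        lambda: stats_core.halflife_bootstrap_ci(
            cohort["age"], cohort["MC_density"], config.bootstrap
        ),
    )

    bundle = ReportBundle(
        cohort=cohort,
        mu_table=mu_table,
        composites=composites,
        distributions=distributions,
        predictor_correlations=predictor_corr,
        friction_correlations=friction_corr,
        pca_friction_perception=pca_fp,
        pca_physiology=pca_phys,
        regression_table=regression_table,
        relative_weights=relative_weights,
        interaction=interaction,
        psychometric_fit=weibull,
        detection_rates=detection,
        decay_fit=decay,
        decay_ci=decay_ci,
        seed=config.seed,
        config_hash=config.config_hash(),
        stage_log=stage_log,
    )
    if config.output_dir is not None:
        write_report(bundle, config.output_dir)
    return bundle


def write_report(bundle: ReportBundle, output_dir) -> list[Path]:
    """Write the report bundle as CSV files, each with a provenance header."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# seed={bundle.seed} config_hash={bundle.config_hash}\n"

    def dump(name: str, df: pd.DataFrame, index=True) -> Path:
        path = out / name
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, index=index, float_format="%.6g")
        return path

    paths = [
        dump("cohort.csv", bundle.cohort),
        dump("friction_coefficients.csv", bundle.mu_table),
        dump("composites.csv", bundle.composites),
        dump("distributions.csv", bundle.distributions),
        dump("correlations_predictors.csv", bundle.predictor_correlations),
        dump("correlations_friction.csv", bundle.friction_correlations),
        dump("pca_friction_perception_loadings.csv",
             bundle.pca_friction_perception.rotated_loadings),
        dump("pca_physiology_loadings.csv", bundle.pca_physiology.rotated_loadings),
        dump("regressions.csv", bundle.regression_table),
        dump("relative_weights.csv", bundle.relative_weights, index=False),
        dump("detection_rates.csv", bundle.detection_rates, index=False),
    ]
    fit = bundle.psychometric_fit
    summary = pd.DataFrame(
        {
            "quantity": [
                "weibull_k", "weibull_d", "jnd", "weibull_loglik",
                "decay_half_life_y", "decay_ci_low_y", "decay_ci_high_y",
                "decay_r_logscale",
                "pca_fp_components", "pca_fp_cumvar_pct",
                "pca_phys_components", "pca_phys_cumvar_pct",
                "kmo_friction_perception", "bartlett_chi2_friction_perception",
                "kmo_physiology", "bartlett_chi2_physiology",
                "interaction_coef", "interaction_p", "interaction_delta_r2",
            ],
            "value": [
                fit.k, fit.d, fit.jnd, fit.log_likelihood,
                bundle.decay_fit.half_life, bundle.decay_ci[0], bundle.decay_ci[1],
                bundle.decay_fit.r,
                bundle.pca_friction_perception.n_components,
                bundle.pca_friction_perception.cumulative_variance_pct,
                bundle.pca_physiology.n_components,
                bundle.pca_physiology.cumulative_variance_pct,
                bundle.pca_friction_perception.kmo,
                bundle.pca_friction_perception.bartlett_chi2,
                bundle.pca_physiology.kmo,
                bundle.pca_physiology.bartlett_chi2,
                bundle.interaction["interaction_coef"],
                bundle.interaction["interaction_p"],
                bundle.interaction["delta_r2"],
            ],
        }
    )
    paths.append(dump("summary.csv", summary, index=False))
    return paths


def read_participant_table(path) -> tuple[pd.DataFrame, list[str]]:
    """Read and validate an external participant table.

    Column names are matched case-insensitively against the documented alias
    map; unknown columns are preserved and returned in the flag list.
    Non-numeric cells in numeric columns raise with the row named.
    """
    df = pd.read_csv(path, comment="#")
    renames = {}
    unknown = []
    for col in df.columns:
        key = col.strip().lower().replace(" ", "_")
        if key in COLUMN_ALIASES:
            renames[col] = COLUMN_ALIASES[key]
        elif key.startswith("mu_") or key.startswith("µ"):
            renames[col] = "mu_" + key.removeprefix("mu_").lstrip("µs_")
        else:
            unknown.append(col)
    df = df.rename(columns=renames)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"participant table lacks mandatory column(s): {missing}")
    if "participant" in df.columns:
        df = df.set_index("participant")
    numeric = [c for c in df.columns if c != "sex" and c not in unknown]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & converted.isna()
        if bad.any():
            row = df.index[bad][0]
            raise ValueError(f"non-numeric value in column {col!r}, row {row!r}")
        df[col] = converted
    return df, unknown


def run_benchmark(table_path, bootstrap: stats_core.BootstrapConfig | None = None) -> dict:
    """Analysis stages on a deposited participant table (no simulation).

    Runs the physiology PCA (and the friction/perception PCA when friction
    columns are present), the headline regressions and the MC-age decay fit
    with bootstrap CI, using pairwise/listwise deletion as each statistic
    requires.  Returns a dict of results.
    """
    table, unknown = read_participant_table(table_path)
    if unknown:
        logger.warning("ignoring unrecognized columns: %s", unknown)
    results: dict = {"n_rows": len(table), "unknown_columns": unknown}

    phys_cols = [c for c in
                 ("MC_density", "age", "R2", "SC_thickness", "ridge_distance",
                  "SC_hydration", "SG_density", "R0") if c in table.columns]
    phys = table[phys_cols].dropna()
    results["pca_physiology"] = components.pca_varimax(phys)

    mu_cols = [c for c in table.columns if c.startswith("mu_")]
    if mu_cols:
        results["pca_friction"] = components.pca_varimax(table[mu_cols].dropna())

    results["decay_fit"] = stats_core.fit_age_decay(table["age"], table["MC_density"])
    results["decay_ci"] = stats_core.halflife_bootstrap_ci(
        table["age"], table["MC_density"],
        bootstrap or stats_core.BootstrapConfig(),
    )
    preds = [c for c in PREDICTORS if c in table.columns]
    results["predictor_correlations"] = stats_core.correlation_matrix(
        table, preds + (["age"] if "age" in table.columns else [])
    )
    return results
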