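"""Shared descriptive and inferential statistics.

Pearson correlations with the regression t-test for significance, relative
standard deviations, z-scores, percentile-bootstrap confidence intervals over
resampled value pairs, Welch's t-test for sex differences, and the log-linear
fit of Meissner-corpuscle density against age that yields the density
half-life.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "DecayFit",
    "BootstrapConfig",
    "pearson_with_p",
    "relative_sd",
    "zscore",
    "fit_age_decay",
    "bootstrap_ci",
    "halflife_bootstrap_ci",
    "welch_ttest",
    "write_correlation_matrix",
    "correlation_matrix",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class DecayFit:
    """Log-linear decay of a positive quantity with age.

    ``slope`` and ``intercept`` refer to natural-log density versus age;
    ``half_life`` is ln(2)/|slope| in years (any log base gives the same
    half-life).  ``half_life`` is NaN when the fitted slope is non-negative
    (no decay).  ``r`` is the Pearson correlation on the log scale.
    """

    slope: float
    intercept: float
    half_life: float
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class BootstrapConfig:
    n_resamples: int = 10_000
    confidence: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence must lie in (0, 1)")
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be positive")


def _paired_finite(x, y) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise deletion: keep index positions where both values are finite."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson_with_p(x, y) -> CorrelationResult:
    """Pearson R with a two-sided p-value from t = R*sqrt((n-2)/(1-R^2)).

    Missing pairs are dropped (pairwise deletion).  The t-based test is the
    single-predictor regression ANOVA.
    """
    x, y = _paired_finite(x, y)
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs at least 3 complete pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def relative_sd(x) -> float:
    """Sample standard deviation (n-1 denominator) divided by the mean."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    mean = x.mean()
    if mean == 0.0:
        raise ValueError("relative SD undefined for zero mean")
    return float(np.std(x, ddof=1) / mean)


def zscore(x) -> np.ndarray:
    """Standardize to mean 0 and SD 1 (n-1 denominator); NaNs propagate."""
    x = np.asarray(x, dtype=float)
    finite = x[np.isfinite(x)]
    sd = np.std(finite, ddof=1)
    if sd == 0.0:
        raise ValueError("z-score undefined for zero-variance input")
    return (x - finite.mean()) / sd


def fit_age_decay(age, density) -> DecayFit:
    """OLS of ln(density) on age; half-life = ln(2)/(-slope).

    The half-life is invariant to multiplying all densities by a positive
    constant (only the intercept shifts).
    """
    age, density = _paired_finite(age, density)
    if np.any(density <= 0):
        raise ValueError("densities must be positive for the log-linear fit")
    if age.size < 3:
        raise ValueError("decay fit needs at least 3 complete pairs")
    res = sps.linregress(age, np.log(density))
    slope = float(res.slope)
    half_life = np.log(2.0) / -slope if slope < 0 else float("nan")
    return DecayFit(
        slope=slope,
        intercept=float(res.intercept),
        half_life=half_life,
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=age.size,
    )


def bootstrap_ci(
    statistic: Callable[[np.ndarray, np.ndarray], float],
    x,
    y,
    config: BootstrapConfig = BootstrapConfig(),
) -> tuple[float, float]:
    """Percentile CI of a paired statistic, resampling value pairs with
    replacement.

    The statistic may raise on degenerate resamples; resamples failing on
    more than 1% of draws abort the interval.
    """
    x, y = _paired_finite(x, y)
    n = x.size
    rng = np.random.default_rng(config.seed)
    values = np.empty(config.n_resamples)
    failures = 0
    for b in range(config.n_resamples):
        idx = rng.integers(0, n, size=n)
        try:
            values[b] = statistic(x[idx], y[idx])
        except (ValueError, ZeroDivisionError, FloatingPointError):
            values[b] = np.nan
            failures += 1
    if failures > 0.01 * config.n_resamples:
        raise RuntimeError(
            f"statistic failed on {failures}/{config.n_resamples} resamples"
        )
    alpha = 1.0 - config.confidence
    lo, hi = np.nanpercentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def halflife_bootstrap_ci(
    age, density, config: BootstrapConfig = BootstrapConfig()
) -> tuple[float, float]:
    """Vectorized percentile-bootstrap CI for the decay half-life.

    Resamples (age, density) pairs with replacement and recomputes the
    log-linear slope for every resample in one array pass, which keeps the
    paper-scale resample counts affordable.
    """
    age, density = _paired_finite(age, density)
    if np.any(density <= 0):
        raise ValueError("densities must be positive for the log-linear fit")
    n = age.size
    logd = np.log(density)
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, n, size=(config.n_resamples, n))
    a = age[idx]
    d = logd[idx]
    a_c = a - a.mean(axis=1, keepdims=True)
    d_c = d - d.mean(axis=1, keepdims=True)
    denom = np.sum(a_c**2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.sum(a_c * d_c, axis=1) / denom
        half_lives = np.where(slopes < 0, np.log(2.0) / -slopes, np.nan)
    failures = np.count_nonzero(~np.isfinite(half_lives))
    if failures > 0.01 * config.n_resamples:
        raise RuntimeError(
            f"decay fit failed on {failures}/{config.n_resamples} resamples"
        )
    alpha = 1.0 - config.confidence
    lo, hi = np.nanpercentile(half_lives, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def welch_ttest(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t-test; returns (t, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    res = sps.ttest_ind(a[np.isfinite(a)], b[np.isfinite(b)], equal_var=False)
    return float(res.statistic), float(res.pvalue)


def correlation_matrix(table: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Square matrix with Pearson R above the diagonal and p below.

    Layout mirrors the usual supplementary correlation matrices: entry (i, j)
    with i < j holds R, entry (j, i) the corresponding p-value, and the
    diagonal is 1.  Pairwise deletion sets the n of each cell independently.
    """
    cols = list(columns) if columns is not None else list(table.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            if i < j:
                res = pearson_with_p(table[ci], table[cj])
                out.iloc[i, j] = res.r
                out.iloc[j, i] = res.p
    return out


def write_correlation_matrix(table: pd.DataFrame, path, columns=None, header_lines=()) -> None:
    """Write the R-above / p-below correlation matrix as CSV."""
    mat = correlation_matrix(table, columns)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# Pearson R above the diagonal, two-sided p below\n")
        for line in header_lines:
            fh.write(f"# {line}\n")
        mat.to_csv(fh, float_format="%.6g")
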