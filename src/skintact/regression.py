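"""Multiple linear regression with per-predictor t-statistics, Johnson
relative weights for correlated predictors, and the interaction model for
Meissner-corpuscle density x hydration.

Johnson's relative weights decompose the regression R^2 into non-negative
per-predictor contributions even when predictors are correlated: the
standardized predictor matrix is approximated by its closest orthogonal
counterpart Z (via the symmetric square root of the predictor correlation
matrix, Lambda = V Delta V'), y is regressed on Z, and each predictor's
weight is the squared-loading-weighted sum of the squared orthogonal
coefficients, epsilon_j = sum_k lambda_jk^2 beta_k^2.  The weights sum to
R^2 exactly and reduce to squared zero-order correlations when the
predictors are mutually orthogonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .stats_core import zscore

__all__ = [
    "OLSResult",
    "RelativeWeightsResult",
    "ols_fit",
    "johnson_relative_weights",
    "interaction_model",
    "per_sample_regressions",
]


@dataclass
class OLSResult:
    coefficients: pd.Series   # includes "const"
    r_squared: float
    t_values: pd.Series
    p_values: pd.Series
    df_resid: int
    n: int

    def summary_row(self, predictors=None) -> dict:
        """Flat dict shaped like one row of a regression report table."""
        preds = predictors if predictors is not None else [
            c for c in self.coefficients.index if c != "const"
        ]
        row: dict = {"R2": self.r_squared, "df": self.df_resid}
        for pname in preds:
            row[f"t_{pname}"] = self.t_values[pname]
            row[f"p_{pname}"] = self.p_values[pname]
        return row


def _design(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"x{i + 1}" for i in range(X.shape[1])]
    return X.astype(float)


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy()
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        # name the first column that is linearly dependent on its predecessors
        for j in range(1, mat.shape[1] + 1):
            if np.linalg.matrix_rank(mat[:, :j]) < j:
                raise ValueError(
                    f"rank-deficient design: column {X.columns[j - 1]!r} is "
                    "collinear with the preceding columns"
                )
        raise ValueError("rank-deficient design matrix")


def ols_fit(X, y) -> OLSResult:
    """Least-squares fit with intercept; reports R^2 and per-coefficient
    two-sided t-tests."""
    X = _design(X)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    X, y = X.loc[keep], y[keep]
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more observations than predictors plus intercept")
    _check_rank(X)
    model = sm.OLS(y, sm.add_constant(X, prepend=True)).fit()
    return OLSResult(
        coefficients=model.params,
        r_squared=float(model.rsquared),
        t_values=model.tvalues,
        p_values=model.pvalues,
        df_resid=int(model.df_resid),
        n=n,
    )


@dataclass
class RelativeWeightsResult:
    raw_weights: pd.Series    # epsilon_j, variance units; sums to R^2
    rescaled_pct: pd.Series   # percent of R^2; sums to 100
    r_squared: float


def johnson_relative_weights(X, y, condition_limit: float = 1e8) -> RelativeWeightsResult:
    """Johnson's relative weights of standardized predictors for y.

    Predictors and outcome are standardized internally, so the weights are
    invariant to affine rescaling of any predictor.
    """
    X = _design(X)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(y) & np.isfinite(X.to_numpy()).all(axis=1)
    X, y = X.loc[keep], y[keep]
    _check_rank(X)
    Z = np.column_stack([zscore(X[c].to_numpy()) for c in X.columns])
    yz = zscore(y)
    rxx = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(rxx)
    if eigval.min() <= 0 or eigval.max() / eigval.min() > condition_limit:
        raise ValueError("predictor correlation matrix is near-singular")
    lam = eigvec @ np.diag(np.sqrt(eigval)) @ eigvec.T     # symmetric square root
    r_xy = Z.T @ yz / (len(yz) - 1)
    beta = np.linalg.solve(lam, r_xy)                      # coefficients on orthogonal Z
    eps = (lam**2) @ (beta**2)
    r2 = float(eps.sum())
    raw = pd.Series(eps, index=X.columns)
    return RelativeWeightsResult(
        raw_weights=raw,
        rescaled_pct=100.0 * raw / r2,
        r_squared=r2,
    )


def interaction_model(x1, x2, y, covariates: pd.DataFrame | None = None) -> dict:
    """Fit y on x1, x2, their product (centered before multiplying) and any
    covariates; report the interaction term and the R^2 gain.

    Returns a dict with the full OLSResult (``with_interaction``), the
    no-interaction OLSResult (``main_effects``), the interaction
    coefficient, its t and p, and ``delta_r2``.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    x1c = x1 - np.nanmean(x1)
    x2c = x2 - np.nanmean(x2)
    main = pd.DataFrame({"x1": x1c, "x2": x2c})
    if covariates is not None:
        cov = _design(covariates).reset_index(drop=True)
        main = pd.concat([main, cov], axis=1)
    full = main.copy()
    full["x1:x2"] = x1c * x2c

    fit_main = ols_fit(main, y)
    fit_full = ols_fit(full, y)
    return {
        "main_effects": fit_main,
        "with_interaction": fit_full,
        "interaction_coef": float(fit_full.coefficients["x1:x2"]),
        "interaction_t": float(fit_full.t_values["x1:x2"]),
        "interaction_p": float(fit_full.p_values["x1:x2"]),
        "delta_r2": float(fit_full.r_squared - fit_main.r_squared),
    }


def per_sample_regressions(
    mu_table: pd.DataFrame, predictors: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample OLS + relative weights over a table of friction columns.

    One row per sample column: total R^2 and the rescaled percent weight of
    each predictor, mirroring a per-sample relative-importance figure.
    """
    rows = []
    for col in mu_table.columns:
        y = mu_table[col].to_numpy()
        fit = ols_fit(predictors, y)
        rw = johnson_relative_weights(predictors, y)
        row = {"sample": col, "R2": fit.r_squared}
        for pname in predictors.columns:
            row[f"weight_pct_{pname}"] = rw.rescaled_pct[pname]
        rows.append(row)
    return pd.DataFrame(rows)
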