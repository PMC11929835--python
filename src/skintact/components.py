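"""Principal components with varimax rotation, sampling-adequacy
diagnostics, Bartlett factor scores, and the composite-outcome rule.

The PCA operates on the correlation matrix (the variables have heterogeneous
units), retains components by the Kaiser criterion (eigenvalue > 1), and
rotates the retained loadings with Kaiser-normalized varimax.  Rotation is
orthogonal, so communalities (row sums of squared loadings) are preserved.
Observation scores use Bartlett's weighted-least-squares method.

The composite outcomes follow the loading-threshold rule: per-participant
mean friction over the six rough plastic samples (mu_rough), mean friction
over the four pillar samples with aspect ratio > 1 (mu_fibril), and the
perception sensitivity S_perc = mean of the z-scored pillar-detection rate
and the negated z-scored two-point threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats_core import zscore
from .surface_models import FIBRIL_SAMPLES, ROUGH_SAMPLES

__all__ = [
    "FactorAnalysisResult",
    "CompositeOutcomes",
    "kmo_score",
    "bartlett_sphericity",
    "varimax",
    "pca_varimax",
    "build_composites",
]


def _correlation(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.nonzero(sd == 0)[0]
        raise ValueError(f"zero-variance column(s) at positions {bad.tolist()}")
    return np.corrcoef(X, rowvar=False)


def _as_matrix(X) -> tuple[np.ndarray, list]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"v{i}" for i in range(X.shape[1])]


def kmo_score(X) -> float:
    """Overall Kaiser-Meyer-Olkin measure of sampling adequacy, in [0, 1].

    KMO = sum of squared off-diagonal correlations divided by that sum plus
    the sum of squared off-diagonal anti-image partial correlations.  Values
    near 1 mean the partial correlations are small and the variables share
    common factors.
    """
    X, _ = _as_matrix(X)
    if X.shape[1] < 3:
        raise ValueError("KMO needs at least 3 variables")
    corr = _correlation(X)
    try:
        inv = np.linalg.inv(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular correlation matrix") from err
    d = np.sqrt(np.diag(inv))
    partial = -inv / np.outer(d, d)
    off = ~np.eye(corr.shape[0], dtype=bool)
    r2 = np.sum(corr[off] ** 2)
    q2 = np.sum(partial[off] ** 2)
    return float(r2 / (r2 + q2))


def bartlett_sphericity(X) -> tuple[float, int, float]:
    """Bartlett's test that the correlation matrix is the identity.

    chi2 = -(n - 1 - (2p + 5)/6) * ln det(R), df = p(p-1)/2; the p-value is
    the upper chi-square tail.
    """
    from scipy import stats as sps

    X, _ = _as_matrix(X)
    n, p = X.shape
    if n <= p:
        raise ValueError("Bartlett sphericity needs more observations than variables")
    corr = _correlation(X)
    sign, logdet = np.linalg.slogdet(corr)
    if sign <= 0:
        raise ValueError("correlation matrix must be positive definite")
    chi2 = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    pval = float(sps.chi2.sf(chi2, df))
    return float(chi2), int(df), pval


def varimax(
    loadings: np.ndarray,
    kaiser_normalize: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix; returns (rotated, rotation).

    Classic SVD-based iteration maximizing the variance of squared loadings
    per column.  With Kaiser normalization the rows are scaled to unit
    communality during rotation and scaled back afterwards.  The rotation
    matrix is orthogonal, so ``rotated = loadings @ rotation`` and
    communalities are preserved.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, m = L.shape
    if m < 2:
        return L, np.eye(m)
    comm = np.sqrt(np.sum(L**2, axis=1))
    if kaiser_normalize:
        scale = np.where(comm > 0, comm, 1.0)
        L = L / scale[:, None]
    R = np.eye(m)
    variance = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag(np.sum(Lr**2, axis=0)) / p)
        )
        R = u @ vt
        new_variance = np.sum(s)
        if new_variance < variance * (1.0 + tol):
            break
        variance = new_variance
    rotated = L @ R
    if kaiser_normalize:
        rotated = rotated * scale[:, None]
    return rotated, R


@dataclass
class FactorAnalysisResult:
    eigenvalues: np.ndarray
    n_components: int
    loadings: pd.DataFrame            # unrotated, variables x components
    rotated_loadings: pd.DataFrame    # varimax-rotated, variables x components
    variance_explained_pct: pd.Series # per rotated component
    cumulative_variance_pct: float
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float
    scores: pd.DataFrame              # Bartlett WLS scores, observations x components

    @property
    def communalities(self) -> pd.Series:
        return (self.rotated_loadings**2).sum(axis=1)


def pca_varimax(X, n_components: int | None = None) -> FactorAnalysisResult:
    """Correlation-matrix PCA with Kaiser retention and varimax rotation.

    Components with eigenvalue > 1 are retained unless ``n_components``
    overrides the Kaiser criterion.  After rotation each component is
    sign-fixed so its largest-|loading| entry is positive, and components
    are ordered by explained variance.  Scores are Bartlett's weighted-
    least-squares estimates computed from the standardized data.
    """
    Xmat, names = _as_matrix(X)
    index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(Xmat.shape[0])
    n, p = Xmat.shape
    corr = _correlation(Xmat)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if n_components is None:
        n_components = max(1, int(np.sum(eigval > 1.0)))
    L = eigvec[:, :n_components] * np.sqrt(eigval[:n_components])

    rotated, _ = varimax(L)
    # sign convention: largest-|loading| entry of each component positive
    for j in range(rotated.shape[1]):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            rotated[:, j] = -rotated[:, j]
    # order rotated components by explained variance
    ssl = np.sum(rotated**2, axis=0)
    comp_order = np.argsort(ssl)[::-1]
    rotated = rotated[:, comp_order]
    ssl = ssl[comp_order]

    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    var_pct = pd.Series(100.0 * ssl / p, index=comp_names)

    # Bartlett weighted-least-squares scores from the rotated solution
    Z = np.column_stack([zscore(Xmat[:, j]) for j in range(p)])
    psi = np.clip(1.0 - np.sum(rotated**2, axis=1), 1e-8, None)
    Lw = rotated / psi[:, None]
    scores = Z @ Lw @ np.linalg.inv(rotated.T @ Lw)

    chi2, df, pval = bartlett_sphericity(Xmat)
    return FactorAnalysisResult(
        eigenvalues=eigval,
        n_components=n_components,
        loadings=pd.DataFrame(L, index=names, columns=comp_names),
        rotated_loadings=pd.DataFrame(rotated, index=names, columns=comp_names),
        variance_explained_pct=var_pct,
        cumulative_variance_pct=float(var_pct.sum()),
        kmo=kmo_score(Xmat),
        bartlett_chi2=chi2,
        bartlett_df=df,
        bartlett_p=pval,
        scores=pd.DataFrame(scores, index=index, columns=comp_names),
    )


@dataclass
class CompositeOutcomes:
    """Per-participant composite outcomes (rows indexed by participant)."""

    table: pd.DataFrame  # columns: mu_rough, mu_fibril, s_perc

    @property
    def mu_rough(self) -> pd.Series:
        return self.table["mu_rough"]

    @property
    def mu_fibril(self) -> pd.Series:
        return self.table["mu_fibril"]

    @property
    def s_perc(self) -> pd.Series:
        return self.table["s_perc"]


def build_composites(
    mu_table: pd.DataFrame,
    pillar_perception: pd.Series,
    two_point: pd.Series,
    loadings: pd.DataFrame | None = None,
    loading_threshold: float = 0.75,
) -> CompositeOutcomes:
    """Composite outcomes from friction and perception measures.

    By default mu_rough averages the six rough-sample columns and mu_fibril
    the four aspect-ratio > 1 pillar columns (the aspect-ratio-1 samples
    100/100 and 150/150 belong to neither composite).  When a rotated
    loading matrix is supplied, group membership is instead derived from it:
    a friction column joins the composite of the component on which it loads
    above ``loading_threshold``.

    S_perc is the mean of the z-scored pillar-perception rate and the
    negated z-scored two-point distance, so it is invariant to the units of
    the two-point distances and has cohort mean ~ 0.
    """
    if loadings is not None:
        rough_cols: list = []
        fibril_cols: list = []
        # derive groups: a column joins the composite of the component whose
        # strongest loader is a rough sample (else the fibrillar composite)
        comp_of = loadings.abs().idxmax(axis=1)
        for col in mu_table.columns:
            if col not in loadings.index:
                continue
            comp = comp_of[col]
            if abs(loadings.loc[col, comp]) < loading_threshold:
                continue
            top = loadings[comp].abs().idxmax()
            (rough_cols if top in ROUGH_SAMPLES else fibril_cols).append(col)
    else:
        rough_cols = list(ROUGH_SAMPLES)
        fibril_cols = list(FIBRIL_SAMPLES)

    missing = (set(rough_cols) | set(fibril_cols)) - set(mu_table.columns)
    if missing:
        raise ValueError(f"mu table lacks sample column(s): {sorted(missing)}")

    idx = mu_table.index
    pillar = pillar_perception.reindex(idx)
    tp = two_point.reindex(idx)
    s_perc = (zscore(pillar.to_numpy()) - zscore(tp.to_numpy())) / 2.0
    table = pd.DataFrame(
        {
            "mu_rough": mu_table[rough_cols].mean(axis=1),
            "mu_fibril": mu_table[fibril_cols].mean(axis=1),
            "s_perc": s_perc,
        },
        index=idx,
    )
    return CompositeOutcomes(table)
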