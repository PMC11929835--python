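"""The perception arm: triplet roughness-ranking design and scoring, Weibull
psychometric fitting with the just-noticeable difference (JND), two-point
discrimination scoring, and pillar-detection rates.

The psychometric model for two-alternative roughness comparisons is

    p(x) = 1 - 0.5 * exp(-(k*x)^d)

where x is the relative difference in RMS curvature between the two samples
of a pair.  The curve starts at chance (0.5) for x = 0 and approaches 1 for
large differences; the JND is the x at which it crosses 0.75, analytically
(ln 2)^(1/d) / k.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "TripletDesign",
    "WeibullFit",
    "TwoPointRecord",
    "TWO_POINT_DISTANCES_MM",
    "relative_difference",
    "build_triplet_design",
    "pairwise_outcomes",
    "aggregate_pairwise",
    "weibull_probability",
    "weibull_jnd",
    "fit_weibull",
    "two_point_threshold",
    "detection_probability",
]

#: Distances probed in the first pass of the two-point protocol, mm.
TWO_POINT_DISTANCES_MM = (0.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0)

#: Extra distance probed in the confirmation pass, mm.
TWO_POINT_RETEST_MM = 1.0


def relative_difference(c1: float, c2: float, convention: str = "mean") -> float:
    """Relative difference between two positive quantities.

    ``mean`` (default): |c1 - c2| / ((c1 + c2)/2); ``smaller``: / min(c1,c2);
    ``larger``: / max(c1,c2).  The convention is configurable because
    psychophysical Weber fractions are quoted under all three in the
    literature.
    """
    if c1 <= 0 or c2 <= 0:
        raise ValueError("relative difference needs positive inputs")
    diff = abs(c1 - c2)
    if convention == "mean":
        return diff / ((c1 + c2) / 2.0)
    if convention == "smaller":
        return diff / min(c1, c2)
    if convention == "larger":
        return diff / max(c1, c2)
    raise ValueError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class TripletDesign:
    """Ten ordered triples over six sample labels, each label covered 5 times."""

    triplets: tuple[tuple[str, str, str], ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.triplets) != 10:
            raise ValueError("a triplet design holds exactly 10 triplets")
        counts = {lab: 0 for lab in self.labels}
        for tri in self.triplets:
            for lab in tri:
                counts[lab] += 1
        if any(c != 5 for c in counts.values()):
            raise ValueError("each label must appear exactly 5 times")

    def within_pairs(self) -> list[tuple[str, str]]:
        """All 30 within-triplet pair slots (3 per triplet), in design order."""
        pairs = []
        for tri in self.triplets:
            pairs.extend(itertools.combinations(tri, 2))
        return pairs

    def pair_table(
        self, curvature_by_label: Mapping[str, float], convention: str = "mean"
    ) -> pd.DataFrame:
        """One row per pair slot with the pair's relative curvature difference."""
        rows = []
        for a, b in self.within_pairs():
            if a not in curvature_by_label or b not in curvature_by_label:
                raise KeyError(f"unknown sample id in pair ({a}, {b})")
            rows.append(
                {
                    "pair": f"{a}-{b}",
                    "rougher": a if curvature_by_label[a] >= curvature_by_label[b] else b,
                    "rel_diff": relative_difference(
                        curvature_by_label[a], curvature_by_label[b], convention
                    ),
                }
            )
        return pd.DataFrame(rows)


def build_triplet_design(labels: Sequence[str], seed: int = 0) -> TripletDesign:
    """Find 10 of the 20 possible triples so each label appears exactly 5 times.

    The search over subsets is exhaustive with count pruning; the first valid
    cover (in lexicographic order) is used and its triplet order is then
    shuffled under ``seed`` to randomize presentation per participant.
    """
    labels = tuple(labels)
    if len(labels) != 6:
        raise ValueError("the triplet design is defined for exactly 6 samples")
    triples = list(itertools.combinations(labels, 3))

    target = {lab: 5 for lab in labels}

    def search(start: int, chosen: list, counts: dict) -> list | None:
        if len(chosen) == 10:
            return list(chosen)
        # prune: remaining slots cannot overfill any label
        if any(c > 5 for c in counts.values()):
            return None
        for i in range(start, len(triples)):
            tri = triples[i]
            if any(counts[lab] + 1 > target[lab] for lab in tri):
                continue
            for lab in tri:
                counts[lab] += 1
            chosen.append(tri)
            found = search(i + 1, chosen, counts)
            if found is not None:
                return found
            chosen.pop()
            for lab in tri:
                counts[lab] -= 1
        return None

    chosen = search(0, [], {lab: 0 for lab in labels})
    if chosen is None:  # pragma: no cover - a valid cover always exists
        raise RuntimeError("no valid triplet cover found")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chosen))
    return TripletDesign(tuple(chosen[i] for i in order), labels)


def pairwise_outcomes(
    rankings: Iterable[tuple],
    curvature_by_label: Mapping[str, float],
) -> pd.DataFrame:
    """Score triplet rankings as pairwise roughness comparisons.

    ``rankings`` yields ``(participant, ordering)`` where ``ordering`` is the
    participant's total order of one triplet from least rough to roughest.
    For every within-triplet pair, success = 1 iff the member with the higher
    RMS curvature was ranked rougher.  Ties in curvature count as success.
    """
    rows = []
    for participant, ordering in rankings:
        ordering = tuple(ordering)
        if len(ordering) != 3 or len(set(ordering)) != 3:
            raise ValueError(f"incomplete ranking {ordering!r}")
        for a, b in itertools.combinations(sorted(ordering), 2):
            ca, cb = curvature_by_label[a], curvature_by_label[b]
            rougher_truth = a if ca >= cb else b
            rougher_judged = a if ordering.index(a) > ordering.index(b) else b
            rows.append(
                {
                    "participant": participant,
                    "pair": f"{min(a, b)}-{max(a, b)}",
                    "rel_diff": relative_difference(ca, cb) if ca != cb else 0.0,
                    "success": int(rougher_judged == rougher_truth),
                }
            )
    return pd.DataFrame(rows)


def aggregate_pairwise(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Pool binary outcomes into (pair, rel_diff, n_success, n_trials) rows."""
    grouped = (
        outcomes.groupby(["pair", "rel_diff"], as_index=False)["success"]
        .agg(n_success="sum", n_trials="count")
    )
    return grouped.sort_values("rel_diff", ignore_index=True)


# ---------------------------------------------------------------------------
# Weibull psychometric function


def weibull_probability(x, k: float, d: float):
    """p(x) = 1 - 0.5*exp(-(k*x)^d); equals 0.5 at x = 0 for any k, d > 0."""
    if k <= 0 or d <= 0:
        raise ValueError("Weibull parameters k and d must be positive")
    x = np.asarray(x, dtype=float)
    out = 1.0 - 0.5 * np.exp(-((k * x) ** d))
    return float(out) if out.ndim == 0 else out


def weibull_jnd(k: float, d: float) -> float:
    """x at which the psychometric curve crosses 0.75: (ln 2)^(1/d) / k."""
    return math.log(2.0) ** (1.0 / d) / k


@dataclass(frozen=True)
class WeibullFit:
    k: float
    d: float
    jnd: float
    n_obs: int
    log_likelihood: float
    boundary: bool = False

    def probability(self, x):
        return weibull_probability(x, self.k, self.d)


def fit_weibull(
    x: Sequence[float],
    n_success: Sequence[int],
    n_trials: Sequence[int],
) -> WeibullFit:
    """Binomial maximum-likelihood fit of the Weibull psychometric function.

    Optimized over (log k, log d) with Nelder-Mead from several starts; the
    JND is then computed analytically.  All-success or all-failure data push
    k to a boundary; the fit is still returned with ``boundary=True``.
    """
    x = np.asarray(x, dtype=float)
    succ = np.asarray(n_success, dtype=float)
    trials = np.asarray(n_trials, dtype=float)
    if not (x.shape == succ.shape == trials.shape):
        raise ValueError("x, n_success, n_trials must have equal length")
    if np.unique(x[x > 0]).size < 2:
        raise ValueError("need at least 2 distinct positive stimulus levels")
    if np.any(succ > trials) or np.any(succ < 0) or np.any(trials <= 0):
        raise ValueError("invalid binomial counts")

    tiny = 1e-12

    def nll(params):
        k, d = np.exp(params)
        p = np.clip(1.0 - 0.5 * np.exp(-((k * x) ** d)), tiny, 1.0 - tiny)
        return -np.sum(succ * np.log(p) + (trials - succ) * np.log(1.0 - p))

    starts = [
        (math.log(1.0 / max(np.median(x[x > 0]), tiny)), math.log(2.0)),
        (math.log(5.0), math.log(2.0)),
        (math.log(1.0), math.log(1.0)),
        (math.log(20.0), math.log(3.0)),
    ]
    best = None
    for s in starts:
        res = optimize.minimize(nll, s, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    k, d = np.exp(best.x)
    boundary = bool(
        np.all(succ == trials) or np.all(succ == 0) or k > 1e6 or k < 1e-6
    )
    return WeibullFit(
        k=float(k),
        d=float(d),
        jnd=float(weibull_jnd(k, d)),
        n_obs=int(trials.sum()),
        log_likelihood=float(-best.fun),
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# Two-point discrimination


@dataclass(frozen=True)
class TwoPointRecord:
    participant: object
    threshold_mm: float  # inf when never perceived as two points

    @property
    def resolved(self) -> bool:
        return math.isfinite(self.threshold_mm)


def two_point_threshold(
    perceives_two: Mapping[float, bool] | Callable[[float], bool],
    participant=None,
) -> TwoPointRecord:
    """Walk the two-point protocol and record the final threshold.

    First pass: the distances 0, 2, 3, ..., 8 mm are probed (order is
    irrelevant for scoring) and the minimal distance perceived as two points
    is found.  Confirmation pass: that minimum m is retested together with
    1 mm; if 1 mm is perceived as two the threshold is 1 mm, else if m is
    confirmed it is m.  On a contradictory retest (m no longer two points)
    the retest wins and the next larger first-pass two-point distance is
    recorded (infinity if none).
    """
    if callable(perceives_two):
        probe = perceives_two
    else:
        responses = dict(perceives_two)
        missing = set(TWO_POINT_DISTANCES_MM) - set(responses)
        if missing:
            raise ValueError(f"responses missing for distances {sorted(missing)}")

        def probe(dist: float) -> bool:
            return bool(responses[dist])

    first_pass = {dist: probe(dist) for dist in TWO_POINT_DISTANCES_MM}
    two_dists = sorted(d for d, two in first_pass.items() if two and d > 0)
    if not two_dists:
        return TwoPointRecord(participant, float("inf"))
    m = two_dists[0]
    if probe(TWO_POINT_RETEST_MM):
        return TwoPointRecord(participant, TWO_POINT_RETEST_MM)
    if probe(m):
        return TwoPointRecord(participant, m)
    larger = [d for d in two_dists if d > m]
    return TwoPointRecord(participant, larger[0] if larger else float("inf"))


# ---------------------------------------------------------------------------
# Pillar detection


def detection_probability(
    detections: pd.DataFrame, confidence: float = 0.95
) -> pd.DataFrame:
    """Per-sample detection rate with exact (Clopper-Pearson) binomial CI.

    ``detections`` is a participants x samples boolean table; NaNs are
    treated as missing trials.  The per-participant mean rate (over samples)
    feeds the perception composite.
    """
    rows = []
    for col in detections.columns:
        series = detections[col].dropna()
        n = int(series.size)
        if n == 0:
            raise ValueError(f"empty detection column {col!r}")
        successes = int(series.astype(bool).sum())
        ci = sps.binomtest(successes, n).proportion_ci(
            confidence_level=confidence, method="exact"
        )
        rows.append(
            {
                "sample": col,
                "rate": successes / n,
                "n": n,
                "ci_low": float(ci.low),
                "ci_high": float(ci.high),
            }
        )
    return pd.DataFrame(rows)
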