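"""Per-trial friction summaries from raw 3-axis force traces.

A trial records normal force FN and the two tangential components (Fx, Fy)
at 50 Hz while the finger circles over the sample.  Touch is gated by the
rule that FN must exceed four times the noise of the unloaded sensor; the
friction coefficient is the per-sample ratio FF/FN with FF = sqrt(Fx^2+Fy^2),
summarized as its median over the touch samples.  Circling is quantified by
unwrapping the phase of the tangential force vector.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ForceTrace",
    "FrictionSummary",
    "MissingTrialError",
    "TOUCH_NOISE_FACTOR",
    "FN_GUIDANCE_RANGE",
    "touch_mask",
    "estimate_noise",
    "friction_coefficient",
    "cycle_rate",
    "read_force_trace",
    "write_force_trace",
]

#: Touch is assumed where FN exceeds this multiple of the unloaded-sensor noise.
TOUCH_NOISE_FACTOR = 4.0

#: Normal-force window the investigator guides the participant into, N.
#: Samples outside are flagged, never excluded.
FN_GUIDANCE_RANGE = (0.8, 1.2)

#: Leading window used to estimate the unloaded-sensor noise, s.
NOISE_WINDOW_S = 1.0


class MissingTrialError(RuntimeError):
    """Raised when a trace contains no touch samples (trial unusable)."""


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled force time series (t in s, forces in N)."""

    t: np.ndarray
    fx: np.ndarray
    fy: np.ndarray
    fn: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("t", "fx", "fy", "fn"):
            arrays[name] = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arrays[name])
        lengths = {a.size for a in arrays.values()}
        if len(lengths) != 1:
            raise ValueError("t, Fx, Fy, FN must have equal length")
        if arrays["t"].size < 2:
            raise ValueError("trace must contain at least 2 samples")
        dt = np.diff(arrays["t"])
        if np.any(dt <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if np.max(dt) - np.min(dt) > 0.01 * np.mean(dt):
            raise ValueError("sampling interval must be constant within 1%")

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.t)))

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.dt


@dataclass(frozen=True)
class FrictionSummary:
    mu_median: float
    touch_fraction: float
    touch_duration: float
    n_cycles: int
    cycle_rate: float
    fn_in_range_fraction: float
    noise_estimate: float

    def as_dict(self) -> dict:
        return asdict(self)


def estimate_noise(trace: ForceTrace, window_s: float = NOISE_WINDOW_S) -> float:
    """SD of FN over the leading idle window (unloaded-sensor noise), N."""
    n = max(2, int(round(window_s * trace.sampling_rate)))
    return float(np.std(trace.fn[:n]))


def touch_mask(trace: ForceTrace, noise_level: float | None = None) -> np.ndarray:
    """Boolean mask, true exactly where FN > 4 * noise_level.

    When ``noise_level`` is not supplied it is estimated as the SD of FN over
    the first second of the trace, which the acquisition protocol leaves
    idle.
    """
    if noise_level is None:
        noise_level = estimate_noise(trace)
    if noise_level < 0:
        raise ValueError("noise level must be non-negative")
    return trace.fn > TOUCH_NOISE_FACTOR * noise_level


def cycle_rate(trace: ForceTrace, mask: np.ndarray) -> tuple[int, float]:
    """Circles counted by phase unwrapping of (Fx, Fy) over touch samples.

    Returns ``(n_cycles, rate)`` where the rate is cycles per second of touch
    duration.  Degenerate tangential forces (|F| ~ 0 throughout touch) give
    ``(0, nan)``.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < trace.sampling_rate:  # need >= 1 s of touch
        raise ValueError("cycle counting needs at least 1 s of touch")
    fx = trace.fx[mask]
    fy = trace.fy[mask]
    magnitude = np.hypot(fx, fy)
    if np.median(magnitude) <= 10 * np.finfo(float).eps:
        return 0, float("nan")
    phase = np.unwrap(np.arctan2(fy, fx))
    cycles = abs(phase[-1] - phase[0]) / (2.0 * math.pi)
    touch_duration = mask.sum() * trace.dt
    return int(round(cycles)), float(cycles / touch_duration)


def friction_coefficient(
    trace: ForceTrace, noise_level: float | None = None
) -> FrictionSummary:
    """The per-trial friction summary.

    Per-sample mu = sqrt(Fx^2 + Fy^2) / FN is evaluated on touch samples
    only; samples at or below the touch threshold are excluded entirely.
    ``mu_median`` is the median of that series.  The fraction of touch
    samples with FN inside the 0.8-1.2 N guidance window is reported as a
    flag, not used for exclusion.
    """
    if noise_level is None:
        noise_level = estimate_noise(trace)
    mask = touch_mask(trace, noise_level)
    n_touch = int(mask.sum())
    if n_touch == 0:
        raise MissingTrialError("no touch samples above the 4x-noise threshold")
    fn = trace.fn[mask]
    ff = np.hypot(trace.fx[mask], trace.fy[mask])
    mu = ff / fn
    try:
        n_cycles, rate = cycle_rate(trace, mask)
    except ValueError:
        n_cycles, rate = 0, float("nan")
    lo, hi = FN_GUIDANCE_RANGE
    return FrictionSummary(
        mu_median=float(np.median(mu)),
        touch_fraction=n_touch / trace.t.size,
        touch_duration=n_touch * trace.dt,
        n_cycles=n_cycles,
        cycle_rate=rate,
        fn_in_range_fraction=float(np.mean((fn >= lo) & (fn <= hi))),
        noise_estimate=float(noise_level),
    )


def read_force_trace(path) -> ForceTrace:
    """Read a trace CSV with columns t_s, Fx_N, Fy_N, FN_N."""
    df = pd.read_csv(path, comment="#")
    missing = {"t_s", "Fx_N", "Fy_N", "FN_N"} - set(df.columns)
    if missing:
        raise ValueError(f"trace file lacks columns: {sorted(missing)}")
    return ForceTrace(
        df["t_s"].to_numpy(), df["Fx_N"].to_numpy(),
        df["Fy_N"].to_numpy(), df["FN_N"].to_numpy(),
    )


def write_force_trace(trace: ForceTrace, path) -> None:
    pd.DataFrame(
        {"t_s": trace.t, "Fx_N": trace.fx, "Fy_N": trace.fy, "FN_N": trace.fn}
    ).to_csv(path, index=False)
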