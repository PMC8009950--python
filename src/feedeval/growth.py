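"""Growth metrics and allometric power-curve fitting for juvenile weight series.

Juveniles are weighed in replicate groups every few days; the mean individual
body weight BW(t) (mg) against age t (days after hatching, DAH) is modelled
by a power law BW = a * t**b, fitted by ordinary least squares on the
log-log scale — the convention of spreadsheet "power trendlines", which the
fitted r-squared also follows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class FitError(ValueError):
    """Raised when a power fit is impossible or degenerate."""


@dataclass
class GrowthSeries:
    """Body-weight check points: per-time replicate-group mean weights (mg)."""

    time: np.ndarray  # days after hatching, strictly increasing, >= 0
    group_weights: np.ndarray  # shape (n_times, n_groups), mg per individual
    ci95: np.ndarray | None = None  # printed half-widths, if from a table

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.group_weights = np.atleast_2d(np.asarray(self.group_weights, dtype=float))
        if self.group_weights.shape[0] != self.time.size:
            self.group_weights = self.group_weights.T
        if self.group_weights.shape[0] != self.time.size:
            raise ValueError("group_weights must have one row per check point")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.time < 0):
            raise ValueError("times must be non-negative")

    @property
    def n_groups(self) -> int:
        return self.group_weights.shape[1]

    @property
    def mean_weights(self) -> np.ndarray:
        return self.group_weights.mean(axis=1)


@dataclass
class PowerFit:
    """Fitted BW = a * t**b with log-log and original-scale r-squared."""

    a: float
    b: float
    r2: float  # on (ln t, ln BW), the trendline convention; primary
    r2_original: float  # 1 - SSE/SST in original units, for reference
    n_points_used: int
    log_residuals: np.ndarray = field(repr=False, default=None)

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.a * np.asarray(t, dtype=float) ** self.b


def fit_power(series: GrowthSeries) -> PowerFit:
    """OLS power-law fit on the log-log scale.

    Points with t = 0 are excluded (log undefined); non-positive weights are
    excluded with a warning.  Requires >= 3 usable points.
    """
    t = series.time
    w = series.mean_weights
    usable = t > 0
    if np.any(usable & (w <= 0)):
        warnings.warn("non-positive weights excluded from power fit", stacklevel=2)
        usable &= w > 0
    t, w = t[usable], w[usable]
    if t.size < 3:
        raise FitError(f"need >= 3 usable points, have {t.size}")
    lx, ly = np.log(t), np.log(w)
    res = stats.linregress(lx, ly)
    a = math.exp(res.intercept)
    b = res.slope
    resid = ly - (res.intercept + b * lx)
    pred = np.exp(res.intercept + b * lx)
    sst = float(np.sum((w - w.mean()) ** 2))
    r2_orig = 1.0 - float(np.sum((w - pred) ** 2)) / sst if sst > 0 else float("nan")
    return PowerFit(
        a=a,
        b=b,
        r2=float(res.rvalue**2),
        r2_original=r2_orig,
        n_points_used=int(t.size),
        log_residuals=resid,
    )


def weight_gain_rate(initial: float, final: float) -> float:
    """Weight gain rate WGR = (final - initial)/initial * 100, percent."""
    if initial <= 0:
        raise ValueError("initial weight must be positive")
    return (final - initial) / initial * 100.0


def initial_weight_from_wgr(final: float, wgr_percent: float) -> float:
    """Back-solve the initial weight implied by a reported WGR (%)."""
    return final / (1.0 + wgr_percent / 100.0)


def specific_growth_rate(initial: float, final: float, days: float) -> float:
    """SGR = (ln final - ln initial)/days * 100, percent per day."""
    if initial <= 0 or final <= 0:
        raise ValueError("weights must be positive")
    if days <= 0:
        raise ValueError("duration must be positive")
    return (math.log(final) - math.log(initial)) / days * 100.0


@dataclass(frozen=True)
class NormalityReport:
    W: float
    p: float
    passed: bool  # p > 0.05: residuals consistent with normality


def residual_normality(fit: PowerFit, alpha: float = 0.05) -> NormalityReport:
    """Shapiro-Wilk test on the standardized log-scale fit residuals."""
    resid = np.asarray(fit.log_residuals, dtype=float)
    if resid.size < 3:
        raise FitError("need >= 3 residuals for a normality test")
    sd = resid.std(ddof=1)
    # an exact fit leaves only float rounding noise: treat as constant
    if sd <= 1e-12 * max(1.0, float(np.abs(resid).max())):
        raise FitError("constant residuals: normality test undefined")
    W, p = stats.shapiro(resid / sd)
    return NormalityReport(W=float(W), p=float(p), passed=bool(p > alpha))


def load_growth_csv(path) -> GrowthSeries:
    """Read a growth CSV with columns dah, group_id, total_weight_mg, n_individuals.

    Group totals are converted to mean individual weight at load time.
    """
    import pandas as pd

    df = pd.read_csv(path)
    df["indiv_mg"] = df["total_weight_mg"] / df["n_individuals"]
    wide = df.pivot_table(index="dah", columns="group_id", values="indiv_mg")
    return GrowthSeries(time=wide.index.to_numpy(), group_weights=wide.to_numpy())
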