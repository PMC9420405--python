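"""Reduced major axis (RMA) allometry on ordination scores.

The RMA (geometric-mean / standardized major axis) line treats x and y
symmetrically: slope = sign(r) * sd(y)/sd(x), line through the centroid.
Slope confidence intervals use the analytic method

    CI = slope * (sqrt(B + 1) -/+ sqrt(B)),   B = (1 - r^2) F(0.95; 1, n-2) / (n - 2)

by default, with a seeded BCa bootstrap as an option; intercept intervals
are bootstrapped by default (the analytic interval for the RMA intercept
is less standard).  Slope differences are tested with Clarke's statistic
on the log slopes with an effective-degrees-of-freedom correction:

    T  = |ln|b1| - ln|b2|| / sqrt(s1^2 + s2^2),       s_i^2 = (1 - r_i^2) / n_i
    df = (s1^2 + s2^2)^2 / (s1^4/(n1 - 2) + s2^4/(n2 - 2))

with a two-sided p from Student's t.  The module also measures
ontogenetic-trajectory angles: the angle from the positive first-axis
direction to the (adult centroid - juvenile centroid) vector per group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitError


@dataclass(frozen=True)
class RMAFit:
    """A fitted reduced major axis line with its sampling statistics."""

    slope: float
    intercept: float
    r: float
    n: int
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    p_r0: float
    x_label: str = "x"
    y_label: str = "y"
    mean_x: float = 0.0
    mean_y: float = 0.0
    sd_x: float = 1.0
    sd_y: float = 1.0

    @property
    def centroid(self) -> np.ndarray:
        return np.array([self.mean_x, self.mean_y])

    @property
    def direction(self) -> np.ndarray:
        """Unit vector along the line, oriented toward increasing x."""
        d = np.array([1.0, self.slope])
        return d / np.linalg.norm(d)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class SlopeComparison:
    """Clarke's test of the difference between two RMA slopes."""

    T: float
    df: float
    p: float
    fits: tuple[RMAFit, RMAFit]


@dataclass(frozen=True)
class InterceptComparison:
    overlap: bool
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]


@dataclass(frozen=True)
class TrajectoryAngle:
    """Angle (degrees in [0, 180]) from +axis-1 to the juvenile->adult centroid vector."""

    group: str
    angle_deg: float
    juvenile_centroid: tuple[float, float]
    adult_centroid: tuple[float, float]


def _rma_stat(x, y, axis=-1):
    """Vectorized (slope, intercept) of the RMA line; used by the bootstrap."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx = x.mean(axis=axis, keepdims=True)
    my = y.mean(axis=axis, keepdims=True)
    sx = x.std(axis=axis, ddof=1)
    sy = y.std(axis=axis, ddof=1)
    cov = ((x - mx) * (y - my)).sum(axis=axis) / (x.shape[axis] - 1)
    sign = np.where(cov >= 0, 1.0, -1.0)
    slope = sign * sy / np.where(sx > 0, sx, np.nan)
    intercept = np.squeeze(my, axis=axis) - slope * np.squeeze(mx, axis=axis)
    return slope, intercept


def fit_rma(
    x: Sequence[float],
    y: Sequence[float],
    *,
    x_label: str = "x",
    y_label: str = "y",
    slope_ci_method: str = "analytic",
    intercept_ci_method: str = "bootstrap",
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> RMAFit:
    """Fit a reduced major axis line to paired scores.

    ``slope_ci_method`` is ``"analytic"`` (default) or ``"bootstrap"``;
    ``intercept_ci_method`` is ``"bootstrap"`` (default, seeded BCa) or
    ``"analytic"`` (intercept interval induced by the analytic slope
    interval through the centroid).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise FitError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 3:
        raise FitError(f"RMA needs n >= 3, got {n}")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx <= 0 or sy <= 0:
        raise FitError("zero variance in x or y")

    r = float(np.corrcoef(x, y)[0, 1])
    if r == 0.0:
        warnings.warn("r is exactly 0; RMA slope sign taken as positive", stacklevel=2)
        sign = 1.0
    else:
        sign = float(np.sign(r))
    slope = sign * sy / sx
    mx, my = float(x.mean()), float(y.mean())
    intercept = my - slope * mx

    # p-value of the t-test of r = 0
    if abs(r) >= 1.0:
        p_r0 = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
        p_r0 = float(2.0 * stats.t.sf(abs(t), n - 2))

    b_term = (1.0 - r**2) * stats.f.ppf(1.0 - alpha, 1, n - 2) / (n - 2)
    lo = slope * (np.sqrt(b_term + 1.0) - np.sqrt(b_term))
    hi = slope * (np.sqrt(b_term + 1.0) + np.sqrt(b_term))
    analytic_slope_ci = (min(lo, hi), max(lo, hi))

    boot_slope_ci = boot_intercept_ci = None
    if "bootstrap" in (slope_ci_method, intercept_ci_method):
        rng = np.random.default_rng(seed)
        if slope_ci_method == "bootstrap":
            res_slope = stats.bootstrap(
                (x, y),
                lambda xs, ys, axis=-1: _rma_stat(xs, ys, axis=axis)[0],
                paired=True,
                vectorized=True,
                n_resamples=n_boot,
                confidence_level=1 - alpha,
                method="BCa",
                random_state=rng,
            )
            boot_slope_ci = (
                float(res_slope.confidence_interval.low),
                float(res_slope.confidence_interval.high),
            )
        if intercept_ci_method == "bootstrap":
            res_int = stats.bootstrap(
                (x, y),
                lambda xs, ys, axis=-1: _rma_stat(xs, ys, axis=axis)[1],
                paired=True,
                vectorized=True,
                n_resamples=n_boot,
                confidence_level=1 - alpha,
                method="BCa",
                random_state=rng,
            )
            boot_intercept_ci = (
                float(res_int.confidence_interval.low),
                float(res_int.confidence_interval.high),
            )

    if slope_ci_method == "analytic":
        slope_ci = analytic_slope_ci
    elif slope_ci_method == "bootstrap":
        slope_ci = boot_slope_ci
    else:
        raise ValueError(f"unknown slope_ci_method {slope_ci_method!r}")

    if intercept_ci_method == "bootstrap":
        intercept_ci = boot_intercept_ci
    elif intercept_ci_method == "analytic":
        cands = [my - s * mx for s in analytic_slope_ci]
        intercept_ci = (min(cands), max(cands))
    else:
        raise ValueError(f"unknown intercept_ci_method {intercept_ci_method!r}")

    return RMAFit(
        slope=float(slope),
        intercept=float(intercept),
        r=r,
        n=int(n),
        slope_ci=slope_ci,
        intercept_ci=intercept_ci,
        p_r0=p_r0,
        x_label=x_label,
        y_label=y_label,
        mean_x=mx,
        mean_y=my,
        sd_x=float(sx),
        sd_y=float(sy),
    )


def clarke_statistic(b1, r1, n1, b2, r2, n2):
    """Vectorized Clarke T, effective df and two-sided p for two RMA slopes."""
    s1 = (1.0 - np.asarray(r1, dtype=float) ** 2) / np.asarray(n1, dtype=float)
    s2 = (1.0 - np.asarray(r2, dtype=float) ** 2) / np.asarray(n2, dtype=float)
    T = np.abs(np.log(np.abs(b1)) - np.log(np.abs(b2))) / np.sqrt(s1 + s2)
    df = (s1 + s2) ** 2 / (s1**2 / (np.asarray(n1) - 2) + s2**2 / (np.asarray(n2) - 2))
    p = 2.0 * stats.t.sf(T, df)
    return T, df, p


def clarke_test(a: RMAFit, b: RMAFit) -> SlopeComparison:
    """Clarke's test for the difference between two RMA slopes.

    Compares the logs of the absolute slopes; slopes of opposite sign are
    rejected (the contrast is undefined across signs) so the caller can
    report the qualitative difference instead.
    """
    if (a.x_label, a.y_label) != (b.x_label, b.y_label):
        raise FitError(
            f"fits are on different axes: {(a.x_label, a.y_label)} vs {(b.x_label, b.y_label)}"
        )
    if a.slope * b.slope < 0:
        raise FitError(
            "slopes have opposite signs; the log-slope contrast is undefined "
            "(the trajectories differ qualitatively)"
        )
    T, df, p = clarke_statistic(a.slope, a.r, a.n, b.slope, b.r, b.n)
    return SlopeComparison(T=float(T), df=float(df), p=float(min(p, 1.0)), fits=(a, b))


def compare_intercepts(a: RMAFit, b: RMAFit) -> InterceptComparison:
    """Do the 95% intercept confidence intervals of two fits overlap?"""
    lo_a, hi_a = a.intercept_ci
    lo_b, hi_b = b.intercept_ci
    overlap = (lo_a <= hi_b) and (lo_b <= hi_a)
    return InterceptComparison(overlap=bool(overlap), ci_a=a.intercept_ci, ci_b=b.intercept_ci)


def centroid_angles(
    scores: pd.DataFrame | np.ndarray,
    groups: Sequence[str],
    stages: Sequence[str],
    *,
    juvenile_label: str = "juvenile",
    adult_label: str = "adult",
) -> dict[str, TrajectoryAngle]:
    """Per-group angle of the juvenile->adult centroid vector.

    The angle is measured from the positive first-axis direction and folded
    to [0, 180] degrees (the trajectory and its mirror about the first axis
    are reported identically, matching how such angles are usually quoted).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise FitError("scores must be an n x 2 array (first two axes)")
    arr = arr[:, :2]
    groups = np.asarray(groups)
    stages = np.asarray(stages)
    out: dict[str, TrajectoryAngle] = {}
    for g in pd.unique(groups):
        sel = groups == g
        juv = arr[sel & (stages == juvenile_label)]
        adu = arr[sel & (stages == adult_label)]
        if len(juv) == 0 or len(adu) == 0:
            raise FitError(f"group {g!r} lacks a {juvenile_label if len(juv) == 0 else adult_label} stage")
        cj = juv.mean(axis=0)
        ca = adu.mean(axis=0)
        d = ca - cj
        angle = abs(np.degrees(np.arctan2(d[1], d[0])))
        out[str(g)] = TrajectoryAngle(
            group=str(g),
            angle_deg=float(angle),
            juvenile_centroid=(float(cj[0]), float(cj[1])),
            adult_centroid=(float(ca[0]), float(ca[1])),
        )
    return out


def rma_table(fits: Mapping[str, RMAFit]) -> pd.DataFrame:
    """Slope / CI / r / n / p table, one row per fitted group."""
    rows = []
    for name, f in fits.items():
        rows.append(
            {
                "group": name,
                "slope": f.slope,
                "ci_low": f.slope_ci[0],
                "ci_high": f.slope_ci[1],
                "intercept": f.intercept,
                "intercept_ci_low": f.intercept_ci[0],
                "intercept_ci_high": f.intercept_ci[1],
                "r": f.r,
                "n": f.n,
                "p_r0": f.p_r0,
            }
        )
    return pd.DataFrame(rows)


def pairwise_slope_tests(fits: Mapping[str, RMAFit]) -> pd.DataFrame:
    """Symmetric matrix of Clarke p-values (NaN where signs differ)."""
    names = list(fits)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for i, a in enumerate(names):
        mat.loc[a, a] = 1.0
        for b in names[i + 1 :]:
            try:
                p = clarke_test(fits[a], fits[b]).p
            except FitError:
                p = np.nan
            mat.loc[a, b] = mat.loc[b, a] = p
    return mat


__all__ = [
    "RMAFit",
    "SlopeComparison",
    "InterceptComparison",
    "TrajectoryAngle",
    "fit_rma",
    "clarke_test",
    "clarke_statistic",
    "compare_intercepts",
    "centroid_angles",
    "rma_table",
    "pairwise_slope_tests",
]
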