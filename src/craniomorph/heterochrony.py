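"""Heterochrony decomposition and encephalization association statistics.

In the size-shape factor plane, the difference between a target group's
centroid and a reference ontogenetic trajectory decomposes into two
orthogonal, independently interpretable components:

* the signed displacement ALONG the reference line in its ontogenetic
  (juvenile -> adult) direction: positive values extend the ancestral
  trajectory (peramorphosis by ontogenetic scaling), negative values
  truncate it (paedomorphosis);
* the signed displacement PERPENDICULAR to the line (lateral
  transposition): a parallel trajectory starting from a different shape
  for a given size.

The module also houses the association statistics relating the shape and
size factors to body mass, endocranial volume and the encephalization
quotient EQ = ECV / (a * BM^b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .allometry import RMAFit
from .errors import FitError

SCALING_LABELS = ("paedomorphic", "peramorphic", "none")
TRANSPOSITION_LABELS = ("transposed", "on-trajectory")


@dataclass(frozen=True)
class TrajectoryDecomposition:
    """Ontogenetic-scaling / lateral-transposition split of a centroid shift."""

    reference: RMAFit
    along: float
    offset: float
    scaling_label: str
    transposition_label: str
    offset_threshold: float

    @property
    def distance(self) -> float:
        return float(np.hypot(self.along, self.offset))


def prediction_halfwidth(fit: RMAFit, along: float, alpha: float = 0.05) -> float:
    """Half-width of the reference line's prediction band, in the direction
    perpendicular to the line, at a given along-line coordinate.

    Computed from the second moments of the reference sample rotated into
    line coordinates: with perpendicular residual SD ``s_perp`` and
    along-line variance ``v_along`` (both exact functions of sd_x, sd_y, r
    for an RMA line through the centroid),

        h(t) = t_{1-alpha/2, n-2} * s_perp * sqrt(1 + 1/n + t^2 / ((n-1) v_along)).
    """
    b, sx, sy, r, n = fit.slope, fit.sd_x, fit.sd_y, fit.r, fit.n
    denom = 1.0 + b**2
    var_perp = (b**2 * sx**2 - 2.0 * b * r * sx * sy + sy**2) / denom
    var_along = (sx**2 + 2.0 * b * r * sx * sy + b**2 * sy**2) / denom
    var_perp = max(var_perp, 0.0)
    if var_along <= 0:
        raise FitError("degenerate reference sample: no variance along the line")
    s_perp = np.sqrt(var_perp * (n - 1) / max(n - 2, 1))
    width = s_perp * np.sqrt(1.0 + 1.0 / n + along**2 / ((n - 1) * var_along))
    return float(stats.t.ppf(1.0 - alpha / 2.0, max(n - 2, 1)) * width)


def decompose(
    reference: RMAFit,
    polarity: np.ndarray,
    target_centroid: np.ndarray,
    *,
    deadband: float = 0.1,
    offset_threshold: float | str = "prediction_band",
) -> TrajectoryDecomposition:
    """Decompose a target centroid against a reference ontogenetic trajectory.

    ``polarity`` is a (non-zero) vector along the reference line pointing in
    the juvenile -> adult direction; it fixes which end of the line counts
    as "beyond the adult state".  ``offset_threshold`` is either an
    absolute score-unit threshold or ``"prediction_band"`` (default): the
    95% prediction-band half-width of the reference line at the target's
    along-coordinate.
    """
    polarity = np.asarray(polarity, dtype=float)
    norm = np.linalg.norm(polarity)
    if norm <= 0 or not np.isfinite(norm):
        raise FitError("polarity must be a non-zero finite 2-vector")
    u = polarity / norm
    line_dir = reference.direction
    if abs(u[0] * line_dir[1] - u[1] * line_dir[0]) > 1e-6:
        raise FitError("polarity is not parallel to the reference line")
    n_hat = np.array([-u[1], u[0]])  # +90 degree rotation

    delta = np.asarray(target_centroid, dtype=float) - reference.centroid
    along = float(delta @ u)
    offset = float(delta @ n_hat)

    if along > deadband:
        scaling = "peramorphic"
    elif along < -deadband:
        scaling = "paedomorphic"
    else:
        scaling = "none"

    if offset_threshold == "prediction_band":
        thr = prediction_halfwidth(reference, along)
    else:
        thr = float(offset_threshold)
    transposition = "transposed" if abs(offset) > thr else "on-trajectory"

    return TrajectoryDecomposition(
        reference=reference,
        along=along,
        offset=offset,
        scaling_label=scaling,
        transposition_label=transposition,
        offset_threshold=thr,
    )


def ontogenetic_polarity(juvenile_centroid, adult_centroid, fit: RMAFit) -> np.ndarray:
    """Unit vector along ``fit``'s line pointing toward the adult state.

    The juvenile -> adult centroid vector is projected onto the line
    direction; the line direction (or its negation) is returned.
    """
    d = np.asarray(adult_centroid, dtype=float) - np.asarray(juvenile_centroid, dtype=float)
    u = fit.direction
    proj = d @ u
    if proj == 0:
        raise FitError("juvenile->adult vector is perpendicular to the line")
    return u if proj > 0 else -u


@dataclass(frozen=True)
class EncephalizationRecord:
    """Body mass, endocranial volume and the derived encephalization quotient."""

    bm_kg: np.ndarray
    ecv_cm3: np.ndarray
    eq: np.ndarray
    log_bm: np.ndarray
    log_ecv: np.ndarray
    a: float
    b: float


def compute_eq(bm_kg, ecv_cm3, a: float = 1.77, b: float = 0.76) -> EncephalizationRecord:
    """Encephalization quotient EQ = ECV / (a * BM^b).

    The constants default to the widely used primate scaling a = 1.77,
    b = 0.76 (expected brain size in cm^3 from body mass in kg); they must
    match the convention of whatever published ECV/BM estimates are fed
    in, so they are always recorded on the result.
    """
    bm = np.asarray(bm_kg, dtype=float)
    ecv = np.asarray(ecv_cm3, dtype=float)
    if (bm <= 0).any() or (ecv <= 0).any():
        raise FitError("body mass and endocranial volume must be strictly positive")
    eq = ecv / (a * bm**b)
    return EncephalizationRecord(
        bm_kg=bm, ecv_cm3=ecv, eq=eq, log_bm=np.log10(bm), log_ecv=np.log10(ecv), a=a, b=b
    )


@dataclass(frozen=True)
class AssocResult:
    """Pairwise Pearson correlations with two-sided p-values."""

    correlation_matrix: pd.DataFrame
    pvalues: pd.DataFrame
    n: int


def correlations(table: pd.DataFrame, groupby: str | None = None):
    """Pairwise Pearson correlations among the table's numeric columns.

    Complete cases only.  With ``groupby``, returns a dict of per-group
    :class:`AssocResult` (e.g. australopithecines vs fossil *Homo*).
    """
    if groupby is not None:
        return {
            str(g): correlations(sub.drop(columns=[groupby]))
            for g, sub in table.groupby(groupby, sort=False)
        }
    data = table.dropna()
    n = len(data)
    if n < 4:
        raise FitError(f"need at least 4 complete cases, got {n}")
    cols = list(data.columns)
    rmat = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pmat = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            r, p = stats.pearsonr(data[a], data[b])
            rmat.loc[a, b] = rmat.loc[b, a] = r
            pmat.loc[a, b] = pmat.loc[b, a] = p
    return AssocResult(correlation_matrix=rmat, pvalues=pmat, n=n)


@dataclass(frozen=True)
class PartialCorrelation:
    r: float
    df: int
    p: float
    n: int


def partial_correlation(x, y, control) -> PartialCorrelation:
    """First-order partial correlation of x and y controlling for one variable.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)), tested
    against zero with Student's t on n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(control, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    x, y, z = x[mask], y[mask], z[mask]
    n = x.size
    if n < 5:
        raise FitError(f"partial correlation needs n >= 5, got {n}")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        raise FitError("control variable is (near-)collinear with x or y")
    r = (r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    df = n - 3
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PartialCorrelation(r=float(r), df=int(df), p=p, n=int(n))


__all__ = [
    "TrajectoryDecomposition",
    "EncephalizationRecord",
    "AssocResult",
    "PartialCorrelation",
    "decompose",
    "ontogenetic_polarity",
    "prediction_halfwidth",
    "compute_eq",
    "correlations",
    "partial_correlation",
]
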