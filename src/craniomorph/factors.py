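"""Factor (size/shape) decomposition of the log-raw craniometric matrix.

Factors are obtained from a principal component analysis of the 6 x 6
Pearson correlation matrix of the log10 measurements: the loading matrix
is ``eigenvector * sqrt(eigenvalue)``, so each loading is the correlation
between its variable and the factor, and the communality ``h^2`` of a
variable is the row sum of squared retained loadings.  Factor scores are
standardized to unit variance.

On two-module craniometric data the first two factors separate shape from
size: one factor opposes neurocranial to splanchnocranial variables
(relative neurocranium size), the other loads all six variables positively
(overall cranial size).  The ``isometry_angle`` diagnostic quantifies this
by mapping the isometric direction — equal proportional change in every
measurement — into the factor plane and measuring its angle to each axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import NEURO_VARIABLES
from .errors import FitError
from .preprocess import LogMatrix


@dataclass
class FactorModel:
    """Correlation-matrix PCA rescaled to factor loadings."""

    eigenvalues: np.ndarray  # all 6, descending
    loadings: pd.DataFrame  # 6 x k, eigenvector * sqrt(eigenvalue)
    communalities: pd.Series  # h^2 per variable over the k retained factors
    scores: pd.DataFrame  # n x k, unit variance per factor
    pct_variance: np.ndarray  # per retained factor, 100 * eigenvalue / 6
    scoring_coefficients: pd.DataFrame = field(repr=False, default=None)  # 6 x k
    means: pd.Series = field(repr=False, default=None)
    sds: pd.Series = field(repr=False, default=None)

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.loadings.index)

    def loadings_table(self) -> pd.DataFrame:
        """Loadings with communalities, eigenvalues and % variance rows."""
        table = self.loadings.copy()
        table["h2"] = self.communalities
        return table

    def summary(self) -> dict:
        return {
            "eigenvalues": [float(e) for e in self.eigenvalues],
            "pct_variance_retained": [float(p) for p in self.pct_variance],
            "pct_variance_all": [float(100 * e / self.eigenvalues.sum()) for e in self.eigenvalues],
        }


@dataclass(frozen=True)
class IsometryAngles:
    """Angles (degrees, folded to [0, 90]) between the isometric image and each factor."""

    angle_to_factor1: float
    angle_to_factor2: float


def fit_factors(
    logm: LogMatrix,
    k: int = 2,
    neuro_variables: Sequence[str] = NEURO_VARIABLES,
) -> FactorModel:
    """Fit the factor model on a log-raw matrix, retaining ``k`` factors.

    Orientation convention: the first factor is signed so the neurocranial
    variables load positively (relatively large neurocranium scores high);
    every other factor is signed so the sum of all six loadings is
    positive (for the size factor: bigger crania score high).
    """
    n, p = logm.data.shape
    if n < p + 1:
        raise FitError(f"need more specimens than variables (+1): n={n}, p={p}")
    if not 1 <= k <= p:
        raise FitError(f"k must be in [1, {p}], got {k}")
    sds = logm.data.std(ddof=1)
    constant = sds.index[sds <= 0]
    if len(constant):
        raise FitError(f"constant column {constant[0]!r}")

    corr = logm.data.corr().to_numpy()
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    variables = list(logm.variables)
    neuro_idx = [variables.index(v) for v in neuro_variables if v in variables]
    for j in range(p):
        if j == 0:
            s = eigvec[neuro_idx, j].sum()
        else:
            s = eigvec[:, j].sum()
        if s < 0:
            eigvec[:, j] = -eigvec[:, j]

    if eigval[k - 1] <= 1e-12:
        raise FitError(
            f"retained factor {k} has a (near-)zero eigenvalue; the data are "
            "rank-deficient — retain fewer factors"
        )
    load = eigvec[:, :k] * np.sqrt(eigval[:k])
    coefs = eigvec[:, :k] / np.sqrt(eigval[:k])
    means = logm.data.mean()
    z = (logm.data - means) / sds
    scores = z.to_numpy() @ coefs

    cols = [f"factor{j + 1}" for j in range(k)]
    idx = pd.Index(logm.specimen_ids, name="specimen_id")
    loadings = pd.DataFrame(load, index=variables, columns=cols)
    return FactorModel(
        eigenvalues=eigval,
        loadings=loadings,
        communalities=pd.Series((load**2).sum(axis=1), index=variables, name="h2"),
        scores=pd.DataFrame(scores, index=idx, columns=cols),
        pct_variance=100.0 * eigval[:k] / eigval.sum(),
        scoring_coefficients=pd.DataFrame(coefs, index=variables, columns=cols),
        means=means,
        sds=sds,
    )


def score(model: FactorModel, logm: LogMatrix) -> pd.DataFrame:
    """Score new specimens in a fitted factor space (training means/SDs)."""
    missing = [v for v in model.variables if v not in logm.data.columns]
    if missing:
        raise FitError(f"log matrix lacks variables {missing}")
    z = (logm.data[list(model.variables)] - model.means) / model.sds
    out = z.to_numpy() @ model.scoring_coefficients.to_numpy()
    return pd.DataFrame(
        out, index=pd.Index(logm.specimen_ids, name="specimen_id"),
        columns=list(model.scores.columns),
    )


def isometry_angle(model: FactorModel) -> IsometryAngles:
    """Angle between the image of the isometric vector and each factor axis.

    The unit isometric direction (1, ..., 1)/sqrt(6) in log-variable space
    is pushed through the factor-scoring transformation (standardization by
    the training SDs followed by the scoring-coefficient matrix); the
    angle of its image to each factor axis, folded to [0, 90] degrees, is
    returned.  A small angle to one factor identifies that factor as the
    size axis.
    """
    if model.k != 2:
        raise FitError(f"isometry angles require exactly 2 retained factors, got {model.k}")
    p = len(model.variables)
    iso = np.ones(p) / np.sqrt(p)
    image = (iso / model.sds.to_numpy()) @ model.scoring_coefficients.to_numpy()
    norm = np.linalg.norm(image)
    if norm <= 1e-12:
        raise FitError("isometric vector maps to the origin of the factor plane")
    a1 = np.degrees(np.arccos(np.clip(abs(image[0]) / norm, -1.0, 1.0)))
    a2 = np.degrees(np.arccos(np.clip(abs(image[1]) / norm, -1.0, 1.0)))
    return IsometryAngles(angle_to_factor1=float(a1), angle_to_factor2=float(a2))


__all__ = ["FactorModel", "IsometryAngles", "fit_factors", "score", "isometry_angle"]
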