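"""Two-block partial least squares (2B-PLS) between cranial modules.

The covariation between the neurocranial block (GOL, BBH, XCB) and the
splanchnocranial block (NPH, BPL, ZYB) is extracted by a singular value
decomposition of the 3 x 3 between-block association matrix computed over
all specimens jointly (non-pooled).  In ``correlation`` mode (the default)
the association matrix holds the cross-correlations between blocks and
block data are column-standardized before scoring; in ``covariance`` mode
it holds cross-covariances and scores are computed from centered data.

Each PLS dimension pairs one unit-norm loading vector per block; the pair
maximizes the covariance between the corresponding block scores.  The
fraction of squared covariation carried by dimension *i* is
``100 * s_i^2 / sum_j s_j^2`` for singular values ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import DEFAULT_BLOCK_MAP
from .errors import FitError
from .preprocess import ShapeMatrix

_MODES = ("correlation", "covariance")


@dataclass
class PLSModel:
    """Fitted 2B-PLS: loadings, singular values, scores and training stats."""

    block_names: tuple[str, str]
    block_variables: tuple[tuple[str, ...], tuple[str, ...]]
    loadings: tuple[np.ndarray, np.ndarray]  # each 3 x d, unit-norm columns
    singular_values: np.ndarray  # (d,), descending
    pct_covariation: np.ndarray  # (d,), sums to 100
    scores: tuple[pd.DataFrame, pd.DataFrame]  # each n x d
    score_correlation: np.ndarray  # (d,)
    mode: str
    # training statistics needed to project new specimens
    means: tuple[np.ndarray, np.ndarray] = field(repr=False, default=(None, None))
    sds: tuple[np.ndarray, np.ndarray] = field(repr=False, default=(None, None))

    @property
    def n_dimensions(self) -> int:
        return int(self.singular_values.size)

    @property
    def variables(self) -> tuple[str, ...]:
        return self.block_variables[0] + self.block_variables[1]

    def loadings_table(self) -> pd.DataFrame:
        """Long-form loadings: variable, block, dimension, loading."""
        rows = []
        for b, (name, vs) in enumerate(zip(self.block_names, self.block_variables)):
            for j, v in enumerate(vs):
                for d in range(self.n_dimensions):
                    rows.append(
                        {
                            "variable": v,
                            "block": name,
                            "dimension": d + 1,
                            "loading": self.loadings[b][j, d],
                        }
                    )
        return pd.DataFrame(rows)

    def scores_table(self) -> pd.DataFrame:
        """Wide scores table keyed by specimen_id."""
        n1, n2 = self.block_names
        t1 = self.scores[0].add_prefix(f"{n1}_")
        t2 = self.scores[1].add_prefix(f"{n2}_")
        return pd.concat([t1, t2], axis=1)

    def summary(self) -> dict:
        return {
            "mode": self.mode,
            "singular_values": [float(s) for s in self.singular_values],
            "pct_covariation": [float(p) for p in self.pct_covariation],
            "score_correlation": [float(r) for r in self.score_correlation],
        }


def _block_arrays(
    shape: ShapeMatrix, block_map: Mapping[str, Sequence[str]]
) -> tuple[tuple[str, str], tuple[tuple[str, ...], tuple[str, ...]], list[np.ndarray]]:
    names = tuple(block_map)
    if len(names) != 2:
        raise FitError(f"expected exactly two blocks, got {names}")
    variables = tuple(tuple(block_map[n]) for n in names)
    arrays = [shape.data[list(vs)].to_numpy(dtype=float) for vs in variables]
    return names, variables, arrays  # type: ignore[return-value]


def fit_pls(
    shape: ShapeMatrix,
    block_map: Mapping[str, Sequence[str]] | None = None,
    mode: str = "correlation",
) -> PLSModel:
    """Fit 2B-PLS on a size-scaled shape matrix.

    The sign of each dimension is fixed so that the neurocranial (first
    block) loadings sum to a positive value; the paired splanchnocranial
    vector is flipped together with it, so the between-block geometry
    (including the sign of the score correlation) is data-driven.
    """
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {_MODES}")
    block_map = block_map or DEFAULT_BLOCK_MAP
    names, variables, (x1, x2) = _block_arrays(shape, block_map)
    n = x1.shape[0]
    if n < 4:
        raise FitError(f"2B-PLS needs at least 4 specimens, got {n}")

    means, sds, std = [], [], []
    for arr, vs in zip((x1, x2), variables):
        mu = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1)
        bad = np.flatnonzero(sd <= 0)
        if bad.size:
            raise FitError(f"constant column {vs[bad[0]]!r}: block is rank-deficient")
        means.append(mu)
        sds.append(sd)
        centered = arr - mu
        std.append(centered / sd if mode == "correlation" else centered)

    assoc = std[0].T @ std[1] / (n - 1)
    u, s, vt = np.linalg.svd(assoc)
    v = vt.T

    # orientation: neurocranial loading sums positive, paired flip
    for d in range(s.size):
        if u[:, d].sum() < 0:
            u[:, d] = -u[:, d]
            v[:, d] = -v[:, d]

    scores1 = std[0] @ u
    scores2 = std[1] @ v
    with np.errstate(invalid="ignore"):
        corr = np.array(
            [
                np.corrcoef(scores1[:, d], scores2[:, d])[0, 1]
                for d in range(s.size)
            ]
        )
    pct = 100.0 * s**2 / np.sum(s**2)

    cols = [f"dim{d + 1}" for d in range(s.size)]
    idx = pd.Index(shape.specimen_ids, name="specimen_id")
    return PLSModel(
        block_names=names,
        block_variables=variables,
        loadings=(u, v),
        singular_values=s,
        pct_covariation=pct,
        scores=(
            pd.DataFrame(scores1, index=idx, columns=cols),
            pd.DataFrame(scores2, index=idx, columns=cols),
        ),
        score_correlation=corr,
        mode=mode,
        means=(means[0], means[1]),
        sds=(sds[0], sds[1]),
    )


def project(model: PLSModel, shape: ShapeMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Project new size-scaled specimens into a fitted PLS space.

    Centering (and standardization, in correlation mode) uses the TRAINING
    means and standard deviations, so fossils or perturbed replicates are
    placed in the fixed ordination rather than re-fitting it.
    """
    out = []
    idx = pd.Index(shape.specimen_ids, name="specimen_id")
    cols = [f"dim{d + 1}" for d in range(model.n_dimensions)]
    for b in range(2):
        vs = model.block_variables[b]
        missing = [v for v in vs if v not in shape.data.columns]
        if missing:
            raise FitError(f"shape matrix lacks block variables {missing}")
        arr = shape.data[list(vs)].to_numpy(dtype=float)
        centered = arr - model.means[b]
        if model.mode == "correlation":
            centered = centered / model.sds[b]
        out.append(pd.DataFrame(centered @ model.loadings[b], index=idx, columns=cols))
    return out[0], out[1]


__all__ = ["PLSModel", "fit_pls", "project"]
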