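"""Log transformation and Mosimann geometric-mean size scaling.

Two analysis matrices are derived from a :class:`~craniomorph.datasets.Dataset`:

* the log-raw matrix ``log10(x)`` used by the factor (size/shape) model;
* the size-scaled shape matrix ``log10(x / GM(x))`` used by two-block PLS,
  where GM is the per-specimen geometric mean over all six variables, so
  every cranium is rescaled to geometric mean 1 and only proportions remain.

On the log scale the second form is simply row-centering, which is how it
is implemented (numerically exact row sums of zero up to rounding).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import Dataset, VARIABLES
from .errors import ValidationError


@dataclass(frozen=True)
class LogMatrix:
    """n x 6 matrix of base-10 log measurements with a fixed variable order."""

    data: pd.DataFrame

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.data.columns)

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class ShapeMatrix(LogMatrix):
    """Log-shape (Mosimann) matrix: each row sums to zero."""


def _measurement_frame(ds: Dataset, order: Sequence[str]) -> pd.DataFrame:
    order = tuple(order)
    if sorted(order) != sorted(VARIABLES):
        raise ValidationError(f"variable order must be a permutation of {VARIABLES}")
    frame = ds.to_frame().set_index("specimen_id")[list(order)].astype(float)
    if (frame.to_numpy() <= 0).any() or not np.isfinite(frame.to_numpy()).all():
        raise ValidationError("all measurements must be strictly positive and finite")
    return frame


def log_transform(ds: Dataset, order: Sequence[str] = VARIABLES) -> LogMatrix:
    """Base-10 logarithms of the six measurements, specimen by specimen."""
    frame = _measurement_frame(ds, order)
    return LogMatrix(np.log10(frame))


def gm_scale(ds: Dataset, order: Sequence[str] = VARIABLES) -> ShapeMatrix:
    """Mosimann size-scaled shape variables on the log scale.

    Dividing each measurement by the specimen's geometric mean and taking
    log10 equals subtracting the row mean of the logs; the result is
    invariant to rescaling a specimen by any positive factor.
    """
    logs = np.log10(_measurement_frame(ds, order))
    centered = logs.sub(logs.mean(axis=1), axis=0)
    return ShapeMatrix(centered)


__all__ = ["LogMatrix", "ShapeMatrix", "log_transform", "gm_scale"]
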