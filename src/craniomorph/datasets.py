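"""Domain types and CSV I/O for two-module craniometric tables.

A specimen is described by six classical anthropometric distances (mm),
three per cranial module:

* neurocranium — GOL (glabella-opisthocranion length), XCB (maximum
  biparietal cranial breadth), BBH (basion-bregma height);
* splanchnocranium — BPL (basion-prosthion length), NPH (nasion-prosthion
  height), ZYB (bizygomatic breadth);

plus taxon / group / age-class labels and optional body mass (kg),
endocranial volume (cm^3) and geological age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, ValidationError

#: Neurocranial variables, in the fixed analysis order.
NEURO_VARIABLES: tuple[str, ...] = ("GOL", "BBH", "XCB")
#: Splanchnocranial variables, in the fixed analysis order.
SPLANCHNO_VARIABLES: tuple[str, ...] = ("NPH", "BPL", "ZYB")
#: Default variable order used by every downstream matrix.
VARIABLES: tuple[str, ...] = NEURO_VARIABLES + SPLANCHNO_VARIABLES
#: Default block assignment: three variables per cranial module.
DEFAULT_BLOCK_MAP: dict[str, tuple[str, ...]] = {
    "neurocranium": NEURO_VARIABLES,
    "splanchnocranium": SPLANCHNO_VARIABLES,
}

#: Optional per-specimen covariates carried through unchanged.
OPTIONAL_FIELDS: tuple[str, ...] = ("bm_kg", "ecv_cm3", "geo_age")

AGE_CLASSES: tuple[str, ...] = ("adult", "juvenile")

_CSV_COLUMNS = (
    "specimen_id",
    "taxon",
    "group",
    "age_class",
    "GOL",
    "XCB",
    "BBH",
    "BPL",
    "NPH",
    "ZYB",
    "bm_kg",
    "ecv_cm3",
    "geo_age",
)


@dataclass(frozen=True)
class SpecimenRecord:
    """One cranium: identifiers, labels and the six measurements in mm."""

    specimen_id: str
    taxon: str
    group: str
    age_class: str
    GOL: float
    XCB: float
    BBH: float
    BPL: float
    NPH: float
    ZYB: float
    bm_kg: float | None = None
    ecv_cm3: float | None = None
    geo_age: float | None = None

    def measurement(self, variable: str) -> float:
        if variable not in VARIABLES:
            raise KeyError(f"unknown craniometric variable {variable!r}")
        return float(getattr(self, variable))

    def measurements(self, order: Sequence[str] = VARIABLES) -> tuple[float, ...]:
        return tuple(self.measurement(v) for v in order)

    def validate(self) -> None:
        for v in VARIABLES:
            x = getattr(self, v)
            if not isinstance(x, (int, float)) or not math.isfinite(float(x)) or float(x) <= 0.0:
                raise ValidationError(
                    f"specimen {self.specimen_id!r}: variable {v} must be a "
                    f"strictly positive finite number, got {x!r}"
                )
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: age_class {self.age_class!r} "
                f"not in {AGE_CLASSES}"
            )


@dataclass
class Dataset:
    """An ordered collection of validated specimens plus the block map."""

    records: list[SpecimenRecord]
    block_map: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_MAP)
    )
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpecimenRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.records == other.records
            and {k: tuple(v) for k, v in self.block_map.items()}
            == {k: tuple(v) for k, v in other.block_map.items()}
        )

    def validate(self) -> None:
        if not self.records:
            raise ValidationError("dataset is empty")
        blocks = [tuple(v) for v in self.block_map.values()]
        flat = [v for b in blocks for v in b]
        if sorted(flat) != sorted(VARIABLES) or any(len(b) != 3 for b in blocks):
            raise ValidationError(
                "block_map must partition the six variables, three per block; "
                f"got {dict(self.block_map)!r}"
            )
        seen: set[str] = set()
        for r in self.records:
            r.validate()
            if r.specimen_id in seen:
                raise ValidationError(f"duplicate specimen_id {r.specimen_id!r}")
            seen.add(r.specimen_id)

    @property
    def specimen_ids(self) -> list[str]:
        return [r.specimen_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, one row per specimen, in the canonical column order."""
        rows = []
        for r in self.records:
            rows.append({c: getattr(r, c) for c in _CSV_COLUMNS})
        return pd.DataFrame(rows, columns=list(_CSV_COLUMNS))

    def filter(
        self,
        predicate: Callable[[SpecimenRecord], bool] | None = None,
        *,
        taxon: str | Iterable[str] | None = None,
        group: str | Iterable[str] | None = None,
        age_class: str | Iterable[str] | None = None,
    ) -> "Dataset":
        """Subset by predicate and/or label equality, preserving order.

        An empty result raises :class:`ValidationError` (a Dataset is
        non-empty by contract), so downstream code never silently analyses
        nothing.
        """

        def as_set(x):
            if x is None:
                return None
            return {x} if isinstance(x, str) else set(x)

        taxa, groups, ages = as_set(taxon), as_set(group), as_set(age_class)

        def keep(r: SpecimenRecord) -> bool:
            if predicate is not None and not predicate(r):
                return False
            if taxa is not None and r.taxon not in taxa:
                return False
            if groups is not None and r.group not in groups:
                return False
            if ages is not None and r.age_class not in ages:
                return False
            return True

        kept = [r for r in self.records if keep(r)]
        if not kept:
            raise ValidationError("filter produced an empty dataset")
        return Dataset(kept, block_map=dict(self.block_map), metadata=dict(self.metadata))


def _parse_optional(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def read_dataset(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    delimiter: str = ",",
    block_map: Mapping[str, tuple[str, ...]] | None = None,
) -> Dataset:
    """Read a craniometric CSV into a validated :class:`Dataset`.

    ``schema`` maps canonical field names to the column names actually
    present in the file (only entries that differ need to be given).
    Row order is preserved.  Missing mapped columns raise
    :class:`SchemaError`; invalid measurements raise
    :class:`ValidationError` naming the specimen and variable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep=delimiter, dtype={0: str})

    colmap = {c: c for c in _CSV_COLUMNS}
    if schema:
        colmap.update(schema)

    required = ("specimen_id", "taxon", "group", "age_class", *VARIABLES)
    for canon in required:
        if colmap[canon] not in table.columns:
            raise SchemaError(
                f"column {colmap[canon]!r} (for field {canon!r}) missing from {path}"
            )

    records: list[SpecimenRecord] = []
    for _, row in table.iterrows():
        sid = str(row[colmap["specimen_id"]])
        values: dict = {
            "specimen_id": sid,
            "taxon": str(row[colmap["taxon"]]),
            "group": str(row[colmap["group"]]),
            "age_class": str(row[colmap["age_class"]]),
        }
        for v in VARIABLES:
            raw = row[colmap[v]]
            try:
                values[v] = float(raw)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"specimen {sid!r}: variable {v} is not numeric: {raw!r}"
                ) from exc
        for opt in OPTIONAL_FIELDS:
            col = colmap[opt]
            values[opt] = _parse_optional(row[col]) if col in table.columns else None
        records.append(SpecimenRecord(**values))

    ds = Dataset(records, block_map=dict(block_map or DEFAULT_BLOCK_MAP))
    ds.metadata["source"] = str(path)
    return ds


def write_dataset(ds: Dataset, path: str | Path, *, delimiter: str = ",") -> None:
    """Write ``ds`` as a plain CSV (header + one row per specimen).

    Measurements keep at least three decimal places; absent optional
    fields become empty cells.
    """
    frame = ds.to_frame()
    out = frame.copy()
    for col in (*VARIABLES, *OPTIONAL_FIELDS):
        out[col] = frame[col].map(
            lambda x: "" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.6f}"
        )
    out.to_csv(path, sep=delimiter, index=False)


def subset_complete(ds: Dataset, fields: Sequence[str] = ("bm_kg", "ecv_cm3")) -> Dataset:
    """Specimens with all of ``fields`` present (complete-case analysis)."""
    return ds.filter(lambda r: all(getattr(r, f) is not None for f in fields))


__all__ = [
    "SpecimenRecord",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "subset_complete",
    "VARIABLES",
    "NEURO_VARIABLES",
    "SPLANCHNO_VARIABLES",
    "DEFAULT_BLOCK_MAP",
]
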