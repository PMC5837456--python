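"""Core domain types shared across the scan pipeline."""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .exceptions import MalformedColumn

__all__ = [
    "FieldType",
    "DataType",
    "CatMultipleMissingness",
    "ColumnKey",
    "FieldMetadata",
    "DataCoding",
    "DerivedVariable",
    "AnalysisDataset",
    "MISSING",
]

#: Sentinel used in metadata files for a reassignment target meaning "missing".
MISSING = "NA"


class FieldType(enum.Enum):
    """Declared biobank field type, as found in the variable-information file."""

    CONTINUOUS = "CONTINUOUS"
    INTEGER = "INTEGER"
    CAT_SINGLE = "CAT_SINGLE"
    CAT_MULTIPLE = "CAT_MULTIPLE"


class DataType(enum.Enum):
    """Statistical data type assigned to a derived, test-ready variable."""

    CONTINUOUS = "CONTINUOUS"
    ORDERED = "ORDERED"
    UNORDERED = "UNORDERED"
    BINARY = "BINARY"


class CatMultipleMissingness(enum.Enum):
    """Who counts as FALSE in a binary child of a categorical (multiple) field.

    OTHER_VALUE_HOLDERS
        participants who hold some other value of the field.
    RESPONDERS
        participants who hold any value of the field (i.e. answered it).
    ALL
        every participant in the cohort.
    """

    OTHER_VALUE_HOLDERS = "OTHER_VALUE_HOLDERS"
    RESPONDERS = "RESPONDERS"
    ALL = "ALL"


_COLUMN_RE = re.compile(r"^x(\d+)_(\d+)_(\d+)$")


@dataclass(frozen=True, order=True)
class ColumnKey:
    """Identifier of one phenotype column: field, time point, repeat.

    A field may be measured at several time points (instances) and several
    times within a time point (array indices). Column headers encode all
    three as ``x<field>_<instance>_<array>``.
    """

    field_id: int
    instance: int
    array_index: int

    def __post_init__(self) -> None:
        if self.field_id <= 0:
            raise ValueError(f"field_id must be positive, got {self.field_id}")
        if self.instance < 0 or self.array_index < 0:
            raise ValueError("instance and array_index must be non-negative")

    @classmethod
    def parse(cls, header: str) -> "ColumnKey":
        m = _COLUMN_RE.match(header)
        if m is None:
            raise MalformedColumn(f"not a field column header: {header!r}")
        field_id = int(m.group(1))
        if field_id == 0:
            raise MalformedColumn(f"field id must be positive in {header!r}")
        return cls(field_id, int(m.group(2)), int(m.group(3)))

    def format(self) -> str:
        return f"x{self.field_id}_{self.instance}_{self.array_index}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


@dataclass(frozen=True)
class FieldMetadata:
    """Per-field scan configuration from the variable-information file."""

    field_id: int
    field_type: FieldType
    data_code_id: Optional[int] = None
    excluded: bool = False
    trait_equivalent: bool = False
    cat_multiple_missingness: Optional[CatMultipleMissingness] = None


@dataclass(frozen=True)
class DataCoding:
    """Reusable description of a categorical value coding.

    ``reassignments`` maps a raw value onto a new value, or onto ``None``
    meaning missing. ``ordering`` lists raw values in rank order for ordinal
    codings. ``default_value`` is substituted for missing entries before any
    type decision is made.
    """

    coding_id: int
    is_ordinal: bool = False
    ordering: Optional[Sequence[float]] = None
    reassignments: Optional[Mapping[float, Optional[float]]] = None
    default_value: Optional[float] = None


@dataclass
class DerivedVariable:
    """A processed, test-ready variable with its provenance trail.

    ``values`` is a pandas Series indexed by participant id. For ORDERED
    variables the values are ranks 1..K of the declared ordering; BINARY
    values are 0/1; CONTINUOUS values are finite reals (post-transform).
    """

    name: str
    field_id: int
    data_type: DataType
    values: pd.Series
    provenance: list = field(default_factory=list)

    def n_nonmissing(self) -> int:
        return int(self.values.notna().sum())


@dataclass
class AnalysisDataset:
    """Joined, participant-aligned scan inputs.

    ``frame`` holds one row per participant (index = participant id) with the
    trait column, confounder columns and all phenotype columns. Phenotype
    columns are keyed by their :class:`ColumnKey`.
    """

    frame: pd.DataFrame
    trait_column: str
    confounder_columns: Sequence[str]
    phenotype_columns: Mapping[ColumnKey, str]

    @property
    def trait(self) -> pd.Series:
        return self.frame[self.trait_column]

    @property
    def confounders(self) -> pd.DataFrame:
        return self.frame[list(self.confounder_columns)]

    def field_columns(self, field_id: int) -> dict:
        """All phenotype columns of a field, keyed by ColumnKey."""
        return {
            k: self.frame[col]
            for k, col in self.phenotype_columns.items()
            if k.field_id == field_id
        }

    def field_ids(self) -> list:
        return sorted({k.field_id for k in self.phenotype_columns})
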