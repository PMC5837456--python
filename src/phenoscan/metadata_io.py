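"""Readers and writers for the scan's three input dialects.

The engine consumes (a) a phenotype CSV with one row per participant and
columns named ``x<field>_<instance>_<array>``, (b) a variable-information
TSV describing each field, and (c) a data-coding TSV describing each
reusable category coding. The trait of interest and confounders may live in
the phenotype file or in separate CSVs keyed on the participant id.

File dialects
-------------
Variable-information TSV columns::

    field_id  field_type  data_coding  excluded  trait_equivalent  cat_mult_missingness

``field_type`` is one of CONTINUOUS / INTEGER / CAT_SINGLE / CAT_MULTIPLE;
``excluded`` and ``trait_equivalent`` are TRUE/FALSE; empty or ``NA`` cells
mean "absent".

Data-coding TSV columns::

    coding_id  is_ordinal  ordering  reassignments  default_value

``ordering`` is a ``|``-separated value list in rank order; ``reassignments``
is a comma-separated list of ``old=new`` pairs where ``new`` may be the
literal ``NA`` to mean missing.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Union

import pandas as pd

from .exceptions import (
    DuplicateField,
    DuplicateParticipant,
    EmptyJoin,
    InvalidReassignment,
    MalformedColumn,
    SchemaError,
)
from .types import (
    MISSING,
    AnalysisDataset,
    CatMultipleMissingness,
    ColumnKey,
    DataCoding,
    FieldMetadata,
    FieldType,
)

logger = logging.getLogger("phenoscan")

VARIABLE_INFO_COLUMNS = [
    "field_id",
    "field_type",
    "data_coding",
    "excluded",
    "trait_equivalent",
    "cat_mult_missingness",
]

DATA_CODING_COLUMNS = [
    "coding_id",
    "is_ordinal",
    "ordering",
    "reassignments",
    "default_value",
]

PathLike = Union[str, Path]


def parse_column_key(header: str) -> ColumnKey:
    """Parse a phenotype column header into its (field, instance, array) key.

    Raises :class:`MalformedColumn` when the header does not match
    ``x<digits>_<digits>_<digits>`` (e.g. for the participant-id column).
    """
    return ColumnKey.parse(header)


def _is_absent(cell) -> bool:
    return pd.isna(cell) or (isinstance(cell, str) and cell.strip() in ("", MISSING))


def _parse_bool(cell, column: str) -> bool:
    if _is_absent(cell):
        return False
    text = str(cell).strip().upper()
    if text in ("TRUE", "1", "YES"):
        return True
    if text in ("FALSE", "0", "NO"):
        return False
    raise SchemaError(f"cannot read {column}={cell!r} as a boolean")


def _parse_number(text: str) -> float:
    value = float(text)
    return int(value) if value == int(value) else value


def load_variable_info(path: PathLike) -> Dict[int, FieldMetadata]:
    """Load the variable-information TSV into FieldMetadata keyed by field id."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in VARIABLE_INFO_COLUMNS if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"variable-information file lacks columns {missing_cols}")

    out: Dict[int, FieldMetadata] = {}
    for _, row in table.iterrows():
        field_id = int(row["field_id"])
        if field_id in out:
            raise DuplicateField(f"field {field_id} listed more than once")
        try:
            field_type = FieldType(str(row["field_type"]).strip())
        except ValueError:
            raise SchemaError(
                f"unknown field_type {row['field_type']!r} for field {field_id}"
            ) from None
        data_code = None if _is_absent(row["data_coding"]) else int(float(row["data_coding"]))
        option = None
        if not _is_absent(row["cat_mult_missingness"]):
            option = CatMultipleMissingness(str(row["cat_mult_missingness"]).strip())
        out[field_id] = FieldMetadata(
            field_id=field_id,
            field_type=field_type,
            data_code_id=data_code,
            excluded=_parse_bool(row["excluded"], "excluded"),
            trait_equivalent=_parse_bool(row["trait_equivalent"], "trait_equivalent"),
            cat_multiple_missingness=option,
        )
    logger.info("variable info: %d fields loaded from %s", len(out), path)
    return out


def _parse_reassignments(cell: str) -> Dict[float, Optional[float]]:
    pairs: Dict[float, Optional[float]] = {}
    for chunk in str(cell).split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise InvalidReassignment(f"malformed reassignment {chunk!r}")
        old_s, new_s = chunk.split("=", 1)
        old = _parse_number(old_s)
        new = None if new_s.strip() == MISSING else _parse_number(new_s)
        if old in pairs:
            raise InvalidReassignment(f"value {old} reassigned twice")
        pairs[old] = new
    # no chains: a target of one pair must not be the source of another
    targets = {v for v in pairs.values() if v is not None}
    chained = targets & set(pairs)
    if chained:
        raise InvalidReassignment(f"chained reassignment through {sorted(chained)}")
    return pairs


def load_data_coding(path: PathLike) -> Dict[int, DataCoding]:
    """Load the data-coding TSV into DataCoding records keyed by coding id."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in DATA_CODING_COLUMNS if c not in table.columns]
    if missing_cols:
        raise SchemaError(f"data-coding file lacks columns {missing_cols}")

    out: Dict[int, DataCoding] = {}
    for _, row in table.iterrows():
        coding_id = int(row["coding_id"])
        ordering = None
        if not _is_absent(row["ordering"]):
            ordering = tuple(
                _parse_number(tok) for tok in str(row["ordering"]).split("|") if tok.strip()
            )
            if len(set(ordering)) != len(ordering):
                raise SchemaError(f"coding {coding_id}: duplicate values in ordering")
        reassignments = None
        if not _is_absent(row["reassignments"]):
            reassignments = _parse_reassignments(row["reassignments"])
        default = None if _is_absent(row["default_value"]) else _parse_number(row["default_value"])
        out[coding_id] = DataCoding(
            coding_id=coding_id,
            is_ordinal=_parse_bool(row["is_ordinal"], "is_ordinal"),
            ordering=ordering,
            reassignments=reassignments,
            default_value=default,
        )
    logger.info("data codings: %d loaded from %s", len(out), path)
    return out


def _fmt_number(value: float) -> str:
    return str(int(value)) if float(value) == int(value) else repr(float(value))


def save_variable_info(metadata: Iterable[FieldMetadata], path: PathLike) -> None:
    """Serialize FieldMetadata back to the variable-information dialect."""
    rows = []
    for m in metadata:
        rows.append(
            {
                "field_id": m.field_id,
                "field_type": m.field_type.value,
                "data_coding": MISSING if m.data_code_id is None else m.data_code_id,
                "excluded": "TRUE" if m.excluded else "FALSE",
                "trait_equivalent": "TRUE" if m.trait_equivalent else "FALSE",
                "cat_mult_missingness": (
                    MISSING
                    if m.cat_multiple_missingness is None
                    else m.cat_multiple_missingness.value
                ),
            }
        )
    pd.DataFrame(rows, columns=VARIABLE_INFO_COLUMNS).to_csv(path, sep="\t", index=False)


def save_data_coding(codings: Iterable[DataCoding], path: PathLike) -> None:
    """Serialize DataCoding records back to the data-coding dialect."""
    rows = []
    for c in codings:
        if c.reassignments:
            reass = ",".join(
                f"{_fmt_number(old)}={MISSING if new is None else _fmt_number(new)}"
                for old, new in c.reassignments.items()
            )
        else:
            reass = MISSING
        rows.append(
            {
                "coding_id": c.coding_id,
                "is_ordinal": "TRUE" if c.is_ordinal else "FALSE",
                "ordering": (
                    MISSING if c.ordering is None else "|".join(_fmt_number(v) for v in c.ordering)
                ),
                "reassignments": reass,
                "default_value": MISSING if c.default_value is None else _fmt_number(c.default_value),
            }
        )
    pd.DataFrame(rows, columns=DATA_CODING_COLUMNS).to_csv(path, sep="\t", index=False)


def _read_keyed(path: PathLike, id_column: str) -> pd.DataFrame:
    table = pd.read_csv(path)
    if id_column not in table.columns:
        raise SchemaError(f"{path}: participant-id column {id_column!r} not found")
    if table[id_column].duplicated().any():
        dup = table[id_column][table[id_column].duplicated()].iloc[0]
        raise DuplicateParticipant(f"{path}: participant id {dup!r} appears more than once")
    return table.set_index(id_column)


def assemble_dataset(
    pheno_path: PathLike,
    trait: str,
    trait_path: Optional[PathLike] = None,
    confounders: Optional[Sequence[str]] = None,
    confounder_path: Optional[PathLike] = None,
    id_column: str = "userId",
) -> AnalysisDataset:
    """Join phenotype, trait and confounder inputs into one analysis dataset.

    ``trait`` names the trait-of-interest column, found either in the
    phenotype file or in ``trait_path``. Confounder columns are taken from
    ``confounder_path`` when given (all of its non-id columns, unless
    ``confounders`` restricts them), otherwise from the phenotype file.
    The join is a strict inner join on the participant id; participants
    missing from any supplied file are dropped globally.
    """
    pheno = _read_keyed(pheno_path, id_column)

    phenotype_columns: Dict[ColumnKey, str] = {}
    for col in pheno.columns:
        try:
            key = parse_column_key(col)
        except MalformedColumn:
            continue
        phenotype_columns[key] = col

    frames = [pheno]
    if trait_path is not None:
        trait_table = _read_keyed(trait_path, id_column)
        if trait not in trait_table.columns:
            raise SchemaError(f"trait column {trait!r} not in {trait_path}")
        frames.append(trait_table[[trait]])
    elif trait not in pheno.columns:
        raise SchemaError(f"trait column {trait!r} not in phenotype file")

    confounder_cols: list = []
    if confounder_path is not None:
        conf_table = _read_keyed(confounder_path, id_column)
        confounder_cols = list(confounders) if confounders else list(conf_table.columns)
        missing = [c for c in confounder_cols if c not in conf_table.columns]
        if missing:
            raise SchemaError(f"confounder columns {missing} not in {confounder_path}")
        frames.append(conf_table[confounder_cols])
    elif confounders:
        confounder_cols = list(confounders)
        missing = [c for c in confounder_cols if c not in pheno.columns]
        if missing:
            raise SchemaError(f"confounder columns {missing} not in phenotype file")

    joined = pd.concat(frames, axis=1, join="inner")
    if joined.empty:
        raise EmptyJoin("no participant id is shared across the supplied files")
    # trait must be present for every regression
    joined = joined[joined[trait].notna()]
    if joined.empty:
        raise EmptyJoin("no participant has a non-missing trait value")

    logger.info(
        "assembled dataset: %d participants, %d phenotype columns, %d confounders",
        len(joined),
        len(phenotype_columns),
        len(confounder_cols),
    )
    return AnalysisDataset(
        frame=joined,
        trait_column=trait,
        confounder_columns=confounder_cols,
        phenotype_columns=phenotype_columns,
    )
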