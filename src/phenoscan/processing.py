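"""Rule-based variable processing flow.

Each raw biobank field is turned into zero or more test-ready derived
variables of one of four data types (continuous, ordered categorical,
unordered categorical, binary), following a fixed decision flow keyed on
the declared field type:

* CONTINUOUS  -> collapse arrays -> recode -> inverse-rank-normal, unless a
  single value dominates the distribution, in which case the variable is
  binned into ordered categories (or binary at two distinct values).
* INTEGER     -> collapse -> recode -> binary at 2 distinct values, ordered
  at 3..20, otherwise treated exactly like a continuous variable.
* CAT_SINGLE  -> recode via its data coding -> binary at 2 distinct values,
  else ordered or unordered per the coding's ordinal flag.
* CAT_MULTIPLE-> expanded into one binary child per observed value.

Where a field is measured at several time points, only the first occurrence
(lowest instance index, normally 0) is used. Negative values of categorical
fields denote flavours of missingness and are recoded to missing.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass, field as dc_field
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    AmbiguousSingle,
    DegenerateDistribution,
    EmptyExpansion,
    MissingDataCode,
)
from .types import (
    AnalysisDataset,
    CatMultipleMissingness,
    ColumnKey,
    DataCoding,
    DataType,
    DerivedVariable,
    FieldMetadata,
    FieldType,
)

logger = logging.getLogger("phenoscan")

__all__ = [
    "ProcessingConfig",
    "FlowCounters",
    "IntegerRoute",
    "collapse_field_columns",
    "recode_values",
    "inverse_rank_normal",
    "needs_binning",
    "bin_to_ordered",
    "classify_integer",
    "expand_cat_multiple",
    "process_field",
    "process_all",
    "export_derived",
]


@dataclass(frozen=True)
class ProcessingConfig:
    """Tunable thresholds of the processing flow.

    dominance_threshold
        a continuous vector is binned instead of rank-normalised when its
        single most frequent value holds strictly more than this share of
        the non-missing observations.
    n_bins
        number of ordered categories produced by equal-mass binning.
    integer_distinct_max
        integer fields with at most this many distinct values become
        ordered categorical; above it they follow the continuous path.
    seed
        run-level seed for random tie-breaking in the rank transform;
        offset deterministically per field id so partitioned and whole
        scans agree.
    """

    dominance_threshold: float = 0.2
    n_bins: int = 3
    integer_distinct_max: int = 20
    seed: int = 1234

    def field_seed(self, field_id: int) -> int:
        return (self.seed + field_id) % (2**31)


# removal reasons used by FlowCounters
REMOVED_EXCLUDED = "excluded_a_priori"
REMOVED_DEGENERATE = "single_value"
REMOVED_EMPTY_EXPANSION = "empty_expansion"
REMOVED_SAMPLE_SIZE = "sample_size_lt_500"
REMOVED_CATEGORY_LIMIT = "gt_1000_categories"


@dataclass
class FlowCounters:
    """Per-stage tallies of the processing flow.

    Conservation holds at the field level: every field that enters the flow
    either emits at least one derived variable or is counted under exactly
    one removal reason.
    """

    fields_entered: int = 0
    fields_emitted: int = 0
    fields_removed: Counter = dc_field(default_factory=Counter)
    variables_emitted: Counter = dc_field(default_factory=Counter)

    def record_emit(self, variables: Sequence[DerivedVariable]) -> None:
        self.fields_emitted += 1
        for v in variables:
            self.variables_emitted[v.data_type.value] += 1

    def record_removed(self, reason: str) -> None:
        self.fields_removed[reason] += 1

    def balanced(self) -> bool:
        return self.fields_entered == self.fields_emitted + sum(self.fields_removed.values())

    def merge(self, other: "FlowCounters") -> None:
        self.fields_entered += other.fields_entered
        self.fields_emitted += other.fields_emitted
        self.fields_removed.update(other.fields_removed)
        self.variables_emitted.update(other.variables_emitted)


class IntegerRoute(enum.Enum):
    CONTINUOUS_PATH = "CONTINUOUS_PATH"
    ORDERED = "ORDERED"
    BINARY = "BINARY"


def collapse_field_columns(
    columns: Mapping[ColumnKey, pd.Series], field_type: FieldType
) -> Tuple[pd.Series, str]:
    """Reduce a field's columns to a single per-participant vector.

    Only the first occurrence (lowest instance) is used. Continuous and
    integer fields with several array columns at that instance are averaged
    per participant over their non-missing values; a participant with all
    arrays missing stays missing. Returns the vector and a provenance label.
    """
    if not columns:
        raise ValueError("collapse_field_columns requires at least one column")
    first_instance = min(k.instance for k in columns)
    at_first = {k: s for k, s in columns.items() if k.instance == first_instance}
    keys = sorted(at_first)
    label = f"collapse:instance={first_instance},arrays={len(keys)}"
    if len(keys) == 1:
        return at_first[keys[0]].astype(float), label
    if field_type is FieldType.CAT_SINGLE:
        raise AmbiguousSingle(
            f"categorical (single) field {keys[0].field_id} has "
            f"{len(keys)} array columns at instance {first_instance}"
        )
    block = pd.concat([at_first[k] for k in keys], axis=1)
    return block.mean(axis=1, skipna=True), label


def recode_values(
    values: pd.Series,
    coding: Optional[DataCoding],
    field_type: FieldType,
) -> pd.Series:
    """Apply a data coding's reassignments, missingness rules and default.

    Reassignments run first; then, for categorical field types only,
    remaining negative values become missing (they denote answer categories
    such as "prefer not to answer"); finally the coding's default value, if
    any, is substituted for missing entries. Negative measurements of
    continuous/integer fields are left untouched unless explicitly
    reassigned.
    """
    out = values.astype(float).copy()
    if coding is not None and coding.reassignments:
        for old, new in coding.reassignments.items():
            mask = out == old
            out[mask] = np.nan if new is None else new
    if field_type in (FieldType.CAT_SINGLE, FieldType.CAT_MULTIPLE):
        out[out < 0] = np.nan
    if coding is not None and coding.default_value is not None:
        out = out.fillna(float(coding.default_value))
    return out


def inverse_rank_normal(values: pd.Series, seed: int = 1234) -> pd.Series:
    """Inverse-rank-normal transform: value -> Phi^-1((r - 0.5) / n).

    r is the 1-based rank among the n non-missing values. Tied values
    receive distinct ranks assigned uniformly at random under ``seed``, so
    the output is an exact permutation of the n normal quantiles. Missing
    entries stay missing.
    """
    out = values.astype(float).copy()
    mask = out.notna()
    v = out[mask].to_numpy()
    n = v.size
    if np.unique(v).size < 2:
        raise DegenerateDistribution("rank transform needs >= 2 distinct values")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    # stable sort after a random shuffle => uniformly random ranks among ties
    order = np.argsort(v[perm], kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[perm[order]] = np.arange(1, n + 1)
    out[mask] = stats.norm.ppf((ranks - 0.5) / n)
    return out


def needs_binning(values: pd.Series, dominance_threshold: float = 0.2) -> bool:
    """True when one value dominates the distribution.

    A vector where a large share of participants hold one value (e.g. zero
    alcohol intake) cannot be meaningfully rank-normalised — the ranks
    within the tie are random and would only add noise — so it is binned
    into ordered categories instead. The test is strict: a share exactly at
    the threshold does not trigger binning.
    """
    counts = values.dropna().value_counts()
    if counts.empty:
        return False
    return counts.iloc[0] / counts.sum() > dominance_threshold


def _bin_splits(counts: np.ndarray, k: int) -> Tuple[List[int], float]:
    """Choose k-1 split positions over distinct-value counts.

    Splits lie between distinct values; the objective minimises the largest
    absolute deviation of any category count from n/k, breaking ties toward
    the lexicographically smallest split positions. Returns the chosen
    boundary indices (a category spans distinct values [b_i, b_{i+1}))
    and the achieved objective.
    """
    d = counts.size
    n = counts.sum()
    target = n / k
    cum = np.concatenate([[0], np.cumsum(counts)])

    def objective(bounds: Sequence[int]) -> float:
        edges = [0, *bounds, d]
        return max(abs((cum[b] - cum[a]) - target) for a, b in zip(edges, edges[1:]))

    if math.comb(d - 1, k - 1) <= 100_000:
        best: Optional[Tuple[float, Tuple[int, ...]]] = None
        for bounds in itertools.combinations(range(1, d), k - 1):
            score = objective(bounds)
            if best is None or score < best[0]:
                best = (score, bounds)
        assert best is not None
        return list(best[1]), best[0]

    # dynamic program on suffixes for large numbers of distinct values
    INF = float("inf")
    suffix = np.full((d + 1, k + 1), INF)
    for i in range(d):
        suffix[i][1] = abs((cum[d] - cum[i]) - target)
    for r in range(2, k + 1):
        for i in range(d - r + 1):
            best_val = INF
            for j in range(i + 1, d - r + 2):
                val = max(abs((cum[j] - cum[i]) - target), suffix[j][r - 1])
                if val < best_val:
                    best_val = val
            suffix[i][r] = best_val
    bounds: List[int] = []
    i, r = 0, k
    while r > 1:
        for j in range(i + 1, d - r + 2):
            if max(abs((cum[j] - cum[i]) - target), suffix[j][r - 1]) == suffix[i][r]:
                bounds.append(j)
                i, r = j, r - 1
                break
    return bounds, objective(bounds)


def bin_to_ordered(
    values: pd.Series,
    k: int = 3,
    *,
    name: str = "binned",
    field_id: int = 0,
) -> DerivedVariable:
    """Bin a dominated continuous vector into k equal-mass ordered categories.

    Split points fall strictly between distinct observed values and are
    chosen to minimise the maximum deviation of category counts from n/k
    (ties resolved toward the lowest split values). Category labels 1..k
    preserve the value order. With more than 2 but fewer than k distinct
    values, each distinct value becomes its own category.
    """
    nonmiss = values.dropna()
    distinct = np.sort(nonmiss.unique())
    if distinct.size <= 2:
        raise DegenerateDistribution(
            f"binning needs > 2 distinct values, got {distinct.size}"
        )
    if distinct.size <= k:
        edges = list(range(1, distinct.size))
        n_cats = distinct.size
        label = f"bin:one_category_per_value,k={n_cats}"
    else:
        counts = nonmiss.value_counts().reindex(distinct).to_numpy()
        edges, score = _bin_splits(counts, k)
        n_cats = k
        label = f"bin:k={k},max_dev={score:g}"
    # boundaries as value thresholds: category i+1 starts at distinct[edge]
    cut_values = [distinct[e] for e in edges]
    cats = pd.Series(np.nan, index=values.index, dtype=float)
    cats[nonmiss.index] = 1.0 + np.searchsorted(
        np.asarray(cut_values), nonmiss.to_numpy(), side="right"
    )
    return DerivedVariable(
        name=name,
        field_id=field_id,
        data_type=DataType.ORDERED,
        values=cats,
        provenance=[label],
    )


def classify_integer(
    values: pd.Series, distinct_max: int = 20
) -> IntegerRoute:
    """Route an integer field by its number of distinct non-missing values.

    2 distinct -> binary; 3..``distinct_max`` -> ordered categorical in
    natural numeric order; more -> the continuous path (rank transform or
    binning). One or zero distinct values is degenerate.
    """
    n_distinct = values.dropna().nunique()
    if n_distinct <= 1:
        raise DegenerateDistribution("integer field with <= 1 distinct value")
    if n_distinct == 2:
        return IntegerRoute.BINARY
    if n_distinct <= distinct_max:
        return IntegerRoute.ORDERED
    return IntegerRoute.CONTINUOUS_PATH


def _encode_binary(values: pd.Series) -> pd.Series:
    """Map the two distinct non-missing values onto 0/1 preserving order."""
    lo, hi = np.sort(values.dropna().unique())
    out = pd.Series(np.nan, index=values.index, dtype=float)
    out[values == lo] = 0.0
    out[values == hi] = 1.0
    return out


def _encode_ordered(values: pd.Series, ordering: Optional[Sequence[float]]) -> pd.Series:
    """Replace raw values by ranks 1..K of the declared (or natural) ordering."""
    observed = values.dropna().unique()
    if ordering is not None:
        ranked = [v for v in ordering if v in set(observed)]
        dropped = set(observed) - set(ranked)
        if dropped:
            logger.warning("values %s absent from declared ordering -> missing", sorted(dropped))
    else:
        ranked = list(np.sort(observed))
    rank_of = {v: i + 1.0 for i, v in enumerate(ranked)}
    return values.map(rank_of)


def expand_cat_multiple(
    value_sets: "pd.Series",
    missingness_option: CatMultipleMissingness,
    coding: Optional[DataCoding] = None,
    *,
    field_id: int = 0,
) -> List[DerivedVariable]:
    """Expand a categorical (multiple) field into binary children.

    ``value_sets`` holds, per participant, the set of raw values observed
    across the field's array columns. One binary child is produced per
    distinct non-negative value v: a participant is TRUE for v iff v is in
    their set. FALSE membership depends on the missingness option (holders
    of another value / responders / everyone). Regardless of the option, a
    participant whose set contains a negative missingness code and lacks v
    is set to missing rather than FALSE — the unknown answer could have
    been v.
    """
    if coding is not None and coding.reassignments:
        def reassign_set(s):
            out = set()
            for v in s:
                if v in coding.reassignments:
                    new = coding.reassignments[v]
                    if new is not None:
                        out.add(new)
                else:
                    out.add(v)
            return out

        value_sets = value_sets.map(reassign_set)

    all_values = sorted({v for s in value_sets for v in s if v >= 0})
    if not all_values:
        raise EmptyExpansion(f"field {field_id}: no non-negative value observed")

    has_any = value_sets.map(bool)
    has_negative = value_sets.map(lambda s: any(v < 0 for v in s))
    has_nonneg = value_sets.map(lambda s: any(v >= 0 for v in s))

    children: List[DerivedVariable] = []
    for v in all_values:
        is_true = value_sets.map(lambda s, v=v: v in s)
        if missingness_option is CatMultipleMissingness.OTHER_VALUE_HOLDERS:
            in_false_pool = value_sets.map(
                lambda s, v=v: any(u >= 0 and u != v for u in s)
            )
        elif missingness_option is CatMultipleMissingness.RESPONDERS:
            in_false_pool = has_any
        else:  # ALL
            in_false_pool = pd.Series(True, index=value_sets.index)
        is_false = in_false_pool & ~is_true & ~has_negative
        out = pd.Series(np.nan, index=value_sets.index, dtype=float)
        out[is_false] = 0.0
        out[is_true] = 1.0
        name = f"{field_id}#{int(v) if float(v) == int(v) else v}"
        children.append(
            DerivedVariable(
                name=name,
                field_id=field_id,
                data_type=DataType.BINARY,
                values=out,
                provenance=[
                    f"cat_multiple_expand:value={v},option={missingness_option.value}"
                ],
            )
        )
    return children


def _gather_value_sets(columns: Mapping[ColumnKey, pd.Series]) -> pd.Series:
    """Collect each participant's set of values across a field's array columns."""
    first_instance = min(k.instance for k in columns)
    at_first = [s for k, s in sorted(columns.items()) if k.instance == first_instance]
    block = pd.concat(at_first, axis=1)

    def row_set(row):
        return {float(v) for v in row if pd.notna(v)}

    return block.apply(row_set, axis=1)


def _continuous_path(
    values: pd.Series,
    metadata: FieldMetadata,
    config: ProcessingConfig,
    provenance: List[str],
) -> Optional[DerivedVariable]:
    """Shared tail of the continuous and high-cardinality integer routes."""
    n_distinct = values.dropna().nunique()
    if n_distinct <= 1:
        return None
    name = str(metadata.field_id)
    if needs_binning(values, config.dominance_threshold):
        if n_distinct == 2:
            return DerivedVariable(
                name=name,
                field_id=metadata.field_id,
                data_type=DataType.BINARY,
                values=_encode_binary(values),
                provenance=[*provenance, "dominated:binary"],
            )
        binned = bin_to_ordered(
            values, config.n_bins, name=name, field_id=metadata.field_id
        )
        binned.provenance = [*provenance, "dominated", *binned.provenance]
        return binned
    transformed = inverse_rank_normal(values, config.field_seed(metadata.field_id))
    return DerivedVariable(
        name=name,
        field_id=metadata.field_id,
        data_type=DataType.CONTINUOUS,
        values=transformed,
        provenance=[*provenance, "irnt"],
    )


def process_field(
    metadata: FieldMetadata,
    columns: Mapping[ColumnKey, pd.Series],
    codings: Mapping[int, DataCoding],
    config: ProcessingConfig = ProcessingConfig(),
) -> Tuple[List[DerivedVariable], Optional[str]]:
    """Run one field through the decision flow.

    Returns (derived variables, removal reason). Exactly one of the two is
    non-empty: a field either emits at least one variable or is removed
    with a counted reason. Configuration errors (a categorical single field
    without a data code, or with ambiguous array columns) raise instead.
    """
    coding = None
    if metadata.data_code_id is not None:
        coding = codings.get(metadata.data_code_id)

    ft = metadata.field_type
    if ft in (FieldType.CONTINUOUS, FieldType.INTEGER):
        collapsed, label = collapse_field_columns(columns, ft)
        recoded = recode_values(collapsed, coding, ft)
        provenance = [label, "recode"]
        if ft is FieldType.INTEGER:
            try:
                route = classify_integer(recoded, config.integer_distinct_max)
            except DegenerateDistribution:
                return [], REMOVED_DEGENERATE
            name = str(metadata.field_id)
            if route is IntegerRoute.BINARY:
                return [
                    DerivedVariable(
                        name=name,
                        field_id=metadata.field_id,
                        data_type=DataType.BINARY,
                        values=_encode_binary(recoded),
                        provenance=[*provenance, "integer:binary"],
                    )
                ], None
            if route is IntegerRoute.ORDERED:
                return [
                    DerivedVariable(
                        name=name,
                        field_id=metadata.field_id,
                        data_type=DataType.ORDERED,
                        values=_encode_ordered(recoded, None),
                        provenance=[*provenance, "integer:ordered"],
                    )
                ], None
            provenance.append("integer:continuous_path")
        variable = _continuous_path(recoded, metadata, config, provenance)
        if variable is None:
            return [], REMOVED_DEGENERATE
        return [variable], None

    if ft is FieldType.CAT_SINGLE:
        if coding is None:
            raise MissingDataCode(
                f"categorical (single) field {metadata.field_id} has no data coding"
            )
        collapsed, label = collapse_field_columns(columns, ft)
        recoded = recode_values(collapsed, coding, ft)
        provenance = [label, "recode"]
        n_distinct = recoded.dropna().nunique()
        name = str(metadata.field_id)
        if n_distinct <= 1:
            return [], REMOVED_DEGENERATE
        if n_distinct == 2:
            return [
                DerivedVariable(
                    name=name,
                    field_id=metadata.field_id,
                    data_type=DataType.BINARY,
                    values=_encode_binary(recoded),
                    provenance=[*provenance, "cat_single:binary"],
                )
            ], None
        if coding.is_ordinal:
            return [
                DerivedVariable(
                    name=name,
                    field_id=metadata.field_id,
                    data_type=DataType.ORDERED,
                    values=_encode_ordered(recoded, coding.ordering),
                    provenance=[*provenance, "cat_single:ordered"],
                )
            ], None
        return [
            DerivedVariable(
                name=name,
                field_id=metadata.field_id,
                data_type=DataType.UNORDERED,
                values=recoded,
                provenance=[*provenance, "cat_single:unordered"],
            )
        ], None

    # CAT_MULTIPLE
    option = metadata.cat_multiple_missingness or CatMultipleMissingness.RESPONDERS
    sets = _gather_value_sets(columns)
    try:
        children = expand_cat_multiple(
            sets, option, coding, field_id=metadata.field_id
        )
    except EmptyExpansion:
        return [], REMOVED_EMPTY_EXPANSION
    return children, None


def process_all(
    metadata: Mapping[int, FieldMetadata],
    dataset: AnalysisDataset,
    codings: Mapping[int, DataCoding],
    config: ProcessingConfig = ProcessingConfig(),
) -> Tuple[List[DerivedVariable], FlowCounters]:
    """Process every field present in the dataset, honouring exclusions."""
    counters = FlowCounters()
    variables: List[DerivedVariable] = []
    for field_id in dataset.field_ids():
        meta = metadata.get(field_id)
        if meta is None:
            logger.warning("field %d present in data but not in variable info; skipped", field_id)
            continue
        counters.fields_entered += 1
        if meta.excluded:
            counters.record_removed(REMOVED_EXCLUDED)
            continue
        derived, removal = process_field(
            meta, dataset.field_columns(field_id), codings, config
        )
        if removal is not None:
            counters.record_removed(removal)
        else:
            counters.record_emit(derived)
            variables.extend(derived)
    logger.info(
        "processing flow: %d fields in, %d emitted (%s), removed %s",
        counters.fields_entered,
        counters.fields_emitted,
        dict(counters.variables_emitted),
        dict(counters.fields_removed),
    )
    return variables, counters


def export_derived(
    variables: Iterable[DerivedVariable],
    values_path,
    provenance_path,
) -> None:
    """Write derived variables to CSV (participants x variables) plus a
    TSV provenance log, so downstream users can run their own models."""
    variables = list(variables)
    if variables:
        table = pd.concat(
            {v.name: v.values for v in variables}, axis=1
        )
        table.index.name = "userId"
    else:
        table = pd.DataFrame()
    table.to_csv(values_path)
    prov = pd.DataFrame(
        {
            "name": [v.name for v in variables],
            "field_id": [v.field_id for v in variables],
            "data_type": [v.data_type.value for v in variables],
            "provenance": [";".join(v.provenance) for v in variables],
        }
    )
    prov.to_csv(provenance_path, sep="\t", index=False)
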