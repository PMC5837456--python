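"""phenoscan: automated rule-based phenome scans for biobank tables.

Given a phenotype table with thousands of heterogeneous fields, a trait of
interest and confounders, the engine decides per field how to code it
statistically (continuous, ordered, unordered or binary), runs the
matching regression, and returns ranked, Bonferroni-corrected results with
QQ/forest plot data and a hierarchical JSON export for visualization.
"""

from .association import (
    AssociationResult,
    ModelSpec,
    run_scan,
    test_linear,
    test_logistic,
    test_ordered,
    test_unordered_lrt,
)
from .metadata_io import (
    assemble_dataset,
    load_data_coding,
    load_variable_info,
    parse_column_key,
)
from .processing import (
    FlowCounters,
    ProcessingConfig,
    bin_to_ordered,
    classify_integer,
    collapse_field_columns,
    expand_cat_multiple,
    inverse_rank_normal,
    needs_binning,
    process_all,
    process_field,
    recode_values,
)
from .results import (
    ScanResults,
    forest_data,
    qq_points,
    rank_and_threshold,
    write_results_table,
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
from .viz import export_viz_json, validate_viz_document

__version__ = "0.1.0"


def derive_genotype_chip(batch, bileve_prefix: str = "UKBiLEVE"):
    """Derive a binary genotype-chip covariate from measurement-batch labels.

    Batches whose label starts with ``bileve_prefix`` are coded 1, all
    other batches 0. This is a convenience for the common case where a
    genetic trait of interest requires chip adjustment but only the batch
    label is on file; users with a different batch naming scheme should
    build the indicator themselves.
    """
    import pandas as pd

    batch = pd.Series(batch)
    return batch.astype(str).str.startswith(bileve_prefix).astype(float)
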