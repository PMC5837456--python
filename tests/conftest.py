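import pandas as pd
import pytest

from phenoscan.association import ModelSpec, run_scan
from phenoscan.metadata_io import parse_column_key
from phenoscan.processing import ProcessingConfig, process_all
from phenoscan.simulate import (
    FieldPlan,
    SimulationConfig,
    generate_cohort,
    write_cohort,
)
from phenoscan.types import AnalysisDataset, DataType, DerivedVariable


def make_dataset(columns: dict, trait: str, confounders=()) -> AnalysisDataset:
    """Build an AnalysisDataset directly from column vectors (no files)."""
    frame = pd.DataFrame(columns)
    frame.index.name = "userId"
    return AnalysisDataset(
        frame=frame,
        trait_column=trait,
        confounder_columns=list(confounders),
        phenotype_columns={},
    )


def make_variable(values, data_type=DataType.CONTINUOUS, name="v", field_id=1) -> DerivedVariable:
    return DerivedVariable(
        name=name,
        field_id=field_id,
        data_type=data_type,
        values=pd.Series(values, dtype=float),
        provenance=["test"],
    )


@pytest.fixture(scope="session")
def null_scan():
    """A null phenome scan: 500 variables (125 per data type), no true effects.

    The trait is independent of every phenotype, so the p-value
    distribution should be uniform. Shared session-wide because the
    multinomial and ordinal fits dominate suite runtime.
    """
    kinds = ["continuous", "integer_binary", "cat_single_ordinal", "cat_single_unordered"]
    plan = tuple(
        FieldPlan(field_id=1000 + i, kind=kinds[i % 4], missing_rate=0.0)
        for i in range(500)
    )
    config = SimulationConfig(n_participants=1500, seed=20260925, field_plan=plan)
    cohort = generate_cohort(config)
    frame = pd.concat([cohort.trait, cohort.confounders, cohort.pheno], axis=1)
    dataset = AnalysisDataset(
        frame=frame,
        trait_column="score",
        confounder_columns=["age", "sex"],
        phenotype_columns={
            parse_column_key(c): c for c in cohort.pheno.columns
        },
    )
    from phenoscan.simulate import generate_metadata_files

    metadata, codings = generate_metadata_files(config)
    derived, _ = process_all(
        {m.field_id: m for m in metadata},
        dataset,
        {c.coding_id: c for c in codings},
        ProcessingConfig(seed=20260925),
    )
    results, _ = run_scan(
        derived, dataset, ModelSpec(trait="score", confounders=["age", "sex"])
    )
    return results


@pytest.fixture(scope="session")
def small_cohort_files(tmp_path_factory):
    """A compact written-to-disk fixture cohort spanning all field kinds."""
    from phenoscan.simulate import default_field_plan, inject_associations

    config = SimulationConfig(
        n_participants=1200,
        seed=42,
        field_plan=default_field_plan(n_null_per_kind=1),
    )
    config = inject_associations(config, [1000], [0.4])
    cohort = generate_cohort(config)
    out = tmp_path_factory.mktemp("cohort")
    paths = write_cohort(cohort, out)
    return paths, cohort
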