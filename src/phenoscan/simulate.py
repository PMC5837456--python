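"""Synthetic biobank cohorts with known ground truth.

Generates self-consistent scan inputs — phenotype CSV, trait and
confounder files, variable-information and data-coding TSVs, and a small
category hierarchy — so the whole engine is testable without any real
biobank extract.

The trait of interest emulates a weighted allele score: a sum over
simulated biallelic variant dosages weighted by their effect sizes, then
standardised. Phenotypes are generated conditionally on the trait, age and
sex through the link appropriate to their family (identity for continuous,
cumulative logit for ordinal, logit for binary children, softmax for
unordered), so an injected effect size lives on the same scale the
regression estimates.

Field kinds span every branch of the processing flow: plain and
multi-array continuous fields, zero-inflated continuous fields, integer
fields straddling the 2/20/21-distinct boundaries, ordinal and unordered
single-valued categorical fields, and multi-valued categorical fields with
negative missingness codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .metadata_io import save_data_coding, save_variable_info
from .types import (
    CatMultipleMissingness,
    DataCoding,
    FieldMetadata,
    FieldType,
)

__all__ = [
    "FieldPlan",
    "SimulationConfig",
    "GroundTruth",
    "Cohort",
    "default_field_plan",
    "default_config",
    "generate_cohort",
    "generate_metadata_files",
    "inject_associations",
    "write_cohort",
]

FIELD_KINDS = (
    "continuous",
    "continuous_multiarray",
    "continuous_zero_inflated",
    "integer_binary",
    "integer_ordered",
    "integer_many",
    "cat_single_ordinal",
    "cat_single_unordered",
    "cat_multiple",
)

#: expected processing-flow routing per kind (used by coverage tests)
EXPECTED_ROUTING = {
    "continuous": "CONTINUOUS",
    "continuous_multiarray": "CONTINUOUS",
    "continuous_zero_inflated": "ORDERED",
    "integer_binary": "BINARY",
    "integer_ordered": "ORDERED",
    "integer_many": "CONTINUOUS",
    "cat_single_ordinal": "ORDERED",
    "cat_single_unordered": "UNORDERED",
    "cat_multiple": "BINARY",
}


@dataclass(frozen=True)
class FieldPlan:
    """Plan for one simulated field.

    ``effect`` is the true trait effect on the family's link scale (0 for a
    null field). ``missing_rate`` is the marginal probability that a
    participant's value is missing.
    """

    field_id: int
    kind: str
    effect: float = 0.0
    missing_rate: float = 0.02
    n_levels: int = 4  # ordinal / unordered category count
    excluded: bool = False
    trait_equivalent: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FIELD_KINDS:
            raise ConfigError(f"unknown field kind {self.kind!r} for field {self.field_id}")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError(f"field {self.field_id}: bad missing_rate {self.missing_rate}")

    @property
    def field_type(self) -> FieldType:
        if self.kind.startswith("continuous"):
            return FieldType.CONTINUOUS
        if self.kind.startswith("integer"):
            return FieldType.INTEGER
        if self.kind == "cat_multiple":
            return FieldType.CAT_MULTIPLE
        return FieldType.CAT_SINGLE


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic cohort."""

    n_participants: int = 5000
    seed: int = 1234
    field_plan: Tuple[FieldPlan, ...] = ()
    n_variants: int = 96  # variants entering the weighted allele score
    trait_noise_sd: float = 0.5
    age_effect: float = 0.1  # confounding: age enters most phenotypes
    sex_effect: float = 0.2

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        ids = [p.field_id for p in self.field_plan]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate field ids in field plan")


@dataclass
class GroundTruth:
    """Per-field truth: injected effect, intended data type and routing."""

    effects: Dict[int, float] = dc_field(default_factory=dict)
    routing: Dict[int, str] = dc_field(default_factory=dict)


@dataclass
class Cohort:
    """In-memory synthetic cohort plus its ground truth."""

    pheno: pd.DataFrame  # userId index, x<field>_<i>_<a> columns
    trait: pd.DataFrame  # userId index, column "score"
    confounders: pd.DataFrame  # userId index, columns "age", "sex"
    truth: GroundTruth
    config: SimulationConfig


def default_field_plan(
    base_field_id: int = 1000,
    n_null_per_kind: int = 5,
) -> Tuple[FieldPlan, ...]:
    """A plan covering every routing branch, all null effects.

    Produces ``n_null_per_kind`` fields of each of the nine kinds, plus one
    a-priori excluded field and one trait-equivalent continuous field.
    """
    plan: List[FieldPlan] = []
    fid = base_field_id
    for kind in FIELD_KINDS:
        for _ in range(n_null_per_kind):
            plan.append(FieldPlan(field_id=fid, kind=kind))
            fid += 1
    plan.append(FieldPlan(field_id=fid, kind="continuous", excluded=True))
    plan.append(FieldPlan(field_id=fid + 1, kind="continuous", trait_equivalent=True, effect=1.0))
    return tuple(plan)


def default_config(seed: int = 1234, n_participants: int = 5000) -> SimulationConfig:
    return SimulationConfig(
        n_participants=n_participants,
        seed=seed,
        field_plan=default_field_plan(),
    )


def inject_associations(
    config: SimulationConfig,
    targets: Sequence[int],
    sizes: Sequence[float],
) -> SimulationConfig:
    """Return a config with true effects set on the given fields."""
    if len(targets) != len(sizes):
        raise ConfigError("targets and sizes differ in length")
    known = {p.field_id for p in config.field_plan}
    effects = dict(zip(targets, sizes))
    unknown = set(effects) - known
    if unknown:
        raise ConfigError(f"unknown target fields {sorted(unknown)}")
    new_plan = tuple(
        replace(p, effect=effects[p.field_id]) if p.field_id in effects else p
        for p in config.field_plan
    )
    return replace(config, field_plan=new_plan)


def _simulate_trait(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Weighted allele score over simulated variant dosages, standardised."""
    n = config.n_participants
    freqs = rng.uniform(0.05, 0.5, size=config.n_variants)
    weights = np.abs(rng.normal(0.05, 0.02, size=config.n_variants))
    dosages = rng.binomial(2, freqs, size=(n, config.n_variants))
    score = dosages @ weights + rng.normal(0.0, config.trait_noise_sd, size=n)
    return (score - score.mean()) / score.std()


def _ordinal_from_latent(eta: np.ndarray, n_levels: int, rng: np.random.Generator) -> np.ndarray:
    """Cumulative-logit draw: latent = eta + logistic noise, cut at fixed
    thresholds spanning the bulk of the latent distribution."""
    latent = eta + rng.logistic(0.0, 1.0, size=eta.size)
    cuts = np.linspace(-2.0, 2.0, n_levels - 1)
    return np.digitize(latent, cuts).astype(float)  # 0..n_levels-1


def _apply_missing(values: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate > 0:
        mask = rng.uniform(size=values.size) < rate
        values = values.astype(float)
        values[mask] = np.nan
    return values


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _simulate_field(
    plan: FieldPlan,
    eta: np.ndarray,
    rng: np.random.Generator,
) -> Dict[str, np.ndarray]:
    """Generate the column(s) of one field; keys are column headers."""
    n = eta.size
    fid = plan.field_id
    kind = plan.kind
    if kind == "continuous":
        y = eta + rng.normal(0.0, 1.0, size=n)
        return {f"x{fid}_0_0": _apply_missing(y, plan.missing_rate, rng)}
    if kind == "continuous_multiarray":
        # repeat measurement: shared true value, small device noise per array
        true = eta + rng.normal(0.0, 1.0, size=n)
        cols = {}
        for a in range(3):
            y = true + rng.normal(0.0, 0.1, size=n)
            cols[f"x{fid}_0_{a}"] = _apply_missing(y, plan.missing_rate + 0.1 * a, rng)
        return cols
    if kind == "continuous_zero_inflated":
        # ~60% structural zeros; positive part log-normal shifted by eta
        zero = rng.uniform(size=n) < 0.6
        y = np.where(zero, 0.0, np.exp(0.5 * eta + rng.normal(1.0, 0.5, size=n)))
        return {f"x{fid}_0_0": _apply_missing(y, plan.missing_rate, rng)}
    if kind == "integer_binary":
        p = 1.0 / (1.0 + np.exp(-(eta - 0.4)))
        y = rng.binomial(1, p, size=n).astype(float)
        return {f"x{fid}_0_0": _apply_missing(y, plan.missing_rate, rng)}
    if kind == "integer_ordered":
        y = _ordinal_from_latent(eta, min(plan.n_levels + 2, 20), rng)
        return {f"x{fid}_0_0": _apply_missing(y, plan.missing_rate, rng)}
    if kind == "integer_many":
        lam = np.exp(3.0 + 0.2 * eta)
        y = rng.poisson(lam, size=n).astype(float)
        return {f"x{fid}_0_0": _apply_missing(y, plan.missing_rate, rng)}
    if kind == "cat_single_ordinal":
        y = _ordinal_from_latent(eta, plan.n_levels, rng) + 1.0  # codes 1..K
        y = _apply_missing(y, plan.missing_rate, rng)
        # a slice of "prefer not to answer" negative codes
        refuse = rng.uniform(size=n) < 0.01
        y[refuse & ~np.isnan(y)] = -1.0
        return {f"x{fid}_0_0": y}
    if kind == "cat_single_unordered":
        K = plan.n_levels
        alphas = np.linspace(-0.3, 0.3, K)
        betas = np.zeros(K)
        if plan.effect != 0.0:
            betas[1:] = plan.effect * np.linspace(0.5, 1.0, K - 1)
        logits = alphas[None, :] + betas[None, :] * eta[:, None]
        probs = _softmax(logits)
        cum = probs.cumsum(axis=1)
        u = rng.uniform(size=n)[:, None]
        y = (u > cum).sum(axis=1).astype(float) + 1.0  # codes 1..K
        return {f"x{fid}_0_0": _apply_missing(y, plan.missing_rate, rng)}
    # cat_multiple: 5 selectable values coded 100..104, 3 array slots,
    # negative code -7 = "not known", non-responders all-missing
    values = np.arange(100, 105, dtype=float)
    base_p = np.array([0.35, 0.25, 0.2, 0.12, 0.08])
    nonresponse = rng.uniform(size=n) < max(plan.missing_rate, 0.05)
    picks = np.zeros((n, values.size), dtype=bool)
    for j, v in enumerate(values):
        logit = np.log(base_p[j] / (1 - base_p[j]))
        if j == 0:
            logit = logit + plan.effect * eta
        p = 1.0 / (1.0 + np.exp(-logit))
        picks[:, j] = rng.uniform(size=n) < p
    notknown = rng.uniform(size=n) < 0.02
    cols = {f"x{fid}_0_{a}": np.full(n, np.nan) for a in range(3)}
    for i in range(n):
        if nonresponse[i]:
            continue
        chosen = list(values[picks[i]])[:3]
        if notknown[i] and len(chosen) < 3:
            chosen.append(-7.0)
        for a, v in enumerate(chosen):
            cols[f"x{fid}_0_{a}"][i] = v
    return cols


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate the full cohort described by ``config``.

    The same seed always yields the same cohort, bit for bit: each field
    draws from a child generator keyed on (seed, field id), so adding or
    reordering fields does not perturb the others.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    ids = np.arange(1, n + 1)
    trait = _simulate_trait(config, rng)
    age = rng.uniform(40, 70, size=n).round(0)
    sex = rng.binomial(1, 0.5, size=n).astype(float)

    truth = GroundTruth()
    columns: Dict[str, np.ndarray] = {}
    for plan in config.field_plan:
        field_rng = np.random.default_rng((config.seed, plan.field_id))
        eta = (
            plan.effect * trait
            + config.age_effect * (age - 55.0) / 10.0
            + config.sex_effect * sex
        )
        for name, col in _simulate_field(plan, eta, field_rng).items():
            columns[name] = col
        truth.effects[plan.field_id] = plan.effect
        truth.routing[plan.field_id] = EXPECTED_ROUTING[plan.kind]

    index = pd.Index(ids, name="userId")
    pheno = pd.DataFrame(columns, index=index)
    trait_frame = pd.DataFrame({"score": trait}, index=index)
    conf_frame = pd.DataFrame({"age": age, "sex": sex}, index=index)
    return Cohort(
        pheno=pheno, trait=trait_frame, confounders=conf_frame, truth=truth, config=config
    )


def generate_metadata_files(
    config: SimulationConfig,
) -> Tuple[List[FieldMetadata], List[DataCoding]]:
    """Metadata consistent with the generated cohort.

    Each categorical field gets a data coding: ordinal single-valued fields
    an ordered coding over their codes, unordered fields a non-ordinal
    coding, multi-valued fields a coding marking -7 as missing.
    """
    metadata: List[FieldMetadata] = []
    codings: Dict[int, DataCoding] = {}
    for plan in config.field_plan:
        code_id = None
        if plan.kind == "cat_single_ordinal":
            code_id = 100 + plan.n_levels
            codings.setdefault(
                code_id,
                DataCoding(
                    coding_id=code_id,
                    is_ordinal=True,
                    ordering=tuple(float(v) for v in range(1, plan.n_levels + 1)),
                ),
            )
        elif plan.kind == "cat_single_unordered":
            code_id = 200 + plan.n_levels
            codings.setdefault(code_id, DataCoding(coding_id=code_id, is_ordinal=False))
        elif plan.kind == "cat_multiple":
            code_id = 300
            codings.setdefault(
                code_id,
                DataCoding(coding_id=code_id, is_ordinal=False, reassignments={-7.0: None}),
            )
        metadata.append(
            FieldMetadata(
                field_id=plan.field_id,
                field_type=plan.field_type,
                data_code_id=code_id,
                excluded=plan.excluded,
                trait_equivalent=plan.trait_equivalent,
                cat_multiple_missingness=(
                    CatMultipleMissingness.RESPONDERS
                    if plan.kind == "cat_multiple"
                    else None
                ),
            )
        )
    return metadata, sorted(codings.values(), key=lambda c: c.coding_id)


def _hierarchy_tables(config: SimulationConfig) -> Tuple[pd.DataFrame, pd.DataFrame]:
    categories = pd.DataFrame(
        {
            "category_id": [1, 2, 3],
            "parent_id": [pd.NA, 1, 1],
            "title": ["Synthetic cohort", "Lifestyle", "Measures"],
        }
    )
    rows = []
    for i, plan in enumerate(config.field_plan):
        rows.append({"field_id": plan.field_id, "category_id": 2 if i % 2 else 3})
    return categories, pd.DataFrame(rows)


def write_cohort(cohort: Cohort, out_dir, split_files: bool = True) -> Dict[str, Path]:
    """Write the cohort and its metadata in the engine's input dialects.

    With ``split_files`` the trait and confounders go to their own CSVs;
    otherwise they are merged into the phenotype file. Also writes a
    combined file either way under ``combined.csv`` for equivalence tests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}

    combined = pd.concat([cohort.trait, cohort.confounders, cohort.pheno], axis=1)
    paths["combined"] = out / "combined.csv"
    combined.to_csv(paths["combined"])

    if split_files:
        paths["pheno"] = out / "phenotypes.csv"
        cohort.pheno.to_csv(paths["pheno"])
        paths["trait"] = out / "trait.csv"
        cohort.trait.to_csv(paths["trait"])
        paths["confounders"] = out / "confounders.csv"
        cohort.confounders.to_csv(paths["confounders"])
    else:
        paths["pheno"] = paths["combined"]

    metadata, codings = generate_metadata_files(cohort.config)
    paths["variable_info"] = out / "variable_info.tsv"
    save_variable_info(metadata, paths["variable_info"])
    paths["data_coding"] = out / "data_coding.tsv"
    save_data_coding(codings, paths["data_coding"])

    categories, field_cats = _hierarchy_tables(cohort.config)
    paths["hierarchy"] = out / "categories.tsv"
    categories.to_csv(paths["hierarchy"], sep="\t", index=False)
    paths["field_categories"] = out / "field_categories.tsv"
    field_cats.to_csv(paths["field_categories"], sep="\t", index=False)
    return paths
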