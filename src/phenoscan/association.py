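"""Regression dispatch: test each derived variable against the trait.

The derived phenotype is always the dependent variable and the trait of
interest the independent variable. Continuous outcomes use linear
regression, binary outcomes binomial (logistic) regression, ordered
categorical outcomes proportional-odds ordinal logistic regression, and
unordered categorical outcomes multinomial logistic regression with a
likelihood-ratio model p-value. All models adjust for the configured
confounders (by default age at recruitment and sex; plus a genotype-chip
indicator when the trait is genetic; or exactly the columns of a
user-supplied confounder file).

Scan-level filters: variables with fewer than 500 complete cases are not
tested, and unordered variables with more than 1000 categories are not
tested; both removals are counted, not errored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .exceptions import (
    CategoryLimitExceeded,
    DegenerateExposure,
    DegenerateOutcome,
)
from .processing import (
    REMOVED_CATEGORY_LIMIT,
    REMOVED_DEGENERATE,
    REMOVED_SAMPLE_SIZE,
    FlowCounters,
)
from .types import AnalysisDataset, DataType, DerivedVariable

logger = logging.getLogger("phenoscan")

__all__ = [
    "ModelSpec",
    "AssociationResult",
    "MIN_SAMPLE_SIZE",
    "MAX_UNORDERED_CATEGORIES",
    "test_linear",
    "test_logistic",
    "test_ordered",
    "test_unordered_lrt",
    "run_scan",
]

#: Variables with fewer complete cases than this are not tested.
MIN_SAMPLE_SIZE = 500
#: Unordered variables with more categories than this are not tested.
MAX_UNORDERED_CATEGORIES = 1000


@dataclass(frozen=True)
class ModelSpec:
    """Which columns enter each regression, and how p-values are formed.

    ``ordered_p_method`` selects the p-value for the proportional-odds
    model: "lrt" (default, likelihood-ratio test of trait inclusion) or
    "wald".
    """

    trait: str
    confounders: Sequence[str] = ()
    ordered_p_method: str = "lrt"

    def __post_init__(self) -> None:
        if self.trait in self.confounders:
            raise ValueError("trait must not appear among the confounders")


@dataclass
class AssociationResult:
    """One tested variable's regression summary.

    ``estimate`` is the trait coefficient (linear: beta on the transformed
    outcome scale; logistic and ordered: odds ratio per unit trait).
    Unordered models report only a likelihood-ratio p-value — there is no
    single overall estimate, so estimate and CI are absent.
    """

    name: str
    field_id: int
    data_type: DataType
    n: int
    estimate: Optional[float]
    ci_lower: Optional[float]
    ci_upper: Optional[float]
    p_value: Optional[float]
    converged: bool = True
    validation_only: bool = False
    below_threshold: Optional[bool] = None


def _complete_cases(
    outcome: DerivedVariable, data: AnalysisDataset, spec: ModelSpec
) -> Tuple[pd.Series, pd.Series, pd.DataFrame]:
    """Restrict to rows where outcome, trait and all confounders are present.

    Confounders that are constant on the complete cases (e.g. sex for a
    sex-specific field) are dropped with a log notice rather than breaking
    the fit.
    """
    y = outcome.values.reindex(data.frame.index)
    cols = pd.concat(
        [y.rename("__outcome__"), data.frame[[spec.trait, *spec.confounders]]], axis=1
    ).dropna()
    y = cols["__outcome__"]
    trait = cols[spec.trait]
    conf = cols[list(spec.confounders)]
    constant = [c for c in conf.columns if conf[c].nunique() <= 1]
    if constant:
        logger.info("%s: dropping constant confounders %s", outcome.name, constant)
        conf = conf.drop(columns=constant)
    return y, trait, conf


def _design(trait: pd.Series, conf: pd.DataFrame) -> pd.DataFrame:
    X = pd.concat([trait, conf], axis=1)
    return sm.add_constant(X, has_constant="add")


def _check_exposure(trait: pd.Series) -> None:
    if trait.nunique() <= 1:
        raise DegenerateExposure("trait of interest is constant on complete cases")


def test_linear(
    outcome: DerivedVariable, data: AnalysisDataset, spec: ModelSpec
) -> AssociationResult:
    """Linear regression of a (rank-normalised) continuous outcome on the trait."""
    y, trait, conf = _complete_cases(outcome, data, spec)
    _check_exposure(trait)
    X = _design(trait, conf)
    converged = True
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        converged = False
    fit = sm.OLS(y, X).fit()
    est = float(fit.params[spec.trait])
    ci = fit.conf_int().loc[spec.trait]
    p = float(fit.pvalues[spec.trait])
    return AssociationResult(
        name=outcome.name,
        field_id=outcome.field_id,
        data_type=DataType.CONTINUOUS,
        n=len(y),
        estimate=est,
        ci_lower=float(ci[0]),
        ci_upper=float(ci[1]),
        p_value=None if np.isnan(p) else p,
        converged=converged,
    )


def test_logistic(
    outcome: DerivedVariable, data: AnalysisDataset, spec: ModelSpec
) -> AssociationResult:
    """Binomial regression of a binary outcome; estimate is an odds ratio."""
    y, trait, conf = _complete_cases(outcome, data, spec)
    _check_exposure(trait)
    if y.nunique() < 2:
        raise DegenerateOutcome(f"{outcome.name}: single outcome class")
    X = _design(trait, conf)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        converged = bool(fit.mle_retvals.get("converged", True))
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return AssociationResult(
            name=outcome.name,
            field_id=outcome.field_id,
            data_type=DataType.BINARY,
            n=len(y),
            estimate=None,
            ci_lower=None,
            ci_upper=None,
            p_value=None,
            converged=False,
        )
    beta = float(fit.params[spec.trait])
    ci = fit.conf_int().loc[spec.trait]
    p = float(fit.pvalues[spec.trait])
    return AssociationResult(
        name=outcome.name,
        field_id=outcome.field_id,
        data_type=DataType.BINARY,
        n=len(y),
        estimate=float(np.exp(beta)),
        ci_lower=float(np.exp(ci[0])),
        ci_upper=float(np.exp(ci[1])),
        p_value=None if np.isnan(p) else (p if converged else None),
        converged=converged,
    )


def _saturated_ordinal_loglik(y: pd.Series) -> float:
    """Log-likelihood of the intercepts-only cumulative-logit model.

    With no covariates the proportional-odds model saturates the marginal
    category probabilities, so the maximised log-likelihood has the closed
    form sum_k n_k log(n_k / n).
    """
    counts = y.value_counts().to_numpy(dtype=float)
    n = counts.sum()
    return float(np.sum(counts * np.log(counts / n)))


def _fit_ordered(y: pd.Series, X: Optional[pd.DataFrame]):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(y, X, distr="logit")
        return model.fit(method="bfgs", maxiter=500, gtol=1e-08, disp=0)


def test_ordered(
    outcome: DerivedVariable, data: AnalysisDataset, spec: ModelSpec
) -> AssociationResult:
    """Proportional-odds ordinal logistic regression.

    The estimate is the odds ratio per unit trait with a Wald 95% CI; the
    p-value is by default from the likelihood-ratio test of adding the
    trait to the confounder-only model. Outcome levels empty on the
    complete cases simply do not appear (pandas drops them), equivalent to
    collapsing the scale. Two-level outcomes are accepted; the model then
    coincides with binary logistic regression.
    """
    y, trait, conf = _complete_cases(outcome, data, spec)
    _check_exposure(trait)
    if y.nunique() < 2:
        raise DegenerateOutcome(f"{outcome.name}: single outcome level")
    X_full = pd.concat([trait, conf], axis=1)
    try:
        fit = _fit_ordered(y, X_full)
        converged = bool(fit.mle_retvals.get("converged", True))
        if spec.ordered_p_method == "lrt":
            if conf.shape[1] == 0:
                ll0 = _saturated_ordinal_loglik(y)
            else:
                ll0 = float(_fit_ordered(y, conf).llf)
            lr = 2.0 * (float(fit.llf) - ll0)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
        else:
            p = float(fit.pvalues[spec.trait])
    except (np.linalg.LinAlgError, ValueError):
        return AssociationResult(
            name=outcome.name,
            field_id=outcome.field_id,
            data_type=DataType.ORDERED,
            n=len(y),
            estimate=None,
            ci_lower=None,
            ci_upper=None,
            p_value=None,
            converged=False,
        )
    beta = float(fit.params[spec.trait])
    ci = fit.conf_int().loc[spec.trait]
    return AssociationResult(
        name=outcome.name,
        field_id=outcome.field_id,
        data_type=DataType.ORDERED,
        n=len(y),
        estimate=float(np.exp(beta)),
        ci_lower=float(np.exp(ci[0])),
        ci_upper=float(np.exp(ci[1])),
        p_value=p if converged else None,
        converged=converged,
    )


def _fit_multinomial(y_codes: np.ndarray, X: pd.DataFrame):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.MNLogit(y_codes, X).fit(method="bfgs", maxiter=300, disp=0)


def test_unordered_lrt(
    outcome: DerivedVariable, data: AnalysisDataset, spec: ModelSpec
) -> AssociationResult:
    """Multinomial logistic regression with a likelihood-ratio model p-value.

    The full model (trait + confounders) is compared against the null
    (confounders only); the statistic 2(l_full - l_null) is referred to a
    chi-square with K-1 degrees of freedom, K the number of outcome
    categories. No single overall estimate exists, so estimate and CI are
    absent.
    """
    y, trait, conf = _complete_cases(outcome, data, spec)
    _check_exposure(trait)
    categories = np.sort(y.unique())
    K = categories.size
    if K > MAX_UNORDERED_CATEGORIES:
        raise CategoryLimitExceeded(
            f"{outcome.name}: {K} categories exceeds {MAX_UNORDERED_CATEGORIES}"
        )
    if K < 2:
        raise DegenerateOutcome(f"{outcome.name}: single outcome category")
    codes = np.searchsorted(categories, y.to_numpy())
    X_full = _design(trait, conf)
    X_null = sm.add_constant(conf, has_constant="add")
    try:
        full = _fit_multinomial(codes, X_full)
        null = _fit_multinomial(codes, X_null)
        converged = bool(full.mle_retvals.get("converged", True)) and bool(
            null.mle_retvals.get("converged", True)
        )
    except (np.linalg.LinAlgError, ValueError):
        return AssociationResult(
            name=outcome.name,
            field_id=outcome.field_id,
            data_type=DataType.UNORDERED,
            n=len(y),
            estimate=None,
            ci_lower=None,
            ci_upper=None,
            p_value=None,
            converged=False,
        )
    lr = 2.0 * (float(full.llf) - float(null.llf))
    p = float(stats.chi2.sf(max(lr, 0.0), df=K - 1))
    return AssociationResult(
        name=outcome.name,
        field_id=outcome.field_id,
        data_type=DataType.UNORDERED,
        n=len(y),
        estimate=None,
        ci_lower=None,
        ci_upper=None,
        p_value=p if converged else None,
        converged=converged,
    )


_DISPATCH = {
    DataType.CONTINUOUS: test_linear,
    DataType.BINARY: test_logistic,
    DataType.ORDERED: test_ordered,
    DataType.UNORDERED: test_unordered_lrt,
}


def run_scan(
    derived: Iterable[DerivedVariable],
    data: AnalysisDataset,
    spec: ModelSpec,
    validation_fields: Optional[Set[int]] = None,
    counters: Optional[FlowCounters] = None,
) -> Tuple[List[AssociationResult], FlowCounters]:
    """Test every derived variable, applying the scan-level filters.

    Variables with fewer than 500 complete cases, or unordered variables
    exceeding the category limit, are removed and counted. A failure in any
    single model is logged and counted; the scan never aborts on one
    variable. Results for fields flagged trait-equivalent are marked
    validation-only (they are reported but excluded from the
    multiple-testing burden downstream).
    """
    validation_fields = validation_fields or set()
    counters = counters if counters is not None else FlowCounters()
    results: List[AssociationResult] = []
    for variable in derived:
        y, trait, conf = _complete_cases(variable, data, spec)
        if len(y) < MIN_SAMPLE_SIZE:
            counters.record_removed(REMOVED_SAMPLE_SIZE)
            logger.info("%s: n=%d < %d, not tested", variable.name, len(y), MIN_SAMPLE_SIZE)
            continue
        if (
            variable.data_type is DataType.UNORDERED
            and y.nunique() > MAX_UNORDERED_CATEGORIES
        ):
            counters.record_removed(REMOVED_CATEGORY_LIMIT)
            logger.info(
                "%s: %d categories > %d, not tested",
                variable.name,
                y.nunique(),
                MAX_UNORDERED_CATEGORIES,
            )
            continue
        try:
            result = _DISPATCH[variable.data_type](variable, data, spec)
        except (DegenerateOutcome, DegenerateExposure, CategoryLimitExceeded) as exc:
            counters.record_removed(REMOVED_DEGENERATE)
            logger.warning("%s: not tested (%s)", variable.name, exc)
            continue
        result.validation_only = variable.field_id in validation_fields
        results.append(result)
    return results, counters
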