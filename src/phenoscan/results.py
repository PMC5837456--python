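"""Ranking, multiple-testing correction and results output.

Results are ranked by ascending p-value and annotated against the
Bonferroni-corrected family-wise threshold alpha / m, where m counts the
tests that contribute to the multiple-testing burden (validation-only
results — phenotypes flagged a priori as aspects of the trait itself — are
reported but excluded from m). The module also computes QQ-plot points and
per-data-type forest-plot tables; plot rendering is kept separate from
plot-data computation so tests assert on tables, not images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .association import AssociationResult
from .exceptions import NoTests
from .types import DataType

logger = logging.getLogger("phenoscan")

__all__ = [
    "ScanResults",
    "rank_and_threshold",
    "qq_points",
    "forest_data",
    "write_results_table",
    "qq_plot",
    "forest_plots",
]

RESULTS_COLUMNS = [
    "name",
    "field_id",
    "data_type",
    "n",
    "estimate",
    "ci_lower",
    "ci_upper",
    "p_value",
    "below_threshold",
    "validation_only",
    "converged",
]


@dataclass
class ScanResults:
    """Ranked results with the family-wise correction applied."""

    results: List[AssociationResult]
    m_tests: int
    alpha: float
    threshold: float


def rank_and_threshold(
    results: Sequence[AssociationResult], alpha: float = 0.05
) -> ScanResults:
    """Rank results by ascending p and apply the Bonferroni threshold.

    m counts non-validation results that produced a p-value; the threshold
    is alpha / m. Every result with a p-value (validation ones included) is
    annotated ``below_threshold`` by strict comparison p < threshold. Ties
    in p break by field id; results without a p-value sort last.
    """
    countable = [r for r in results if not r.validation_only and r.p_value is not None]
    m = len(countable)
    if m == 0:
        raise NoTests("no countable test produced a p-value")
    threshold = alpha / m
    ranked = sorted(
        results,
        key=lambda r: (r.p_value is None, r.p_value if r.p_value is not None else 0.0, r.field_id),
    )
    for r in ranked:
        r.below_threshold = (r.p_value < threshold) if r.p_value is not None else None
    logger.info(
        "ranked %d results; m_tests=%d, Bonferroni threshold %.3g",
        len(ranked),
        m,
        threshold,
    )
    return ScanResults(results=ranked, m_tests=m, alpha=alpha, threshold=threshold)


def qq_points(results: Sequence[AssociationResult]) -> Tuple[np.ndarray, np.ndarray]:
    """Expected and observed -log10 p sequences for a QQ plot.

    With m p-values, the expected order statistics are -log10((i - 0.5)/m)
    for i = 1..m; both sequences are returned in increasing order so that
    pairing is quantile-against-quantile.
    """
    p = np.array([r.p_value for r in results if r.p_value is not None], dtype=float)
    if p.size == 0:
        raise NoTests("no p-values available for a QQ plot")
    m = p.size
    expected = np.sort(-np.log10((np.arange(1, m + 1) - 0.5) / m))
    # p-values can underflow to exactly 0; clip so -log10 stays finite
    observed = np.sort(-np.log10(np.clip(p, np.finfo(float).tiny, 1.0)))
    return expected, observed


def forest_data(scan: ScanResults) -> Dict[str, pd.DataFrame]:
    """Per-data-type tables of below-threshold effects for forest plots.

    Continuous results report betas, ordered and binary results odds
    ratios, each with 95% CI bounds. Unordered results carry no overall
    estimate and are excluded from every table.
    """
    tables: Dict[str, pd.DataFrame] = {}
    for dtype, label in [
        (DataType.CONTINUOUS, "continuous"),
        (DataType.ORDERED, "ordered"),
        (DataType.BINARY, "binary"),
    ]:
        rows = [
            {
                "name": r.name,
                "field_id": r.field_id,
                "estimate": r.estimate,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "p_value": r.p_value,
            }
            for r in scan.results
            if r.data_type is dtype and r.below_threshold and r.estimate is not None
        ]
        tables[label] = pd.DataFrame(
            rows, columns=["name", "field_id", "estimate", "ci_lower", "ci_upper", "p_value"]
        )
    return tables


def write_results_table(scan: ScanResults, path) -> None:
    """Write the ranked results as a TSV with a fixed column schema."""
    rows = []
    for r in scan.results:
        rows.append(
            {
                "name": r.name,
                "field_id": r.field_id,
                "data_type": r.data_type.value,
                "n": r.n,
                "estimate": "" if r.estimate is None else repr(r.estimate),
                "ci_lower": "" if r.ci_lower is None else repr(r.ci_lower),
                "ci_upper": "" if r.ci_upper is None else repr(r.ci_upper),
                "p_value": "" if r.p_value is None else repr(r.p_value),
                "below_threshold": "" if r.below_threshold is None else r.below_threshold,
                "validation_only": r.validation_only,
                "converged": r.converged,
            }
        )
    pd.DataFrame(rows, columns=RESULTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results_table(path) -> List[AssociationResult]:
    """Read a results TSV back into AssociationResult records."""
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")

    def opt(x) -> Optional[float]:
        return None if pd.isna(x) else float(x)

    out = []
    for _, row in table.iterrows():
        out.append(
            AssociationResult(
                name=str(row["name"]),
                field_id=int(row["field_id"]),
                data_type=DataType(row["data_type"]),
                n=int(row["n"]),
                estimate=opt(row["estimate"]),
                ci_lower=opt(row["ci_lower"]),
                ci_upper=opt(row["ci_upper"]),
                p_value=opt(row["p_value"]),
                converged=bool(row["converged"]),
                validation_only=bool(row["validation_only"]),
                below_threshold=None if pd.isna(row["below_threshold"]) else bool(row["below_threshold"]),
            )
        )
    return out


def qq_plot(scan: ScanResults, path) -> None:
    """Render the QQ plot (observed vs expected -log10 p) to a vector file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    expected, observed = qq_points(scan.results)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(expected, observed, "o", ms=3, color="#1f77b4")
    lim = max(expected.max(), observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], ":", color="grey", label="actual = expected")
    ax.axhline(-np.log10(scan.threshold), ls="--", color="firebrick", lw=0.8,
               label=f"Bonferroni threshold p = {scan.threshold:.3g}")
    ax.set_xlabel("expected $-\\log_{10}(p)$")
    ax.set_ylabel("observed $-\\log_{10}(p)$")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def forest_plots(scan: ScanResults, out_dir) -> List[str]:
    """Render one forest plot per data type with below-threshold results.

    Returns the paths written; data types with no below-threshold results
    are skipped with a log notice. Unordered results never appear (no
    overall estimate exists for the multinomial model).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: List[str] = []
    tables = forest_data(scan)
    for label, table in tables.items():
        if table.empty:
            logger.info("no below-threshold %s results; forest plot skipped", label)
            continue
        null_line = 0.0 if label == "continuous" else 1.0
        fig, ax = plt.subplots(figsize=(6, max(2, 0.3 * len(table) + 1)))
        ypos = np.arange(len(table))[::-1]
        est = table["estimate"].to_numpy()
        ax.errorbar(
            est,
            ypos,
            xerr=[
                est - table["ci_lower"].to_numpy(),
                table["ci_upper"].to_numpy() - est,
            ],
            fmt="s",
            ms=4,
            color="black",
            ecolor="black",
            elinewidth=0.8,
            capsize=2,
        )
        ax.axvline(null_line, ls=":", color="grey")
        ax.set_yticks(ypos)
        ax.set_yticklabels(table["name"])
        ax.set_xlabel("beta (95% CI)" if label == "continuous" else "odds ratio (95% CI)")
        ax.set_title(f"{label} results below threshold")
        fig.tight_layout()
        path = out_dir / f"forest_{label}.svg"
        fig.savefig(path)
        plt.close(fig)
        written.append(str(path))
    return written
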