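"""Pearson correlation screen of per-sample complementarity scores against
gene-expression panels.

For each gene in a panel the sample CS is correlated with normalized
expression over the cases present in both inputs (inner join on case id).
Raw two-sided p-values come from the t-transform of r on n-2 degrees of
freedom; a Benjamini–Hochberg adjusted column is added across the panel but
no rows are filtered — the ranked table keeps every gene, significant or
not.  Correlations use linear expression values by default; a log2(x+1)
transform is available as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ScoreRecord
from .exceptions import JoinError, UndefinedStatisticError, ValidationError


@dataclass(frozen=True)
class CorrelationRow:
    """One panel gene's correlation with the complementarity score."""

    gene: str
    r: float
    p: float
    p_adj: float
    n: int


def validate_expression_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the cases-by-genes invariants: unique labels, finite, nonnegative."""
    if expr.index.duplicated().any():
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate case ids in expression matrix: {dupes}")
    if expr.columns.duplicated().any():
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene symbols: {dupes}")
    values = expr.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("expression matrix contains non-finite values")
    if (values < 0).any():
        raise ValidationError("expression values must be nonnegative")
    return expr


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with its two-sided p-value.

    p is the two-sided tail of t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom.  Requires n >= 3 and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("pearson requires equal-length vectors")
    n = x.size
    if n < 3:
        raise ValidationError(f"pearson requires n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            "correlation undefined for a zero-variance vector"
        )
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_screen(scores: Iterable[ScoreRecord], expr: pd.DataFrame,
                       panel: Sequence[str], log2_transform: bool = False,
                       ) -> tuple[list[CorrelationRow], list[str]]:
    """Correlate per-sample CS against each panel gene over the shared cases.

    Returns the ranked rows (ascending raw p, ties broken by descending |r|
    then gene symbol) and a list of warnings for genes that were absent
    from the matrix or had constant expression; those genes are skipped,
    not fatal.  BH adjustment is computed across the genes actually tested.
    """
    validate_expression_matrix(expr)
    cs_by_case = {r.case_id: r.cs for r in scores}
    shared = [c for c in expr.index if c in cs_by_case]
    if len(shared) < 3:
        raise JoinError(
            f"only {len(shared)} cases shared between scores and expression; "
            "need at least 3"
        )
    cs = np.array([cs_by_case[c] for c in shared])
    warnings: list[str] = []
    tested: list[tuple[str, float, float]] = []
    for gene in panel:
        if gene not in expr.columns:
            warnings.append(f"gene {gene!r} absent from expression matrix; skipped")
            continue
        values = expr.loc[shared, gene].to_numpy(dtype=float)
        if log2_transform:
            values = np.log2(values + 1.0)
        try:
            r, p = pearson(cs, values)
        except UndefinedStatisticError:
            warnings.append(f"gene {gene!r} has constant expression; skipped")
            continue
        tested.append((gene, r, p))
    if not tested:
        raise JoinError("no panel gene could be tested")
    raw_p = [p for _, _, p in tested]
    _, p_adj, _, _ = multipletests(raw_p, method="fdr_bh")
    rows = [
        CorrelationRow(gene, r, p, float(pa), len(shared))
        for (gene, r, p), pa in zip(tested, p_adj)
    ]
    rows.sort(key=lambda row: (row.p, -abs(row.r), row.gene))
    return rows, warnings


def rows_to_frame(rows: list[CorrelationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene": r.gene, "r": r.r, "p": r.p, "p_adj": r.p_adj, "n": r.n}
         for r in rows]
    )


def scatter_data(scores: Iterable[ScoreRecord], expr: pd.DataFrame,
                 gene: str, log2_transform: bool = False) -> pd.DataFrame:
    """Per-case (cs, expression) pairs for one gene, for scatter plotting."""
    cs_by_case = {r.case_id: r.cs for r in scores}
    shared = [c for c in expr.index if c in cs_by_case]
    values = expr.loc[shared, gene].to_numpy(dtype=float)
    if log2_transform:
        values = np.log2(values + 1.0)
    return pd.DataFrame(
        {"case_id": shared,
         "cs": [cs_by_case[c] for c in shared],
         "expression": values}
    )
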