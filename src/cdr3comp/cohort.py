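"""Per-sample score aggregation and median-split cohort stratification.

Each sample contributes many CDR3s; the sample's complementarity score (CS)
against an antigen is an aggregate over its CDR3-level pair scores — by
default the maximum, on the view that a single strongly complementary clone
is the salient event (the mean is available for sensitivity analysis).
The cohort is then split at the median CS: cases strictly above the median
form the upper group, everything else the lower, so with an odd count or
ties at the median the lower group is the larger one.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Sequence

import math

import pandas as pd

from .exceptions import DegenerateSplitError, ValidationError

AGGREGATION_METHODS = ("max", "mean")


@dataclass(frozen=True)
class ScoreRecord:
    """Aggregated complementarity score of one case against one antigen label."""

    case_id: str
    antigen_label: str
    cs: float
    n_cdr3: int

    def __post_init__(self) -> None:
        if self.n_cdr3 < 1:
            raise ValidationError("ScoreRecord requires n_cdr3 >= 1")
        if not math.isfinite(self.cs):
            raise ValidationError("ScoreRecord requires a finite cs")


@dataclass(frozen=True)
class StratifiedCohort:
    """Upper/lower 50th-percentile split of scored cases at ``threshold``."""

    upper: frozenset[str]
    lower: frozenset[str]
    threshold: float


def aggregate_sample_score(case_id: str, antigen_label: str,
                           cdr3_scores: Sequence[float],
                           method: str = "max") -> ScoreRecord:
    """Collapse one case's CDR3-level pair scores into a single CS.

    Cases with no recovered CDR3s are excluded upstream (the analysis is
    restricted to samples with receptor recombination-read recoveries), so
    an empty list is an error here.
    """
    if not cdr3_scores:
        raise ValidationError(
            f"case {case_id!r} has no CDR3 scores to aggregate"
        )
    if method not in AGGREGATION_METHODS:
        raise ValidationError(f"unknown aggregation method {method!r}")
    cs = max(cdr3_scores) if method == "max" else sum(cdr3_scores) / len(cdr3_scores)
    return ScoreRecord(case_id, antigen_label, float(cs), len(cdr3_scores))


def aggregate_matrix(matrix: pd.DataFrame, column: str,
                     method: str = "max") -> list[ScoreRecord]:
    """ScoreRecords for one antigen column of a score matrix.

    Matrix rows are labelled ``case_id:chain:sequence`` (see
    :func:`cdr3comp.scoring.score_matrix`); all CDR3s of a case, both
    chains, pool into one repertoire.
    """
    by_case: dict[str, list[float]] = {}
    for row_label, value in matrix[column].items():
        case_id = str(row_label).split(":", 1)[0]
        by_case.setdefault(case_id, []).append(float(value))
    return [
        aggregate_sample_score(case_id, column, scores, method)
        for case_id, scores in sorted(by_case.items())
    ]


def stratify_median(records: Iterable[ScoreRecord]) -> StratifiedCohort:
    """Split scored cases at the median CS.

    Cases with CS strictly greater than the median go to the upper group;
    ties at the median go to the lower group, which therefore is at least
    as large.  Requires >= 4 cases (the minimum for a meaningful two-group
    survival comparison) and at least two distinct CS values.
    """
    records = list(records)
    if len(records) < 4:
        raise ValidationError(
            f"stratification needs >= 4 scored cases, got {len(records)}"
        )
    seen = set()
    for r in records:
        if r.case_id in seen:
            raise ValidationError(f"duplicate case id {r.case_id!r}")
        seen.add(r.case_id)
    threshold = float(median(r.cs for r in records))
    upper = frozenset(r.case_id for r in records if r.cs > threshold)
    lower = frozenset(r.case_id for r in records if r.cs <= threshold)
    if not upper:
        raise DegenerateSplitError(
            "all complementarity scores are at or below the median; "
            "no upper group can be formed"
        )
    return StratifiedCohort(upper, lower, threshold)
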