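"""Readers and writers for the plain-text formats the pipeline exchanges.

Dialects: FASTA (antigens, fragments, reads), FASTQ (reads; qualities
ignored), tab-separated CDR3 tables with header ``case_id  chain  cdr3_aa``,
and comma-separated tables (header row mandatory, UTF-8, '.' decimal) for
scores, stratifications, survival, expression, KM curves and correlation
results.  Every writer's output round-trips through its reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .association import CorrelationRow, rows_to_frame, validate_expression_matrix
from .cohort import ScoreRecord, StratifiedCohort
from .exceptions import ValidationError
from .recovery import ReadRecord
from .survival import KMCurve, LogrankResult, SurvivalRecord

CDR3_COLUMNS = ["case_id", "chain", "cdr3_aa"]


def read_fasta(path) -> list[tuple[str, str]]:
    """(name, sequence) pairs; names from the first token of the header,
    sequences upper-cased with wrapped lines joined.  Empty records are a
    parse error."""
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        seq = str(rec.seq).upper()
        if not rec.id:
            raise ValidationError(f"{path}: record {i} has an empty header")
        if not seq:
            raise ValidationError(
                f"{path}: record {i} ({rec.id!r}) has an empty sequence"
            )
        records.append((rec.id, seq))
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_reads(path) -> list[ReadRecord]:
    """Raw reads from FASTA or FASTQ (by extension; qualities ignored)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [ReadRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), fmt)]


def read_cdr3_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != CDR3_COLUMNS:
        raise ValidationError(
            f"{path}: expected tab-separated header {CDR3_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    df["case_id"] = df["case_id"].str.strip()
    return df


def write_cdr3_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_survival_csv(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path)
    expected = ["case_id", "time_months", "event"]
    if list(df.columns) != expected:
        raise ValidationError(
            f"{path}: expected header {expected}, got {list(df.columns)}"
        )
    return [
        SurvivalRecord(str(r.case_id).strip(), float(r.time_months), int(r.event))
        for r in df.itertuples(index=False)
    ]


def write_survival_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_expression_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.columns[0] != "case_id":
        raise ValidationError(f"{path}: first column must be 'case_id'")
    df["case_id"] = df["case_id"].astype(str).str.strip()
    df = df.set_index("case_id")
    return validate_expression_matrix(df)


def write_expression_csv(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, index_label="case_id")


def write_score_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index_label="cdr3")


def read_score_records(path) -> list[ScoreRecord]:
    df = pd.read_csv(path)
    return [
        ScoreRecord(str(r.case_id), str(r.antigen_label), float(r.cs), int(r.n_cdr3))
        for r in df.itertuples(index=False)
    ]


def write_score_records(records: Iterable[ScoreRecord], path) -> None:
    pd.DataFrame(
        [{"case_id": r.case_id, "antigen_label": r.antigen_label,
          "cs": r.cs, "n_cdr3": r.n_cdr3} for r in records]
    ).to_csv(path, index=False)


def write_stratification(strata: StratifiedCohort, path) -> None:
    rows = sorted(
        [{"case_id": c, "group": "upper"} for c in strata.upper]
        + [{"case_id": c, "group": "lower"} for c in strata.lower],
        key=lambda r: r["case_id"],
    )
    pd.DataFrame(rows, columns=["case_id", "group"]).to_csv(path, index=False)


def read_stratification(path) -> dict[str, str]:
    df = pd.read_csv(path)
    return dict(zip(df["case_id"].astype(str), df["group"]))


def write_km_curve(curve: KMCurve, path) -> None:
    pd.DataFrame(
        {"time": curve.event_times, "survival": curve.survival,
         "at_risk": curve.at_risk, "events": curve.events}
    ).to_csv(path, index=False)


def write_logrank_json(result: LogrankResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"chi_square": result.chi_square, "p_value": result.p_value,
             "observed": list(result.observed), "expected": list(result.expected)},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")


def write_correlation_csv(rows: list[CorrelationRow], path) -> None:
    rows_to_frame(rows).to_csv(path, index=False)
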