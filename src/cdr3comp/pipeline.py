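"""The two headline analyses wired end-to-end, plus run configuration.

``run_survival_analysis`` takes a cohort's CDR3 table, one or more antigen
targets (whole proteins or fragments from a sweep) and a survival table,
and for each target scores every CDR3, aggregates to one CS per case,
median-splits the cohort and compares the groups by Kaplan–Meier curves
and the logrank test.  ``run_correlation_analysis`` does the same scoring
and aggregation, then screens a gene panel for Pearson correlation with
the CS.  ``run_synthetic_pipeline`` drives both from a single seeded
CohortSpec with no external input.

All result tables are written deterministically: two runs with identical
inputs and configuration produce byte-identical files (plots exempt).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as cio
from .association import CorrelationRow, correlation_screen
from .charges import ChargeTable
from .cohort import ScoreRecord, StratifiedCohort, aggregate_matrix, stratify_median
from .exceptions import JoinError, ValidationError
from .fragments import fragment_protein, whole_protein
from .scoring import AntigenFragment, CDR3Peptide, ScoreWeights, score_matrix
from .simulate import (CohortSpec, simulate_antigen, simulate_expression,
                       simulate_repertoires, simulate_survival)
from .survival import KMCurve, LogrankResult, SurvivalRecord, km_estimate, logrank_test

logger = logging.getLogger("cdr3comp")

_CONFIG_KEYS = {"charge_overrides", "weights", "aggregation", "chain",
                "k", "log_level", "outdir", "seed"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run options shared by every stage."""

    charge_overrides: dict = field(default_factory=dict)
    weights: ScoreWeights = field(default_factory=ScoreWeights)
    aggregation: str = "max"
    chain: str | None = None  # None = pool TRA and TRB
    k: int | None = None      # fragment count for a sweep; None = whole protein
    log_level: str = "INFO"
    outdir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.aggregation not in ("max", "mean"):
            raise ValidationError(f"unknown aggregation {self.aggregation!r}")
        if self.chain not in (None, "TRA", "TRB"):
            raise ValidationError(f"chain filter must be TRA or TRB, got {self.chain!r}")
        if self.k is not None and self.k <= 0:
            raise ValidationError("fragment count k must be positive")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _CONFIG_KEYS
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "weights" in kwargs and isinstance(kwargs["weights"], dict):
            kwargs["weights"] = ScoreWeights(**kwargs["weights"])
        return cls(**kwargs)

    def charge_table(self) -> ChargeTable:
        if self.charge_overrides:
            return ChargeTable.with_overrides(**self.charge_overrides)
        return ChargeTable.default()

    def to_jsonable(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass(frozen=True)
class SurvivalAnalysisResult:
    records: tuple[ScoreRecord, ...]
    strata: StratifiedCohort
    curves: dict[str, KMCurve]
    logrank: LogrankResult


@dataclass(frozen=True)
class CorrelationAnalysisResult:
    records: tuple[ScoreRecord, ...]
    rows: tuple[CorrelationRow, ...]
    warnings: tuple[str, ...]


def cdr3_peptides(cdr3_df: pd.DataFrame, chain: str | None = None) -> list[CDR3Peptide]:
    """CDR3 objects from a table, optionally filtered to one chain."""
    if chain is not None:
        cdr3_df = cdr3_df[cdr3_df["chain"] == chain]
    peptides = [CDR3Peptide(str(r.case_id), str(r.chain), str(r.cdr3_aa))
                for r in cdr3_df.itertuples(index=False)]
    if not peptides:
        raise ValidationError("no CDR3s left after filtering")
    return peptides


def antigen_targets(antigens: list[tuple[str, str]],
                    k: int | None) -> list[AntigenFragment]:
    """Whole proteins, or a k-fragment sweep of each, as scoring targets."""
    targets: list[AntigenFragment] = []
    for name, seq in antigens:
        if k is None:
            targets.append(whole_protein(seq, name))
        else:
            targets.extend(fragment_protein(seq, k, name))
    return targets


def score_cohort(cdr3_df: pd.DataFrame, antigens: list[tuple[str, str]],
                 config: RunConfig) -> tuple[pd.DataFrame, dict[str, list[ScoreRecord]]]:
    """Score matrix plus per-target aggregated ScoreRecords."""
    peptides = cdr3_peptides(cdr3_df, config.chain)
    targets = antigen_targets(antigens, config.k)
    matrix = score_matrix(peptides, targets, config.weights, config.charge_table())
    records = {t.label: aggregate_matrix(matrix, t.label, config.aggregation)
               for t in targets}
    return matrix, records


def _survival_for_cases(survival: list[SurvivalRecord],
                        case_ids: frozenset[str]) -> list[SurvivalRecord]:
    return [r for r in survival if r.case_id in case_ids]


def survival_comparison(records: list[ScoreRecord],
                        survival: list[SurvivalRecord]) -> SurvivalAnalysisResult:
    """Median split -> per-group KM -> logrank, for one antigen target."""
    surv_ids = {r.case_id for r in survival}
    scored = [r for r in records if r.case_id in surv_ids]
    if len(scored) < 4:
        raise JoinError(
            f"only {len(scored)} cases shared between scores and survival; need >= 4"
        )
    strata = stratify_median(scored)
    upper = _survival_for_cases(survival, strata.upper)
    lower = _survival_for_cases(survival, strata.lower)
    return SurvivalAnalysisResult(
        records=tuple(scored),
        strata=strata,
        curves={"upper": km_estimate(upper), "lower": km_estimate(lower)},
        logrank=logrank_test(upper, lower),
    )


def run_survival_analysis(cdr3_df: pd.DataFrame, antigens: list[tuple[str, str]],
                          survival: list[SurvivalRecord], config: RunConfig,
                          outdir: str | Path | None = None,
                          ) -> dict[str, SurvivalAnalysisResult]:
    """The median-split survival comparison for every antigen target."""
    matrix, per_target = score_cohort(cdr3_df, antigens, config)
    results = {}
    for label, records in per_target.items():
        try:
            results[label] = survival_comparison(records, survival)
        except (JoinError, ValidationError) as err:
            raise type(err)(f"survival stage for target {label!r}: {err}") from err
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_score_matrix(matrix, outdir / "score_matrix.csv")
        for label, res in results.items():
            safe = label.replace(":", "_").replace("/", "_")
            cio.write_score_records(res.records, outdir / f"scores_{safe}.csv")
            cio.write_stratification(res.strata, outdir / f"strata_{safe}.csv")
            for group, curve in res.curves.items():
                cio.write_km_curve(curve, outdir / f"km_{group}_{safe}.csv")
            cio.write_logrank_json(res.logrank, outdir / f"logrank_{safe}.json")
        _write_manifest(outdir, config, stage="survival")
    return results


def run_correlation_analysis(cdr3_df: pd.DataFrame, antigens: list[tuple[str, str]],
                             expr: pd.DataFrame, panel: list[str],
                             config: RunConfig,
                             outdir: str | Path | None = None,
                             ) -> dict[str, CorrelationAnalysisResult]:
    """The CS-vs-expression Pearson screen for every antigen target."""
    matrix, per_target = score_cohort(cdr3_df, antigens, config)
    results = {}
    for label, records in per_target.items():
        rows, warnings = correlation_screen(records, expr, panel)
        for w in warnings:
            logger.warning("%s: %s", label, w)
        results[label] = CorrelationAnalysisResult(
            records=tuple(records), rows=tuple(rows), warnings=tuple(warnings)
        )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_score_matrix(matrix, outdir / "score_matrix.csv")
        for label, res in results.items():
            safe = label.replace(":", "_").replace("/", "_")
            cio.write_correlation_csv(list(res.rows), outdir / f"correlations_{safe}.csv")
        _write_manifest(outdir, config, stage="correlation")
    return results


def run_synthetic_pipeline(spec: CohortSpec, outdir: str | Path,
                           config: RunConfig | None = None,
                           ) -> tuple[SurvivalAnalysisResult, CorrelationAnalysisResult]:
    """End-to-end run from one seeded CohortSpec with no external input.

    Generates repertoires and a synthetic antigen, scores and aggregates,
    simulates survival and expression conditioned on the resulting scores,
    and runs both headline analyses, writing every intermediate.
    """
    config = config or RunConfig(seed=spec.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cdr3_df = simulate_repertoires(spec)
    name, seq = simulate_antigen(spec)
    cio.write_cdr3_table(cdr3_df, outdir / "cdr3s.tsv")
    cio.write_fasta([(name, seq)], outdir / "antigen.fasta")

    matrix, per_target = score_cohort(cdr3_df, [(name, seq)], config)
    label = next(iter(per_target))
    records = per_target[label]
    cio.write_score_matrix(matrix, outdir / "score_matrix.csv")
    cio.write_score_records(records, outdir / "scores.csv")

    survival_df = simulate_survival(records, spec)
    cio.write_survival_csv(survival_df, outdir / "survival.csv")
    survival = [SurvivalRecord(str(r.case_id), float(r.time_months), int(r.event))
                for r in survival_df.itertuples(index=False)]
    surv_res = survival_comparison(records, survival)
    cio.write_stratification(surv_res.strata, outdir / "strata.csv")
    for group, curve in surv_res.curves.items():
        cio.write_km_curve(curve, outdir / f"km_{group}.csv")
    cio.write_logrank_json(surv_res.logrank, outdir / "logrank.json")

    expr = simulate_expression(records, spec)
    cio.write_expression_csv(expr, outdir / "expression.csv")
    panel = [g for g, _, _ in spec.gene_specs]
    rows, warnings = correlation_screen(records, expr, panel)
    cio.write_correlation_csv(rows, outdir / "correlations.csv")
    corr_res = CorrelationAnalysisResult(tuple(records), tuple(rows), tuple(warnings))

    _write_manifest(outdir, config, stage="pipeline", spec=spec)
    return surv_res, corr_res


def _write_manifest(outdir: Path, config: RunConfig, stage: str,
                    spec: CohortSpec | None = None) -> None:
    """Everything needed to re-execute the run exactly (no timestamps, so
    repeated runs stay byte-identical)."""
    from . import __version__

    manifest = {"stage": stage, "config": config.to_jsonable(),
                "package_version": __version__}
    if spec is not None:
        manifest["cohort_spec"] = dataclasses.asdict(spec)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=list)
        fh.write("\n")


def parse_cohort_config(path) -> CohortSpec:
    """CohortSpec from a flat ``key = value`` file.

    Ranges are written ``lo-hi``; gene couplings as ``gene.SYMBOL = beta,sd``.
    Unknown keys are rejected.
    """
    scalars: dict[str, object] = {}
    genes: list[tuple[str, float, float]] = []
    int_keys = {"seed", "n_samples"}
    range_keys = {"cdr3_per_sample", "cdr3_length"}
    float_keys = {"charge_enrichment", "hazard_ratio", "baseline_hazard",
                  "censor_time_max"}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = (part.strip() for part in line.partition("="))
            if key.startswith("gene."):
                beta, sd = (float(v) for v in value.split(","))
                genes.append((key[len("gene."):], beta, sd))
            elif key in int_keys:
                scalars[key] = int(value)
            elif key in range_keys:
                lo, _, hi = value.partition("-")
                scalars[key] = (int(lo), int(hi))
            elif key in float_keys:
                scalars[key] = float(value)
            else:
                raise ValidationError(f"{path}:{lineno}: unknown key {key!r}")
    if "seed" not in scalars:
        raise ValidationError(f"{path}: a seed is mandatory")
    if genes:
        scalars["gene_specs"] = tuple(genes)
    return CohortSpec(**scalars)  # type: ignore[arg-type]


def write_cohort_config(spec: CohortSpec, path) -> None:
    """Echo a CohortSpec back to the flat key-value dialect (provenance)."""
    lines = [
        f"seed = {spec.seed}",
        f"n_samples = {spec.n_samples}",
        f"cdr3_per_sample = {spec.cdr3_per_sample[0]}-{spec.cdr3_per_sample[1]}",
        f"cdr3_length = {spec.cdr3_length[0]}-{spec.cdr3_length[1]}",
        f"charge_enrichment = {spec.charge_enrichment}",
        f"hazard_ratio = {spec.hazard_ratio}",
        f"baseline_hazard = {spec.baseline_hazard}",
        f"censor_time_max = {spec.censor_time_max}",
    ]
    lines += [f"gene.{g} = {b},{sd}" for g, b, sd in spec.gene_specs]
    Path(path).write_text("\n".join(lines) + "\n")
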