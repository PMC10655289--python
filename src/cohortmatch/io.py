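"""Reading and writing the audit's tabular interfaces.

Trial tables follow a wide CSV schema with, per continuous parameter,
mean/sd/median/q1/q3/min/max columns (empty cell = not reported) plus an
ASA 3+ percentage; optional ``expected_stat_*`` / ``expected_sub_*``
columns carry published verdicts for regression logging.  All output is
RFC-4180 CSV with a header.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import (
    ROCResult,
    SubgroupTally,
    YearPooledPoint,
    pool_by_year,
    roc_auc,
    spearman_rho,
    substantial_mismatch_labels,
    tally_all,
)
from .cohort import ReferenceSummary, build_reference_set, read_cohort
from .config import AuditConfig
from .engine import ParameterVerdict, TrialRecord, TrialVerdict, audit_trials
from .stats import PointEstimate, QuantileReport, Source, SummaryStat

logger = logging.getLogger(__name__)

__all__ = ["read_trials", "RowIssue", "run_audit", "AuditReport",
           "verdicts_frame", "tallies_frame", "pooled_frame", "roc_frame"]

_META_COLUMNS = (
    "trial_id", "publication_year", "years_since_publication", "topic", "specialty",
    "outcome", "n_participants",
)


@dataclass(frozen=True)
class RowIssue:
    """A rejected or degraded row, with its 1-based line number and reason."""

    line: int
    trial_id: str
    reason: str


def _num(row, col) -> float | None:
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def _parse_report(row, prefix: str, n: int):
    """Build a SummaryStat or QuantileReport from one parameter's columns."""
    mean = _num(row, f"{prefix}_mean")
    sd = _num(row, f"{prefix}_sd")
    med = _num(row, f"{prefix}_median")
    q1, q3 = _num(row, f"{prefix}_q1"), _num(row, f"{prefix}_q3")
    lo, hi = _num(row, f"{prefix}_min"), _num(row, f"{prefix}_max")
    if mean is not None:
        if sd is None:
            return PointEstimate(value=mean, n=n)  # no spread: unusable for inference
        return SummaryStat(mean=mean, sd=sd, n=n, source=Source.REPORTED)
    if med is not None:
        has_spread = (q1 is not None and q3 is not None) or (
            lo is not None and hi is not None
        )
        if not has_spread:
            return PointEstimate(value=med, n=n)
        return QuantileReport(median=med, n=n, minimum=lo, maximum=hi, q1=q1, q3=q3)
    return None


def read_trials(path) -> tuple[list[TrialRecord], list[RowIssue]]:
    """Read a trial table CSV into validated :class:`TrialRecord` objects.

    Schema violations (missing columns, empty file) raise; row-level
    invariant violations (e.g. q1 > q3) reject the row and are returned
    as :class:`RowIssue` entries with line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path} is missing columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"trial file {path} contains no rows")

    records: list[TrialRecord] = []
    issues: list[RowIssue] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        trial_id = str(row["trial_id"])
        try:
            n = int(row["n_participants"])
            expected = {}
            for col in df.columns:
                if col.startswith("expected_") and isinstance(row[col], str):
                    expected[col.removeprefix("expected_")] = row[col]
            rec = TrialRecord(
                trial_id=trial_id,
                publication_year=int(row["publication_year"]),
                years_since_publication=float(row["years_since_publication"]),
                topic=str(row["topic"]),
                specialty=str(row["specialty"]),
                outcome=str(row["outcome"]),
                n_participants=n,
                n_centres=None if pd.isna(row.get("n_centres")) else int(row["n_centres"]),
                uk_recruitment=(
                    None if pd.isna(row.get("uk_recruitment")) else str(row["uk_recruitment"])
                ),
                risk_of_bias=(
                    None if pd.isna(row.get("risk_of_bias")) else str(row["risk_of_bias"])
                ),
                age_report=_parse_report(row, "age", n),
                weight_report=_parse_report(row, "weight", n),
                bmi_report=_parse_report(row, "bmi", n),
                asa_pct_3plus=_num(row, "asa_pct_3plus"),
                expected_verdicts=expected,
            )
        except (ValueError, TypeError) as err:
            issues.append(RowIssue(line=line, trial_id=trial_id, reason=str(err)))
            continue
        records.append(rec)
    if not records:
        raise ValueError(f"trial file {path}: every row was rejected")
    return records, issues


# ---------------------------------------------------------------------------
# output frames

_ARROW = {"higher": "↑", "lower": "↓", "none": ""}


def _verdict_cell(v: ParameterVerdict | None):
    if v is None:
        return np.nan
    flag = "Yes" if v.statistical_mismatch else "No"
    return flag + _ARROW[v.direction.value]


def verdicts_frame(verdicts: list[TrialVerdict], trials: list[TrialRecord]) -> pd.DataFrame:
    """Per-trial verdict table mirroring the audited-trial layout:
    statistical flags with direction arrows plus substantial flags."""
    by_id = {t.trial_id: t for t in trials}
    rows = []
    for v in verdicts:
        t = by_id[v.trial_id]
        row: dict = {
            "trial_id": v.trial_id,
            "specialty": t.specialty,
            "publication_year": t.publication_year,
            "years_since_publication": t.years_since_publication,
            "n_participants": t.n_participants,
        }
        for p in ("age", "weight", "bmi", "asa"):
            pv = v.verdict(p)
            row[f"stat_{p}"] = _verdict_cell(pv)
            row[f"p_{p}"] = np.nan if pv is None else pv.test.p_value
            if p != "asa":
                sub = None if pv is None else pv.substantial_mismatch
                row[f"sub_{p}"] = np.nan if sub is None else ("Yes" if sub else "No")
        row.update(
            n_reported=v.n_reported,
            n_statistical=v.n_statistical,
            mismatch_fraction=v.mismatch_fraction,
            any_statistical=v.any_statistical,
            any_substantial=v.any_substantial,
            excluded_parameters=";".join(v.excluded_parameters),
        )
        rows.append(row)
    return pd.DataFrame(rows)


def tallies_frame(tallies: list[SubgroupTally]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(t) for t in tallies])
    df["pct_trials_any_statistical"] = 100 * df.trials_any_statistical / df.n_trials
    df["pct_params_statistical"] = 100 * df.params_statistical / df.params_reported
    return df


def pooled_frame(points: list[YearPooledPoint]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in points])


def roc_frame(roc: ROCResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "threshold": roc.thresholds,
            "sensitivity": roc.sensitivities,
            "specificity": roc.specificities,
        }
    )


# ---------------------------------------------------------------------------
# full audit orchestration


@dataclass
class AuditReport:
    """Everything one audit run produces."""

    verdicts: list[TrialVerdict]
    trials: list[TrialRecord]
    issues: list[RowIssue]
    tallies: list[SubgroupTally]
    pooled: dict[str, list[YearPooledPoint]]
    correlations: dict[str, float]
    roc: ROCResult | None
    summary_text: str


def _headline(report: AuditReport) -> str:
    n = len(report.verdicts)
    k = sum(v.any_statistical for v in report.verdicts)
    lines = [
        f"Audited {n} trials; {k} ({100 * k / n:.1f}%) statistically mismatched "
        "on at least one reported demographic parameter.",
    ]
    for p in ("age", "weight", "bmi", "asa"):
        rep = [v.verdict(p) for v in report.verdicts]
        rep = [r for r in rep if r is not None]
        if rep:
            mm = sum(r.statistical_mismatch for r in rep)
            lines.append(
                f"  {p}: mismatched in {mm} of {len(rep)} reporting trials "
                f"({100 * mm / len(rep):.1f}%)."
            )
    ks = sum(v.any_substantial for v in report.verdicts)
    lines.append(f"Substantial mismatch (age/weight/BMI rules) in {ks} trials.")
    for p, rho in report.correlations.items():
        if not math.isnan(rho):
            lines.append(f"  IVW-pooled Spearman rho, {p} vs publication year: {rho:+.2f}.")
    if report.roc is not None:
        lines.append(
            f"ROC of years-since-publication predicting any substantial mismatch: "
            f"AUC {report.roc.auc:.2f} "
            f"({report.roc.n_positive} positive / {report.roc.n_negative} negative trials)."
        )
    if report.issues:
        lines.append(f"{len(report.issues)} input rows rejected (see log).")
    return "\n".join(lines)


def run_audit(
    config: AuditConfig,
    trials_path,
    cohort_path=None,
    reference: dict[str, ReferenceSummary] | None = None,
) -> AuditReport:
    """Run the complete audit and, if ``config.output_dir`` is set, write
    the verdict, subgroup, temporal-series and ROC CSVs plus a summary.

    Exactly one of ``cohort_path`` (patient-level CSV) or ``reference``
    (prebuilt summaries) must be provided.
    """
    if (cohort_path is None) == (reference is None):
        raise ValueError("provide exactly one of cohort_path or reference")
    trials, issues = read_trials(trials_path)
    for issue in issues:
        logger.warning("rejected row %d (%s): %s", issue.line, issue.trial_id, issue.reason)
    if reference is None:
        reference = build_reference_set(read_cohort(cohort_path))
    if config.audit_date is not None:
        for t in trials:
            t.years_since_publication = max(
                0.0, config.audit_date.year + config.audit_date.month / 12
                - (t.publication_year + 0.5)
            )
    verdicts = audit_trials(trials, reference, config)
    tallies = tally_all(verdicts, trials)

    pooled: dict[str, list[YearPooledPoint]] = {}
    correlations: dict[str, float] = {}
    for p in ("age", "weight", "bmi", "asa"):
        try:
            pts = pool_by_year(trials, p, config)
        except ValueError:
            continue
        pooled[p] = pts
        if len(pts) >= 3:
            correlations[p] = spearman_rho(
                [pt.year for pt in pts], [pt.pooled_value for pt in pts]
            )

    scores, labels = substantial_mismatch_labels(verdicts, trials)
    roc = None
    if len(scores) and 0 < labels.sum() < len(labels):
        roc = roc_auc(scores, labels)

    report = AuditReport(
        verdicts=verdicts, trials=trials, issues=issues, tallies=tallies,
        pooled=pooled, correlations=correlations, roc=roc, summary_text="",
    )
    report.summary_text = _headline(report)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        verdicts_frame(verdicts, trials).to_csv(out / "verdicts.csv", index=False)
        tallies_frame(tallies).to_csv(out / "subgroups.csv", index=False)
        for p, pts in pooled.items():
            pooled_frame(pts).to_csv(out / f"pooled_{p}.csv", index=False)
        if roc is not None:
            roc_frame(roc).to_csv(out / "roc_points.csv", index=False)
        (out / "summary.txt").write_text(report.summary_text + "\n")
    return report
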