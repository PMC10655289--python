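"""Aggregate outputs of the audit.

Four families of results are produced from the per-trial verdicts:

* subgroup tallies (by specialty, topic, outcome, size split at the
  median trial size, and age split at the median years since
  publication), with chi-squared contrasts between subgroups;
* per-year inverse-variance-weighted pooling of trial demographics;
* Spearman rank correlation of the pooled series against calendar
  publication year (the "evidence expiry" trend);
* ROC analysis of years-since-publication as a predictor of substantial
  mismatch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .config import AuditConfig
from .engine import TrialRecord, TrialVerdict, normalise_report
from .stats import TestResult, chi_squared_proportions

__all__ = [
    "GROUPINGS",
    "SubgroupTally",
    "YearPooledPoint",
    "ROCResult",
    "tally",
    "tally_all",
    "compare_subgroups",
    "pool_by_year",
    "spearman_rho",
    "temporal_correlation",
    "roc_auc",
    "substantial_mismatch_labels",
]

GROUPINGS = ("all", "specialty", "topic", "outcome", "size_split", "age_split")


@dataclass(frozen=True)
class SubgroupTally:
    """Mismatch counts for one subgroup of trials."""

    grouping: str
    label: str
    n_trials: int
    trials_any_statistical: int
    params_reported: int
    params_statistical: int
    trials_any_substantial: int
    params_substantial: int
    params_substantial_evaluated: int  # age/weight/bmi verdicts (ASA has no rule)

    def __post_init__(self) -> None:
        if self.params_statistical > self.params_reported:
            raise ValueError("mismatched parameters cannot exceed reported parameters")
        if self.trials_any_statistical > self.n_trials:
            raise ValueError("mismatched trials cannot exceed trials")


@dataclass(frozen=True)
class YearPooledPoint:
    """Inverse-variance-weighted pooled value of one parameter in one year."""

    year: int
    pooled_value: float
    total_weight: float
    n_trials: int
    continuity_adjusted: bool = False


@dataclass(frozen=True)
class ROCResult:
    """ROC curve and area for a score predicting a binary label."""

    auc: float
    thresholds: tuple[float, ...]
    sensitivities: tuple[float, ...]
    specificities: tuple[float, ...]
    n_positive: int
    n_negative: int


def _group_key(trial: TrialRecord, grouping: str, medians: dict[str, float]) -> str:
    if grouping == "all":
        return "all"
    if grouping == "specialty":
        return trial.specialty
    if grouping == "topic":
        return trial.topic
    if grouping == "outcome":
        return trial.outcome
    if grouping == "size_split":
        m = medians["size"]
        return f"n<={m:g}" if trial.n_participants <= m else f"n>{m:g}"
    if grouping == "age_split":
        m = medians["years"]
        return f"recent<={m:g}y" if trial.years_since_publication <= m else f"older>{m:g}y"
    raise ValueError(f"unknown grouping {grouping!r}")


def tally(
    verdicts: list[TrialVerdict], trials: list[TrialRecord], grouping: str
) -> list[SubgroupTally]:
    """Tally mismatch counts per subgroup.

    The size and age splits use the medians of the supplied trials, with
    "<= median" defining the smaller/more-recent group.  An empty
    subgroup yields a zero tally rather than an error.
    """
    by_id = {v.trial_id: v for v in verdicts}
    medians = {
        "size": float(np.median([t.n_participants for t in trials])),
        "years": float(np.median([t.years_since_publication for t in trials])),
    }
    groups: dict[str, list[tuple[TrialRecord, TrialVerdict]]] = {}
    for t in trials:
        if t.trial_id not in by_id:
            raise KeyError(f"no verdict for trial {t.trial_id!r}")
        groups.setdefault(_group_key(t, grouping, medians), []).append((t, by_id[t.trial_id]))
    out = []
    for label in sorted(groups):
        vs = [v for _, v in groups[label]]
        out.append(
            SubgroupTally(
                grouping=grouping,
                label=label,
                n_trials=len(vs),
                trials_any_statistical=sum(v.any_statistical for v in vs),
                params_reported=sum(v.n_reported for v in vs),
                params_statistical=sum(v.n_statistical for v in vs),
                trials_any_substantial=sum(v.any_substantial for v in vs),
                params_substantial=sum(v.n_substantial for v in vs),
                params_substantial_evaluated=sum(v.n_substantial_evaluated for v in vs),
            )
        )
    return out


def tally_all(verdicts: list[TrialVerdict], trials: list[TrialRecord]) -> list[SubgroupTally]:
    """Tallies for every grouping, concatenated."""
    out: list[SubgroupTally] = []
    for grouping in GROUPINGS:
        out.extend(tally(verdicts, trials, grouping))
    return out


def compare_subgroups(
    tally_a: SubgroupTally, tally_b: SubgroupTally, basis: str = "params_statistical"
) -> TestResult:
    """Chi-squared contrast of mismatched-vs-matched parameter counts
    between two subgroups.  ``basis`` selects statistical (denominator:
    parameters reported) or substantial (denominator: age/weight/BMI
    parameters) mismatches."""
    if basis == "params_statistical":
        k_a, n_a = tally_a.params_statistical, tally_a.params_reported
        k_b, n_b = tally_b.params_statistical, tally_b.params_reported
    elif basis == "params_substantial":
        k_a, n_a = tally_a.params_substantial, tally_a.params_substantial_evaluated
        k_b, n_b = tally_b.params_substantial, tally_b.params_substantial_evaluated
    else:
        raise ValueError(f"unknown basis {basis!r}")
    if n_a < 1 or n_b < 1:
        raise ValueError("both subgroups need at least one evaluated parameter")
    return chi_squared_proportions(k_a, n_a, k_b, n_b)


def pool_by_year(
    trials: list[TrialRecord],
    parameter: str,
    config: AuditConfig | None = None,
) -> list[YearPooledPoint]:
    """Pool one parameter within each calendar publication year using
    inverse-variance weights.

    For continuous parameters the weight is 1/SE^2 with SE = s/sqrt(n);
    for the ASA 3+ percentage the variance is p(1-p)/n on the proportion
    scale (the pooled value stays in percent).  A reported proportion of
    exactly 0 or 1 is continuity-adjusted to (x+0.5)/(n+1) and flagged.
    """
    cfg = config or AuditConfig()
    per_year: dict[int, list[tuple[float, float]]] = {}
    adjusted: dict[int, bool] = {}
    for t in trials:
        report = t.report(parameter)
        if report is None:
            continue
        if parameter == "asa":
            p = float(report) / 100.0
            adj = False
            if p in (0.0, 1.0):
                x = p * t.n_participants
                p = (x + 0.5) / (t.n_participants + 1)
                adj = True
            var = p * (1 - p) / t.n_participants
            value = 100.0 * p
        else:
            try:
                s = normalise_report(report, method=cfg.conversion_method)
            except Exception:
                continue
            if s.sd == 0:
                # a zero-SD report would get infinite weight; treat as degenerate
                warnings.warn(
                    f"{t.trial_id}: zero SD for {parameter}; excluded from pooling",
                    stacklevel=2,
                )
                continue
            var = s.sd**2 / s.n
            value = s.mean
            adj = False
        per_year.setdefault(t.publication_year, []).append((value, 1.0 / var))
        adjusted[t.publication_year] = adjusted.get(t.publication_year, False) or adj
    if not per_year:
        raise ValueError(f"no trial reports parameter {parameter!r}")
    out = []
    for year in sorted(per_year):
        vals = np.array([v for v, _ in per_year[year]])
        ws = np.array([w for _, w in per_year[year]])
        out.append(
            YearPooledPoint(
                year=year,
                pooled_value=float(np.average(vals, weights=ws)),
                total_weight=float(ws.sum()),
                n_trials=len(vals),
                continuity_adjusted=adjusted[year],
            )
        )
    return out


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties.

    Returns NaN (undefined) when either vector is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("rank correlation needs at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman's rho is undefined", stacklevel=2)
        return float("nan")
    return float(_sps.spearmanr(x, y).statistic)


def temporal_correlation(
    trials: list[TrialRecord], parameter: str, config: AuditConfig | None = None
) -> float:
    """Spearman's rho between publication year and the IVW-pooled per-year
    value of one parameter."""
    points = pool_by_year(trials, parameter, config)
    if len(points) < 3:
        raise ValueError(f"only {len(points)} pooled years for {parameter!r}")
    return spearman_rho([p.year for p in points], [p.pooled_value for p in points])


def roc_auc(scores, labels) -> ROCResult:
    """ROC analysis of a continuous score predicting a binary label.

    The area is computed two ways — the tie-corrected Mann-Whitney rank
    statistic (tied scores contribute 1/2) and trapezoidal integration
    of the empirical curve — and the two must agree to 1e-9.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC analysis needs both classes present")
    ranks = rankdata(scores)
    auc_rank = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc_trap = float(np.trapezoid(tpr, fpr))
    if not math.isclose(auc_rank, auc_trap, abs_tol=1e-9):
        raise AssertionError(
            f"rank AUC {auc_rank!r} and trapezoidal AUC {auc_trap!r} disagree"
        )
    return ROCResult(
        auc=float(auc_rank),
        thresholds=tuple(float(t) for t in thresholds),
        sensitivities=tuple(float(t) for t in tpr),
        specificities=tuple(float(1 - f) for f in fpr),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def substantial_mismatch_labels(
    verdicts: list[TrialVerdict], trials: list[TrialRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """(years-since-publication, any-substantial) pairs for the ROC set.

    Trials reporting none of age/weight/BMI are excluded: they carry no
    substantial-mismatch information.
    """
    by_id = {v.trial_id: v for v in verdicts}
    scores, labels = [], []
    for t in trials:
        v = by_id[t.trial_id]
        if v.n_substantial_evaluated == 0:
            continue
        scores.append(t.years_since_publication)
        labels.append(v.any_substantial)
    return np.asarray(scores), np.asarray(labels)
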