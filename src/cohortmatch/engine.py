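"""Per-trial mismatch classification.

Each demographic parameter a trial reports (age, weight, BMI, ASA 3+)
is compared against the matched reference in two ways:

* **statistical mismatch** — Welch's t-test for the continuous
  parameters, chi-squared on the 2x2 ASA 3+ table, significant at the
  configured two-sided alpha;
* **substantial mismatch** — an absolute clinical-relevance rule:
  mean age differing by more than 10 years, mean weight by more than
  10 kg, or mean BMI falling in a different WHO band from the reference.
  ASA has no substantial rule and contributes to the statistical tally
  only.

A trial's mismatch fraction is the number of statistically mismatched
parameters over the number of parameters it reports; parameters that
cannot be normalised to mean/SD (a bare median, a mean without spread)
are excluded from both numerator and denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .cohort import ReferenceSummary, match_reference
from .config import AuditConfig
from .stats import (
    Direction,
    PointEstimate,
    QuantileReport,
    SummaryStat,
    TestResult,
    chi_squared_proportions,
    summary_from_quantiles,
    welch_from_summaries,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PARAMETERS",
    "TrialRecord",
    "ParameterVerdict",
    "TrialVerdict",
    "UnreportableParameter",
    "normalise_report",
    "bmi_band",
    "classify_substantial",
    "classify_statistical",
    "audit_trial",
    "audit_trials",
]

PARAMETERS = ("age", "weight", "bmi", "asa")

TOPICS = (
    "ileus",
    "thromboprophylaxis",
    "fluid_therapy_gdt",
    "analgesia",
    "transfusion_iron",
    "nutrition",
    "antibiotics",
    "antiemetics",
    "bowel_prep",
    "other",
)


class UnreportableParameter(ValueError):
    """A demographic report that cannot be normalised to mean/SD."""


@dataclass
class TrialRecord:
    """One extracted multicentre RCT with its demographic reports."""

    trial_id: str
    publication_year: int
    years_since_publication: float
    topic: str
    specialty: str
    outcome: str  # significant | non_significant
    n_participants: int
    n_centres: int | None = None
    uk_recruitment: str | None = None  # non_uk | uk_inclusive | uk_only
    risk_of_bias: str | None = None  # low | fair | high
    age_report: SummaryStat | QuantileReport | None = None
    weight_report: SummaryStat | QuantileReport | None = None
    bmi_report: SummaryStat | QuantileReport | None = None
    asa_pct_3plus: float | None = None
    expected_verdicts: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError(f"{self.trial_id}: n_participants must be >= 2")
        if self.years_since_publication < 0:
            raise ValueError(f"{self.trial_id}: years_since_publication must be >= 0")
        if self.topic not in TOPICS:
            raise ValueError(f"{self.trial_id}: unknown topic {self.topic!r}")
        reports = (self.age_report, self.weight_report, self.bmi_report, self.asa_pct_3plus)
        if all(r is None for r in reports):
            raise ValueError(f"{self.trial_id}: no demographic report present")

    def report(self, parameter: str):
        if parameter == "asa":
            return self.asa_pct_3plus
        return getattr(self, f"{parameter}_report")


@dataclass(frozen=True)
class ParameterVerdict:
    """Statistical and substantial mismatch decision for one parameter."""

    parameter: str
    statistical_mismatch: bool
    direction: Direction
    test: TestResult
    substantial_mismatch: bool | None  # None for ASA (no substantial rule)
    trial_value: float
    reference_value: float


@dataclass(frozen=True)
class TrialVerdict:
    """Verdict bundle for one trial."""

    trial_id: str
    verdicts: tuple[ParameterVerdict, ...]
    excluded_parameters: tuple[str, ...] = ()

    @property
    def n_reported(self) -> int:
        return len(self.verdicts)

    @property
    def n_statistical(self) -> int:
        return sum(v.statistical_mismatch for v in self.verdicts)

    @property
    def mismatch_fraction(self) -> float:
        if not self.verdicts:
            return 0.0
        return self.n_statistical / self.n_reported

    @property
    def any_statistical(self) -> bool:
        return any(v.statistical_mismatch for v in self.verdicts)

    @property
    def any_substantial(self) -> bool:
        return any(v.substantial_mismatch for v in self.verdicts if v.substantial_mismatch)

    @property
    def n_substantial_evaluated(self) -> int:
        return sum(v.substantial_mismatch is not None for v in self.verdicts)

    @property
    def n_substantial(self) -> int:
        return sum(bool(v.substantial_mismatch) for v in self.verdicts)

    def verdict(self, parameter: str) -> ParameterVerdict | None:
        for v in self.verdicts:
            if v.parameter == parameter:
                return v
        return None


def normalise_report(
    report: SummaryStat | QuantileReport, n: int | None = None, method: str = "wan"
) -> SummaryStat:
    """Normalise a demographic report to mean/SD/n.

    Mean/SD reports pass through unchanged; median-based reports are
    converted with the configured estimator.  ``n`` overrides a missing
    sample size.  Raises :class:`UnreportableParameter` when no spread
    information is available.
    """
    if isinstance(report, SummaryStat):
        return report
    if isinstance(report, QuantileReport):
        return summary_from_quantiles(report, method=method)
    if isinstance(report, PointEstimate):
        raise UnreportableParameter(
            "report carries a location but no spread (bare mean or median)"
        )
    raise UnreportableParameter(f"cannot normalise report of type {type(report).__name__}")


def bmi_band(bmi: float, cutpoints: tuple[float, ...] = (18.5, 25.0, 30.0)) -> str:
    """WHO-style BMI band: [0,18.5) underweight, [18.5,25) normal,
    [25,30) overweight, [30,inf) obese.  Edges are lower-inclusive, so a
    BMI of exactly 25.0 is overweight."""
    if bmi <= 0:
        raise ValueError(f"BMI must be positive, got {bmi}")
    names = ("underweight", "normal", "overweight", "obese")
    if len(cutpoints) != len(names) - 1:
        # custom band structures get numbered labels
        names = tuple(f"band_{i}" for i in range(len(cutpoints) + 1))
    idx = sum(bmi >= c for c in cutpoints)
    return names[idx]


def classify_substantial(
    parameter: str,
    trial_mean: float,
    reference_mean: float,
    config: AuditConfig | None = None,
) -> bool | None:
    """Apply the absolute mismatch rule for one parameter.

    Thresholds are strict (a difference of exactly 10.0 years is not
    substantial).  Returns None for ASA, which has no substantial rule.
    """
    cfg = config or AuditConfig()
    if parameter == "age":
        return abs(trial_mean - reference_mean) > cfg.age_threshold_years
    if parameter == "weight":
        return abs(trial_mean - reference_mean) > cfg.weight_threshold_kg
    if parameter == "bmi":
        return bmi_band(trial_mean, cfg.bmi_cutpoints) != bmi_band(
            reference_mean, cfg.bmi_cutpoints
        )
    if parameter == "asa":
        return None
    raise ValueError(f"unknown parameter {parameter!r}")


def classify_statistical(
    parameter: str,
    trial: SummaryStat | float,
    trial_n: int,
    reference: ReferenceSummary,
    config: AuditConfig | None = None,
) -> ParameterVerdict:
    """Compare one trial parameter against the matched reference.

    Continuous parameters use Welch's t-test on the summaries; ASA uses
    chi-squared on the 3+ vs <3 2x2 table, reconstructing the trial
    count as round(pct * n).
    """
    cfg = config or AuditConfig()
    if parameter == "asa":
        pct = float(trial)
        successes = round(pct / 100.0 * trial_n)
        test = chi_squared_proportions(
            successes, trial_n, reference.asa_3plus_count, reference.asa_recorded_n
        )
        ref_value = 100.0 * reference.asa_3plus_fraction
        return ParameterVerdict(
            parameter="asa",
            statistical_mismatch=test.p_value < cfg.alpha,
            direction=test.direction,
            test=test,
            substantial_mismatch=None,
            trial_value=pct,
            reference_value=ref_value,
        )
    assert isinstance(trial, SummaryStat)
    ref_stat = reference.parameter(parameter)
    if ref_stat is None or ref_stat.n < 2:
        raise ValueError(
            f"reference for {reference.specialty!r} has no usable {parameter} summary"
        )
    test = welch_from_summaries(trial, ref_stat)
    return ParameterVerdict(
        parameter=parameter,
        statistical_mismatch=test.p_value < cfg.alpha,
        direction=test.direction,
        test=test,
        substantial_mismatch=classify_substantial(parameter, trial.mean, ref_stat.mean, cfg),
        trial_value=trial.mean,
        reference_value=ref_stat.mean,
    )


def audit_trial(
    trial: TrialRecord,
    summaries: dict[str, ReferenceSummary],
    config: AuditConfig | None = None,
) -> TrialVerdict:
    """Run the full per-trial audit: match the reference, normalise each
    reported parameter, classify statistically and substantially."""
    cfg = config or AuditConfig()
    reference = match_reference(trial.specialty, summaries)
    verdicts: list[ParameterVerdict] = []
    excluded: list[str] = []
    for parameter in PARAMETERS:
        report = trial.report(parameter)
        if report is None:
            continue
        if parameter == "asa":
            verdicts.append(
                classify_statistical("asa", report, trial.n_participants, reference, cfg)
            )
            continue
        try:
            summary = normalise_report(report, method=cfg.conversion_method)
        except UnreportableParameter as err:
            logger.warning("%s: %s excluded (%s)", trial.trial_id, parameter, err)
            excluded.append(parameter)
            continue
        verdicts.append(
            classify_statistical(parameter, summary, trial.n_participants, reference, cfg)
        )
    result = TrialVerdict(
        trial_id=trial.trial_id, verdicts=tuple(verdicts), excluded_parameters=tuple(excluded)
    )
    _log_disagreements(trial, result)
    return result


_EXPECTED_MAP = {
    ("yes", Direction.HIGHER): "yes_higher",
    ("yes", Direction.LOWER): "yes_lower",
}


def _log_disagreements(trial: TrialRecord, verdict: TrialVerdict) -> None:
    """Warn whenever a recomputed verdict disagrees with an expected one
    carried in the trial table; the recomputed verdict is never altered."""
    for v in verdict.verdicts:
        expected = trial.expected_verdicts.get(f"stat_{v.parameter}")
        if not expected:
            continue
        got = ("yes" if v.statistical_mismatch else "no") + "_" + v.direction.value
        if expected.startswith("yes") != v.statistical_mismatch or (
            expected not in ("no", "yes") and not expected.endswith(v.direction.value)
        ):
            logger.warning(
                "%s: recomputed %s verdict %s disagrees with expected %s",
                trial.trial_id, v.parameter, got, expected,
            )


def audit_trials(
    trials, summaries: dict[str, ReferenceSummary], config: AuditConfig | None = None
) -> list[TrialVerdict]:
    """Audit a collection of trials against a reference set."""
    return [audit_trial(t, summaries, config) for t in trials]
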