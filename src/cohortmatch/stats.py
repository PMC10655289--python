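"""Two-sample inference from summary statistics.

Multicentre trials report cohort demographics in heterogeneous forms:
mean (SD), median with interquartile range and/or full range, or a
percentage for ordinal grades such as ASA physical status.  This module
normalises those reports to a common mean/SD/n form and performs the
two comparisons the audit relies on:

* Welch's unequal-variance t-test computed directly from summary
  statistics (no raw data required), and
* Pearson's chi-squared test on a 2x2 table of proportions.

Quantile-to-moment conversion follows the normal-order-statistic
estimators of Wan et al. (2014), with the simpler Hozo/Cochrane rules
(range/4, IQR/1.35) available as an alternative mode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

from scipy import stats as _sps

__all__ = [
    "Source",
    "Direction",
    "QuantileReport",
    "PointEstimate",
    "SummaryStat",
    "TestResult",
    "mean_from_quantiles",
    "sd_from_quantiles",
    "combine_arms",
    "welch_from_summaries",
    "chi_squared_proportions",
]


class Source(str, Enum):
    """Provenance of a mean/SD summary."""

    REPORTED = "reported"
    FROM_MEDIAN_RANGE = "from_median_range"
    FROM_MEDIAN_IQR = "from_median_iqr"
    FROM_FIVE_NUMBER = "from_five_number"
    COMBINED_ARMS = "combined_arms"


class Direction(str, Enum):
    """Sign of the trial-minus-reference difference."""

    HIGHER = "higher"
    LOWER = "lower"
    NONE = "none"


class InsufficientQuantilesError(ValueError):
    """A quantile report cannot be converted (median only, or n missing)."""


@dataclass(frozen=True)
class QuantileReport:
    """A median-based demographic summary: median with IQR and/or range.

    Invariants: ``min <= q1 <= median <= q3 <= max`` wherever the pieces
    are present, ``n >= 1``, and at least one of the pairs (min, max) or
    (q1, q3) must accompany the median.
    """

    median: float
    n: int
    minimum: float | None = None
    maximum: float | None = None
    q1: float | None = None
    q3: float | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"sample size must be >= 1, got {self.n}")
        has_range = self.minimum is not None and self.maximum is not None
        has_iqr = self.q1 is not None and self.q3 is not None
        if not (has_range or has_iqr):
            raise InsufficientQuantilesError(
                "a quantile report needs (min, max) and/or (q1, q3) alongside "
                "the median; a bare median cannot be converted to mean/SD"
            )
        seq = [self.minimum, self.q1, self.median, self.q3, self.maximum]
        present = [v for v in seq if v is not None]
        if any(b < a for a, b in zip(present, present[1:])):
            raise ValueError(f"quantiles out of order: {present}")

    @property
    def has_range(self) -> bool:
        return self.minimum is not None and self.maximum is not None

    @property
    def has_iqr(self) -> bool:
        return self.q1 is not None and self.q3 is not None


@dataclass(frozen=True)
class PointEstimate:
    """A location-only report (bare mean or bare median, no spread).

    Carried so the trial row stays valid, but unusable for inference:
    the audit excludes it from both mismatch tallies with a warning.
    """

    value: float
    n: int


@dataclass(frozen=True)
class SummaryStat:
    """Mean, standard deviation and sample size of one demographic parameter."""

    mean: float
    sd: float
    n: int
    source: Source = Source.REPORTED

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")

    @property
    def se(self) -> float:
        return self.sd / math.sqrt(self.n)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample comparison run from summaries."""

    statistic: float
    df: float
    p_value: float
    direction: Direction
    test: str  # "welch_t" or "chi_squared"
    degenerate: bool = False


def _check_n(stat: SummaryStat, label: str) -> None:
    if stat.n < 2:
        raise ValueError(f"{label} needs n >= 2 for a two-sample test, got n={stat.n}")


def mean_from_quantiles(report: QuantileReport) -> float:
    """Estimate the sample mean from a median-based report.

    Uses the standard estimators: (a + 2m + b)/4 for median and range,
    (q1 + m + q3)/3 for median and IQR, and (a + 2 q1 + 2 m + 2 q3 + b)/8
    when all five numbers are available.  The same forms apply in both
    the Wan and the simple-rule conversion modes.
    """
    m = report.median
    if report.has_range and report.has_iqr:
        return (report.minimum + 2 * report.q1 + 2 * m + 2 * report.q3 + report.maximum) / 8
    if report.has_range:
        return (report.minimum + 2 * m + report.maximum) / 4
    return (report.q1 + m + report.q3) / 3


def _xi(n: int) -> float:
    """Expected standardised range divisor: 2 * Phi^-1((n - 0.375) / (n + 0.25))."""
    return 2.0 * _sps.norm.ppf((n - 0.375) / (n + 0.25))


def _eta(n: int) -> float:
    """Expected standardised IQR divisor: 2 * Phi^-1((0.75 n - 0.125) / (n + 0.25))."""
    return 2.0 * _sps.norm.ppf((0.75 * n - 0.125) / (n + 0.25))


def sd_from_quantiles(report: QuantileReport, method: str = "wan") -> float:
    """Estimate the sample SD from a median-based report.

    ``method="wan"`` uses the normal-order-statistic divisors
    (b - a) / (2 Phi^-1((n - 0.375)/(n + 0.25))) for the range and
    (q3 - q1) / (2 Phi^-1((0.75 n - 0.125)/(n + 0.25))) for the IQR;
    with all five numbers the two estimates are averaged.
    ``method="simple"`` applies the rule-of-thumb divisors range/4 and
    IQR/1.35, preferring the IQR when both are present.
    """
    if report.n < 2:
        raise ValueError(f"SD estimation needs n >= 2, got n={report.n}")
    if method not in ("wan", "simple"):
        raise ValueError(f"unknown conversion method {method!r}")

    sd_range = sd_iqr = None
    if report.has_range:
        spread = report.maximum - report.minimum
        if spread == 0:
            warnings.warn("degenerate quantiles (max == min): SD estimated as 0",
                          stacklevel=2)
        sd_range = spread / 4.0 if method == "simple" else spread / _xi(report.n)
    if report.has_iqr:
        spread = report.q3 - report.q1
        if spread == 0 and not report.has_range:
            warnings.warn("degenerate quantiles (q3 == q1): SD estimated as 0",
                          stacklevel=2)
        sd_iqr = spread / 1.35 if method == "simple" else spread / _eta(report.n)

    if sd_range is not None and sd_iqr is not None:
        if method == "simple":
            return sd_iqr
        return 0.5 * (sd_range + sd_iqr)
    out = sd_range if sd_range is not None else sd_iqr
    assert out is not None
    return out


def summary_from_quantiles(report: QuantileReport, method: str = "wan") -> SummaryStat:
    """Convert a quantile report to a :class:`SummaryStat`, tagging the source."""
    if report.has_range and report.has_iqr:
        source = Source.FROM_FIVE_NUMBER
    elif report.has_range:
        source = Source.FROM_MEDIAN_RANGE
    else:
        source = Source.FROM_MEDIAN_IQR
    return SummaryStat(
        mean=mean_from_quantiles(report),
        sd=sd_from_quantiles(report, method=method),
        n=report.n,
        source=source,
    )


def combine_arms(arm1: SummaryStat, arm2: SummaryStat) -> SummaryStat:
    """Pool two trial arms into a single group (Cochrane pooled-group formula).

    The pooled SD reproduces the SD of the concatenated raw samples:
    sqrt{ [(n1-1) s1^2 + (n2-1) s2^2 + n1 n2 / (n1+n2) (x1-x2)^2] / (n1+n2-1) }.
    """
    n1, n2 = arm1.n, arm2.n
    n = n1 + n2
    if n < 2:
        raise ValueError("combined arms need n1 + n2 >= 2")
    mean = (n1 * arm1.mean + n2 * arm2.mean) / n
    num = (
        (n1 - 1) * arm1.sd**2
        + (n2 - 1) * arm2.sd**2
        + n1 * n2 / n * (arm1.mean - arm2.mean) ** 2
    )
    sd = math.sqrt(max(num, 0.0) / (n - 1))
    return SummaryStat(mean=mean, sd=sd, n=n, source=Source.COMBINED_ARMS)


def welch_from_summaries(trial: SummaryStat, reference: SummaryStat) -> TestResult:
    """Two-sided Welch's t-test for unequal variances, from summaries alone.

    Degenerate inputs are handled explicitly: two zero-SD groups with
    equal means give p = 1; zero-SD groups with different means give the
    p -> 0 limit, flagged as degenerate.
    """
    _check_n(trial, "trial")
    _check_n(reference, "reference")
    diff = trial.mean - reference.mean
    direction = (
        Direction.NONE if diff == 0 else Direction.HIGHER if diff > 0 else Direction.LOWER
    )
    if trial.sd == 0 and reference.sd == 0:
        if diff == 0:
            return TestResult(0.0, float(trial.n + reference.n - 2), 1.0,
                              Direction.NONE, "welch_t", degenerate=True)
        return TestResult(math.copysign(math.inf, diff),
                          float(trial.n + reference.n - 2),
                          5e-324,  # smallest positive float: the p -> 0 limit, kept in (0, 1]
                          direction, "welch_t", degenerate=True)
    res = _sps.ttest_ind_from_stats(
        trial.mean, trial.sd, trial.n,
        reference.mean, reference.sd, reference.n,
        equal_var=False,
    )
    p = min(max(float(res.pvalue), 5e-324), 1.0)
    t = float(res.statistic)
    # Welch-Satterthwaite degrees of freedom
    v1 = trial.sd**2 / trial.n
    v2 = reference.sd**2 / reference.n
    df = (v1 + v2) ** 2 / (v1**2 / (trial.n - 1) + v2**2 / (reference.n - 1))
    if t == 0:
        direction = Direction.NONE
    return TestResult(t, df, p, direction, "welch_t")


def chi_squared_proportions(
    trial_success: int,
    trial_n: int,
    ref_success: int,
    ref_n: int,
    method: str = "pearson",
) -> TestResult:
    """Compare two proportions on a 2x2 table.

    Pearson's chi-squared without continuity correction by default; a
    Fisher exact fallback is available via ``method="fisher"`` for small
    expected counts.  A table with an all-zero margin (e.g. no successes
    anywhere) carries no information and returns p = 1, flagged.
    """
    for label, k, n in (("trial", trial_success, trial_n), ("reference", ref_success, ref_n)):
        if n < 1:
            raise ValueError(f"{label} n must be >= 1")
        if not 0 <= k <= n:
            raise ValueError(f"{label} successes must lie in [0, n], got {k}/{n}")
    table = [[trial_success, trial_n - trial_success], [ref_success, ref_n - ref_success]]
    p1 = trial_success / trial_n
    p2 = ref_success / ref_n
    diff = p1 - p2
    direction = (
        Direction.NONE if diff == 0 else Direction.HIGHER if diff > 0 else Direction.LOWER
    )
    col_sums = (trial_success + ref_success, (trial_n - trial_success) + (ref_n - ref_success))
    if 0 in col_sums:
        return TestResult(0.0, 1.0, 1.0, direction, "chi_squared", degenerate=True)
    if method == "fisher":
        res = _sps.fisher_exact(table)
        return TestResult(float(res.statistic), 1.0, float(res.pvalue), direction, "chi_squared")
    chi2, p, df, _ = _sps.chi2_contingency(table, correction=False)
    if chi2 == 0:
        direction = Direction.NONE
    return TestResult(float(chi2), float(df), float(p), direction, "chi_squared")
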