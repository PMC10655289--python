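"""Reference-cohort summaries and specialty matching.

The audit compares each trial against patients undergoing surgery of the
same specialty in a local reference cohort; trials enrolling mixed
specialties are compared against the whole cohort.  This module builds
per-specialty :class:`ReferenceSummary` objects from a patient-level
table and selects the matched reference for a trial.

Missing values are handled parameter-wise: each parameter's n is its own
non-missing count, and the ASA 3+ proportion is taken over patients with
a recorded ASA grade only.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .stats import Source, SummaryStat

__all__ = [
    "SPECIALTIES",
    "OVERALL",
    "ReferenceSummary",
    "summarize_cohort",
    "build_reference_set",
    "match_reference",
    "read_cohort",
    "reference_from_moments",
]

SPECIALTIES = (
    "colorectal",
    "hepatobiliary",
    "upper_gi",
    "gynaecology",
    "urology",
    "vascular",
)
OVERALL = "overall"

COHORT_COLUMNS = ("patient_id", "age", "weight_kg", "bmi", "asa", "specialty")

_PARAM_COLS = {"age": "age", "weight": "weight_kg", "bmi": "bmi"}


@dataclass(frozen=True)
class ReferenceSummary:
    """Per-specialty reference moments plus ASA 3+ counts."""

    specialty: str
    age: SummaryStat | None
    weight: SummaryStat | None
    bmi: SummaryStat | None
    asa_3plus_count: int
    asa_recorded_n: int

    def __post_init__(self) -> None:
        if self.asa_3plus_count > self.asa_recorded_n:
            raise ValueError("ASA 3+ count cannot exceed the recorded-ASA denominator")

    @property
    def asa_3plus_fraction(self) -> float:
        if self.asa_recorded_n == 0:
            return float("nan")
        return self.asa_3plus_count / self.asa_recorded_n

    def parameter(self, name: str) -> SummaryStat | None:
        if name not in _PARAM_COLS:
            raise KeyError(f"no continuous parameter named {name!r}")
        return getattr(self, name)


def summarize_cohort(patients: pd.DataFrame, specialty: str = OVERALL) -> ReferenceSummary:
    """Summarise a patient-level cohort table, optionally filtered to one specialty.

    Each continuous parameter is summarised as mean/SD (ddof=1)/n over its
    non-missing values; ASA 3+ is counted over patients with recorded ASA.
    """
    if specialty == OVERALL:
        sel = patients
    else:
        if specialty not in SPECIALTIES:
            raise ValueError(f"unknown surgical specialty {specialty!r}")
        sel = patients[patients["specialty"] == specialty]
    if len(sel) == 0:
        raise ValueError(f"no patients for specialty {specialty!r} in the cohort")

    def _stat(col: str) -> SummaryStat | None:
        vals = pd.to_numeric(sel[col], errors="coerce").dropna()
        if len(vals) < 2:
            return None
        return SummaryStat(
            mean=float(vals.mean()), sd=float(vals.std(ddof=1)), n=int(len(vals)),
            source=Source.REPORTED,
        )

    asa = pd.to_numeric(sel["asa"], errors="coerce").dropna()
    return ReferenceSummary(
        specialty=specialty,
        age=_stat("age"),
        weight=_stat("weight_kg"),
        bmi=_stat("bmi"),
        asa_3plus_count=int((asa >= 3).sum()),
        asa_recorded_n=int(len(asa)),
    )


def build_reference_set(patients: pd.DataFrame) -> dict[str, ReferenceSummary]:
    """Build the overall summary plus one per specialty present in the cohort."""
    refs = {OVERALL: summarize_cohort(patients, OVERALL)}
    for sp in SPECIALTIES:
        if (patients["specialty"] == sp).any():
            refs[sp] = summarize_cohort(patients, sp)
    return refs


def match_reference(
    trial_specialty: str, summaries: dict[str, ReferenceSummary]
) -> ReferenceSummary:
    """Select the reference for a trial: mixed -> overall, else same specialty.

    A specialty absent from the cohort raises rather than silently falling
    back to the overall sample.
    """
    if trial_specialty in ("mixed", OVERALL):
        return summaries[OVERALL]
    if trial_specialty not in SPECIALTIES:
        raise KeyError(f"unknown surgical specialty {trial_specialty!r}")
    if trial_specialty not in summaries:
        raise KeyError(
            f"specialty {trial_specialty!r} has no patients in the reference cohort; "
            "refusing to fall back to the overall sample"
        )
    return summaries[trial_specialty]


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a patient-level cohort CSV.

    Schema: patient_id, age, weight_kg, bmi, asa, specialty; empty cells
    are missing values; age must be >= 18 (adult cohort) and specialty a
    known surgical specialty.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file {path} is missing columns: {missing}")
    if len(df) == 0:
        raise ValueError(f"cohort file {path} contains no patients")
    bad_spec = set(df["specialty"].dropna()) - set(SPECIALTIES)
    if bad_spec:
        raise ValueError(f"cohort file {path} has unknown specialties: {sorted(bad_spec)}")
    ages = pd.to_numeric(df["age"], errors="coerce")
    if (ages.dropna() < 18).any():
        raise ValueError("cohort contains patients younger than 18 (adult cohort expected)")
    asa = pd.to_numeric(df["asa"], errors="coerce").dropna()
    if ((asa < 1) | (asa > 5)).any():
        raise ValueError("ASA grades must lie in 1..5")
    return df


def reference_from_moments(
    specialty: str,
    age: tuple[float, float] | None,
    weight: tuple[float, float] | None,
    bmi: tuple[float, float] | None,
    n: int,
    asa_3plus_count: int,
    asa_recorded_n: int,
) -> ReferenceSummary:
    """Construct a reference from published (mean, sd) pairs and counts.

    Used when only the printed moments of a cohort are available rather
    than the patient-level table.
    """

    def _stat(pair: tuple[float, float] | None) -> SummaryStat | None:
        if pair is None:
            return None
        mean, sd = pair
        return SummaryStat(mean=mean, sd=sd, n=n, source=Source.REPORTED)

    return ReferenceSummary(
        specialty=specialty,
        age=_stat(age),
        weight=_stat(weight),
        bmi=_stat(bmi),
        asa_3plus_count=asa_3plus_count,
        asa_recorded_n=asa_recorded_n,
    )
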