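"""Packaged data: the audited trial table and the published reference moments.

``load_trial_table`` returns the transcription of the demographic
summary table of 106 multicentre RCTs of perioperative interventions in
major abdominal surgery (per-trial mean (SD) age/weight/BMI, % ASA 3+,
metadata, and the published per-parameter verdict columns).

The reference cohort those trials were audited against — one year of
major abdominal surgery at a London tertiary centre (UCLH, September
2021 to September 2022, n = 2792) — is not deposited; only its overall
moments were published.  ``published_reference`` exposes those moments,
which suffice to audit the mixed-specialty trials (matched to the
overall sample); per-specialty audits need a patient-level cohort, e.g.
a synthetic one from :mod:`cohortmatch.simulate`.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import OVERALL, ReferenceSummary, reference_from_moments
from .engine import TrialRecord
from .io import RowIssue, read_trials

__all__ = [
    "load_trial_table",
    "load_trial_records",
    "published_reference",
    "REFERENCE_N",
    "REFERENCE_AGE",
    "REFERENCE_WEIGHT",
    "REFERENCE_BMI",
    "REFERENCE_ASA_3PLUS",
    "REFERENCE_ASA_RECORDED",
]

# Published overall moments of the reference cohort.
REFERENCE_N = 2792
REFERENCE_AGE = (55.1, 16.0)  # years
REFERENCE_WEIGHT = (77.8, 17.8)  # kg
REFERENCE_BMI = (27.4, 5.6)  # kg/m^2
REFERENCE_ASA_3PLUS = 773  # patients ASA 3 or higher ...
REFERENCE_ASA_RECORDED = 2638  # ... of those with a recorded ASA grade


def _table_path():
    return resources.files("cohortmatch.data") / "included_trials.csv"


def load_trial_table() -> pd.DataFrame:
    """The audited trial table as a raw DataFrame (one row per trial)."""
    with resources.as_file(_table_path()) as p:
        return pd.read_csv(p)


def load_trial_records() -> tuple[list[TrialRecord], list[RowIssue]]:
    """The audited trial table as validated :class:`TrialRecord` objects."""
    with resources.as_file(_table_path()) as p:
        return read_trials(p)


def published_reference() -> dict[str, ReferenceSummary]:
    """Reference set holding only the published overall cohort moments."""
    return {
        OVERALL: reference_from_moments(
            specialty=OVERALL,
            age=REFERENCE_AGE,
            weight=REFERENCE_WEIGHT,
            bmi=REFERENCE_BMI,
            n=REFERENCE_N,
            asa_3plus_count=REFERENCE_ASA_3PLUS,
            asa_recorded_n=REFERENCE_ASA_RECORDED,
        )
    }
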