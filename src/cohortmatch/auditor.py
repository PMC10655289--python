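"""Scikit-learn-style front end to the audit.

``MismatchAuditor`` is fitted on a patient-level reference cohort (a
DataFrame in the cohort CSV schema) and then classifies trials:
``predict`` returns, per trial, whether any reported demographic
parameter is statistically mismatched against the matched reference;
``transform`` returns a per-trial feature frame (counts, mismatch
fraction, flags) suitable for downstream tabulation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import ReferenceSummary, build_reference_set
from .config import AuditConfig
from .engine import TrialRecord, TrialVerdict, audit_trials
from .io import verdicts_frame

__all__ = ["MismatchAuditor"]


class MismatchAuditor(BaseEstimator):
    """Classify trials as demographically mismatched against a local cohort.

    Parameters
    ----------
    alpha : float, default 0.05
        Two-sided significance level for the statistical-mismatch tests.
    conversion_method : {"wan", "simple"}, default "wan"
        Estimator used to convert median-based reports to mean/SD.
    age_threshold_years, weight_threshold_kg : float, default 10
        Absolute-difference thresholds of the substantial-mismatch rule
        (strict inequalities).
    bmi_cutpoints : tuple of float, default (18.5, 25, 30)
        Lower-inclusive BMI band edges for the substantial BMI rule.

    Attributes
    ----------
    reference_set_ : dict[str, ReferenceSummary]
        Overall plus per-specialty reference summaries learned in ``fit``.
    n_patients_ : int
        Number of patients the reference was built from.

    Examples
    --------
    >>> from cohortmatch.simulate import generate_cohort
    >>> auditor = MismatchAuditor(alpha=0.05).fit(generate_cohort())
    >>> sorted(auditor.reference_set_)[:2]
    ['colorectal', 'gynaecology']
    """

    def __init__(
        self,
        alpha: float = 0.05,
        conversion_method: str = "wan",
        age_threshold_years: float = 10.0,
        weight_threshold_kg: float = 10.0,
        bmi_cutpoints: tuple[float, ...] = (18.5, 25.0, 30.0),
    ):
        self.alpha = alpha
        self.conversion_method = conversion_method
        self.age_threshold_years = age_threshold_years
        self.weight_threshold_kg = weight_threshold_kg
        self.bmi_cutpoints = bmi_cutpoints

    def _config(self) -> AuditConfig:
        return AuditConfig(
            alpha=self.alpha,
            conversion_method=self.conversion_method,
            age_threshold_years=self.age_threshold_years,
            weight_threshold_kg=self.weight_threshold_kg,
            bmi_cutpoints=tuple(self.bmi_cutpoints),
        )

    def fit(self, X: pd.DataFrame, y=None) -> "MismatchAuditor":
        """Learn per-specialty reference summaries from a patient-level cohort."""
        self._config()  # validates the parameters
        if not isinstance(X, pd.DataFrame):
            raise TypeError("fit expects a patient-level DataFrame (cohort CSV schema)")
        self.reference_set_ = build_reference_set(X)
        self.n_patients_ = int(len(X))
        return self

    @classmethod
    def from_reference(
        cls, reference: dict[str, ReferenceSummary], **params
    ) -> "MismatchAuditor":
        """Build an already-fitted auditor from precomputed summaries
        (e.g. published cohort moments)."""
        est = cls(**params)
        est._config()
        est.reference_set_ = dict(reference)
        est.n_patients_ = reference["overall"].age.n if reference["overall"].age else 0
        return est

    def _check_fitted(self) -> None:
        if not hasattr(self, "reference_set_"):
            raise AttributeError("MismatchAuditor is not fitted yet; call fit first")

    def audit(self, trials: list[TrialRecord]) -> list[TrialVerdict]:
        """Full verdict objects for a collection of trials."""
        self._check_fitted()
        return audit_trials(trials, self.reference_set_, self._config())

    def predict(self, trials: list[TrialRecord]) -> np.ndarray:
        """Boolean array: any statistical mismatch per trial."""
        return np.array([v.any_statistical for v in self.audit(trials)])

    def transform(self, trials: list[TrialRecord]) -> pd.DataFrame:
        """Per-trial verdict feature frame (flags, counts, mismatch fraction)."""
        return verdicts_frame(self.audit(trials), list(trials))
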