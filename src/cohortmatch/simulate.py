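"""Synthetic patient cohorts and drifting trial populations.

No patient-level data accompany the audited trial table, so this module
generates a stand-in reference cohort — calibrated to the published
overall moments of the real one (age 55.1 (16.0) y, weight 77.8 (17.8)
kg, BMI 27.4 (5.6), 29.3% ASA 3+, n = 2792, urology/gynaecology/
colorectal shares 27.7/26.0/22.0%) — together with sets of synthetic
trials whose populations drift linearly with publication year.  Every
generated trial retains its raw participant sample in a truth manifest,
so summary-based inference can be checked against raw-data oracles and
imposed drift can be recovered by the temporal stage.

Cohort model: per-specialty truncated-normal ages (>= 18); BMI
truncated-normal; height normal; weight = BMI * height^2 (inducing a
realistic BMI-weight correlation); ASA graded by thresholding a latent
comorbidity score linear in age plus unit-normal noise, missing
completely at random at a configured rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats as _sps

from .cohort import SPECIALTIES
from .engine import TrialRecord
from .stats import QuantileReport, Source, SummaryStat

__all__ = ["CohortConfig", "TrialSetConfig", "TruthManifest", "generate_cohort",
           "generate_trial_set"]

# Specialty mix: the three published shares, with the remainder split
# across hepatobiliary / upper-GI / vascular in explicit, overridable
# proportions.
_DEFAULT_MIX = {
    "urology": 0.277,
    "gynaecology": 0.260,
    "colorectal": 0.220,
    "hepatobiliary": 0.100,
    "upper_gi": 0.080,
    "vascular": 0.063,
}

# Per-specialty age locations chosen so that, after truncation at 18,
# the mixture reproduces the published overall mean (55.1 y); a common
# within-specialty SD of 15.2 y plus the between-specialty spread
# reproduces the overall SD of ~16 y.
_DEFAULT_AGE_MEANS = {
    "urology": 54.5,
    "gynaecology": 43.8,
    "colorectal": 60.7,
    "hepatobiliary": 57.6,
    "upper_gi": 59.7,
    "vascular": 66.9,
}


class CohortConfig(BaseModel):
    """Parameters of the synthetic reference cohort."""

    n_patients: int = Field(2792, ge=1)
    specialty_mix: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_MIX))
    age_means: dict[str, float] = Field(default_factory=lambda: dict(_DEFAULT_AGE_MEANS))
    age_sd: float = Field(15.2, gt=0)
    age_min: float = 18.0
    bmi_mean: float = Field(27.4, gt=0)
    bmi_sd: float = Field(5.6, gt=0)
    bmi_range: tuple[float, float] = (14.0, 60.0)
    height_mean_m: float = Field(1.683, gt=0)
    height_sd_m: float = Field(0.10, gt=0)
    asa_link_slope: float = 0.05  # latent comorbidity per year of age
    asa_thresholds: tuple[float, float, float] = (-0.86, 0.70, 2.24)
    asa_missing_rate: float = Field(1.0 - 2638 / 2792, ge=0, lt=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortConfig":
        if abs(sum(self.specialty_mix.values()) - 1.0) > 1e-9:
            raise ValueError("specialty_mix proportions must sum to 1")
        unknown = set(self.specialty_mix) - set(SPECIALTIES)
        if unknown:
            raise ValueError(f"unknown specialties in mix: {sorted(unknown)}")
        if any(p < 0 or p > 1 for p in self.specialty_mix.values()):
            raise ValueError("specialty proportions must lie in [0, 1]")
        if sorted(self.asa_thresholds) != list(self.asa_thresholds):
            raise ValueError("asa_thresholds must be increasing")
        return self


class TrialSetConfig(BaseModel):
    """Parameters of a synthetic set of trials drawn from a drifting population."""

    n_trials: int = Field(106, ge=1)
    year_range: tuple[int, int] = (1988, 2022)
    # log-normal trial sizes moment-matched to median 253, IQR 121-489
    size_log_mu: float = math.log(253.0)
    size_log_sigma: float = math.log(489.0 / 121.0) / (2 * 0.6744897501960817)
    size_range: tuple[int, int] = (30, 4352)
    # linear drift of the trial population per calendar year, anchored at
    # the most recent year (older trials sit further from the reference)
    drift_age_per_year: float = 0.0
    drift_weight_per_year: float = 0.0
    drift_bmi_per_year: float = 0.0
    drift_asa3_logit_per_year: float = 0.0
    # probability that a trial reports each parameter
    report_rate_age: float = Field(0.972, ge=0, le=1)
    report_rate_weight: float = Field(0.274, ge=0, le=1)
    report_rate_bmi: float = Field(0.462, ge=0, le=1)
    report_rate_asa: float = Field(0.235, ge=0, le=1)
    # report-style mix for continuous parameters
    style_mean_sd: float = Field(0.8, ge=0, le=1)
    style_median_iqr: float = Field(0.15, ge=0, le=1)
    style_median_range: float = Field(0.05, ge=0, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "TrialSetConfig":
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (first, last) with first <= last")
        total = self.style_mean_sd + self.style_median_iqr + self.style_median_range
        if abs(total - 1.0) > 1e-9:
            raise ValueError("report-style proportions must sum to 1")
        return self


@dataclass
class TrialTruth:
    """Ground truth retained for one synthetic trial."""

    trial_id: str
    year: int
    true_means: dict[str, float]
    true_asa3_prob: float
    samples: dict[str, np.ndarray] = field(default_factory=dict)
    asa3_count: int = 0


@dataclass
class TruthManifest:
    """Ground truth for a generated trial set: per-trial raw samples,
    the imposed drift coefficients, and the seeds used."""

    drift: dict[str, float]
    seed: int
    trials: dict[str, TrialTruth] = field(default_factory=dict)


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    return _sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a patient-level reference cohort table.

    Deterministic under a fixed ``config.seed``; columns follow the
    cohort CSV schema (patient_id, age, weight_kg, bmi, asa, specialty).
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)
    specs = list(cfg.specialty_mix)
    probs = np.array([cfg.specialty_mix[s] for s in specs])
    specialty = rng.choice(specs, size=cfg.n_patients, p=probs)

    age = np.empty(cfg.n_patients)
    for sp in specs:
        mask = specialty == sp
        mean = cfg.age_means[sp]
        if mean <= cfg.age_min:
            raise ValueError(f"mean age for {sp} lies below the adult truncation point")
        age[mask] = _truncnorm(rng, mean, cfg.age_sd, cfg.age_min, 110.0, mask.sum())

    bmi = _truncnorm(rng, cfg.bmi_mean, cfg.bmi_sd, *cfg.bmi_range, cfg.n_patients)
    height = rng.normal(cfg.height_mean_m, cfg.height_sd_m, cfg.n_patients)
    height = np.clip(height, 1.2, 2.2)
    weight = bmi * height**2

    latent = cfg.asa_link_slope * (age - 55.0) + rng.standard_normal(cfg.n_patients)
    t1, t2, t3 = cfg.asa_thresholds
    asa = 1 + (latent > t1).astype(int) + (latent > t2).astype(int) + (latent > t3).astype(int)
    asa = asa.astype(float)
    asa[rng.random(cfg.n_patients) < cfg.asa_missing_rate] = np.nan

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(cfg.n_patients)],
            "age": np.round(age, 6),
            "weight_kg": np.round(weight, 6),
            "bmi": np.round(bmi, 6),
            "asa": asa,
            "specialty": specialty,
        }
    )


def _summarise(
    values: np.ndarray, style: str
) -> SummaryStat | QuantileReport:
    n = len(values)
    if style == "mean_sd":
        return SummaryStat(
            mean=float(values.mean()), sd=float(values.std(ddof=1)), n=n,
            source=Source.REPORTED,
        )
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    if style == "median_iqr":
        return QuantileReport(median=float(med), q1=float(q1), q3=float(q3), n=n)
    return QuantileReport(
        median=float(med), minimum=float(values.min()), maximum=float(values.max()), n=n
    )


def generate_trial_set(
    config: TrialSetConfig | None = None,
    cohort_config: CohortConfig | None = None,
) -> tuple[list[TrialRecord], TruthManifest]:
    """Generate synthetic trials whose populations drift with publication year.

    Each trial's population is the reference-cohort population (overall
    moments of ``cohort_config``) shifted linearly by the drift
    coefficients times (year - last year); participants are sampled,
    summarised in the configured report style, and masked according to
    the per-parameter reporting rates.  Raw samples are retained in the
    returned :class:`TruthManifest`.
    """
    cfg = config or TrialSetConfig()
    ccfg = cohort_config or CohortConfig()
    rng = np.random.default_rng(cfg.seed)

    # overall population implied by the cohort mixture
    specs = list(ccfg.specialty_mix)
    mix = np.array([ccfg.specialty_mix[s] for s in specs])
    mu_age = float(sum(ccfg.specialty_mix[s] * ccfg.age_means[s] for s in specs))
    between = float(sum(m * (ccfg.age_means[s] - mu_age) ** 2 for s, m in zip(specs, mix)))
    sd_age = math.sqrt(ccfg.age_sd**2 + between)
    mu_w = ccfg.bmi_mean * (ccfg.height_mean_m**2 + ccfg.height_sd_m**2)
    sd_w = 1.08 * ccfg.bmi_sd * ccfg.height_mean_m**2  # first-order propagation
    base_asa3 = 0.293

    drift = {
        "age": cfg.drift_age_per_year,
        "weight": cfg.drift_weight_per_year,
        "bmi": cfg.drift_bmi_per_year,
        "asa3_logit": cfg.drift_asa3_logit_per_year,
    }
    manifest = TruthManifest(drift=drift, seed=cfg.seed)
    trials: list[TrialRecord] = []
    y0, y1 = cfg.year_range
    styles = ("mean_sd", "median_iqr", "median_range")
    style_p = np.array([cfg.style_mean_sd, cfg.style_median_iqr, cfg.style_median_range])

    for i in range(cfg.n_trials):
        year = int(rng.integers(y0, y1 + 1))
        dt = year - y1  # <= 0: older trials are further from the reference
        n = int(np.clip(round(rng.lognormal(cfg.size_log_mu, cfg.size_log_sigma)),
                        *cfg.size_range))
        truth = TrialTruth(
            trial_id=f"SYN{i:04d}",
            year=year,
            true_means={
                "age": mu_age + drift["age"] * dt,
                "weight": mu_w + drift["weight"] * dt,
                "bmi": ccfg.bmi_mean + drift["bmi"] * dt,
            },
            true_asa3_prob=float(
                1 / (1 + math.exp(-(math.log(base_asa3 / (1 - base_asa3))
                                    + drift["asa3_logit"] * dt)))
            ),
        )
        samples = {
            "age": _truncnorm(rng, truth.true_means["age"], sd_age, ccfg.age_min, 110.0, n),
            "weight": rng.normal(truth.true_means["weight"], sd_w, n),
            "bmi": _truncnorm(rng, truth.true_means["bmi"], ccfg.bmi_sd, *ccfg.bmi_range, n),
        }
        truth.samples = samples
        truth.asa3_count = int(rng.binomial(n, truth.true_asa3_prob))

        reports: dict[str, SummaryStat | QuantileReport | None] = {}
        for param, rate in (
            ("age", cfg.report_rate_age),
            ("weight", cfg.report_rate_weight),
            ("bmi", cfg.report_rate_bmi),
        ):
            if rng.random() < rate:
                style = styles[int(rng.choice(3, p=style_p))]
                reports[param] = _summarise(samples[param], style)
            else:
                reports[param] = None
        asa_pct = (
            100.0 * truth.asa3_count / n if rng.random() < cfg.report_rate_asa else None
        )
        if all(v is None for v in reports.values()) and asa_pct is None:
            reports["age"] = _summarise(samples["age"], "mean_sd")  # keep record valid

        trials.append(
            TrialRecord(
                trial_id=truth.trial_id,
                publication_year=year,
                years_since_publication=float(y1 - year),
                topic="other",
                specialty="mixed",
                outcome="non_significant",
                n_participants=n,
                n_centres=int(rng.integers(2, 30)),
                uk_recruitment="non_uk",
                risk_of_bias="low",
                age_report=reports["age"],
                weight_report=reports["weight"],
                bmi_report=reports["bmi"],
                asa_pct_3plus=asa_pct,
            )
        )
        manifest.trials[truth.trial_id] = truth
    return trials, manifest
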