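"""Audit configuration.

All tunable analysis choices live here: the significance level, the
quantile-conversion mode, the "substantial difference" thresholds and
the BMI band cut-points.  The defaults encode the audit as specified:
alpha = 0.05 two-sided, Wan-style conversions, +/-10 years, +/-10 kg,
and WHO BMI bands with lower-inclusive edges.
"""

from __future__ import annotations

import datetime as _dt

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["AuditConfig"]


class AuditConfig(BaseModel):
    """Configuration for a mismatch audit run."""

    alpha: float = Field(0.05, gt=0, lt=1, description="two-sided significance level")
    conversion_method: str = Field("wan", description="'wan' or 'simple' quantile conversion")
    age_threshold_years: float = Field(10.0, gt=0)
    weight_threshold_kg: float = Field(10.0, gt=0)
    bmi_cutpoints: tuple[float, ...] = (18.5, 25.0, 30.0)
    audit_date: _dt.date | None = Field(
        None,
        description="anchor for recomputing years-since-publication; when None the "
        "years_since_publication column in the trial table is trusted as given",
    )
    seed: int = 0
    output_dir: str | None = None

    @field_validator("conversion_method")
    @classmethod
    def _known_method(cls, v: str) -> str:
        if v not in ("wan", "simple"):
            raise ValueError("conversion_method must be 'wan' or 'simple'")
        return v

    @field_validator("bmi_cutpoints")
    @classmethod
    def _increasing(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("bmi_cutpoints must be strictly increasing")
        return v

    @classmethod
    def from_yaml(cls, path, **overrides) -> "AuditConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
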