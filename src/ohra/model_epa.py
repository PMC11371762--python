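"""EPA non-carcinogenic inhalation risk: EC, hazard quotient, ordinal level.

The pathway time-adjusts the measured air concentration onto a continuous-
exposure basis,

    EC = CA * ET * EF * ED / AT,    AT = ED * 365 d/yr * 24 h/d,

so the exposure duration ED cancels algebraically and EC depends only on the
schedule (hours/day, days/year) and the concentration.  The hazard quotient
HQ = EC/RfC is judged against 1: HQ >= 1 is an unacceptable non-cancer risk.
For cross-model comparison HQ is additionally banded onto a five-level
ordinal scale (a mapping the source framework does not define; the default
thresholds are configuration).
"""

from __future__ import annotations

from pydantic import BaseModel, Field, model_validator

from .config import BandingConfig, ConfigurationError
from .core_types import ChemicalProfile, MethodId, RiskResult, SEGRecord, label_for

HOURS_PER_YEAR = 365.0 * 24.0


class EpaInputs(BaseModel):
    ca: float = Field(ge=0, description="contaminant concentration in air CA, mg/m^3")
    et: float = Field(gt=0, le=24, description="exposure time ET, h/day")
    ef: float = Field(gt=0, le=365, description="exposure frequency EF, days/year")
    ed: float = Field(default=1.0, gt=0, description="exposure duration ED, years (cancels)")


class EpaResult(BaseModel):
    ec: float
    hq: float
    acceptable: bool
    level: int = Field(ge=1, le=5)

    @model_validator(mode="after")
    def _consistent(self) -> "EpaResult":
        if self.acceptable != (self.hq < 1):
            raise ValueError("acceptable flag must equal (hq < 1)")
        return self


def exposure_concentration(inputs: EpaInputs) -> float:
    """Time-adjusted exposure concentration EC (mg/m^3); invariant to ED."""
    # ED appears in both numerator and AT, so it is omitted rather than
    # multiplied and divided back out.
    return inputs.ca * inputs.et * inputs.ef / HOURS_PER_YEAR


def hazard_quotient(ec: float, rfc: float) -> float:
    if rfc is None or rfc <= 0:
        raise ConfigurationError("hazard quotient requires a positive reference concentration")
    if ec < 0:
        raise ValueError("exposure concentration cannot be negative")
    return ec / rfc


def epa_level(hq: float, cfg: BandingConfig) -> int:
    """Band HQ onto the five-level harmonization scale.

    Defaults place every unacceptable HQ (>= 1) at level 4 or above, so an
    exceeding group maps to a risk ratio of at least 0.8 on a 5-level scale.
    """
    return cfg.epa.level_thresholds.level(hq)


def assess_epa(record: SEGRecord, chem: ChemicalProfile, cfg: BandingConfig) -> EpaResult:
    """Full pathway for one SEG: schedule-derived ET/EF, measured C-TWA as CA."""
    if record.c_twa is None:
        raise ValueError(f"group {record.group_id}: EPA pathway needs a measured c_twa")
    rfc = cfg.epa.rfc_override if cfg.epa.rfc_override is not None else chem.rfc
    if rfc is None:
        raise ConfigurationError("no RfC available: set ChemicalProfile.rfc or epa.rfc_override")
    inputs = EpaInputs(
        ca=record.c_twa,
        et=record.hours_per_day,
        ef=min(365.0, record.days_per_week * cfg.epa.ef_weeks_per_year),
    )
    ec = exposure_concentration(inputs)
    hq = hazard_quotient(ec, rfc)
    return EpaResult(ec=ec, hq=hq, acceptable=hq < 1, level=epa_level(hq, cfg))


def epa_risk_result(record: SEGRecord, chem: ChemicalProfile, cfg: BandingConfig) -> RiskResult:
    res = assess_epa(record, chem, cfg)
    return RiskResult(
        group_id=record.group_id,
        category=record.category,
        method=MethodId.epa,
        raw=res.hq,
        level=res.level,
        scale_size=5,
        label=label_for(res.level, 5),
    )
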