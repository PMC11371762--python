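"""Domain types for similar-exposure-group (SEG) surveys of airborne solvents.

A SEG is a set of workers sharing a process and hence an exposure profile; it
is the unit at which occupational hygienists measure 8-h time-weighted average
(C-TWA) and short-term (C-STEL) air concentrations and record control
measures.  This module holds the chemical hazard profile, the SEG survey
record, exposure-limit compliance checks and the median/range summaries used
to describe a surveyed population.
"""

from __future__ import annotations

import enum
import statistics
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

from .config import ConfigurationError


class Category(str, enum.Enum):
    printing = "printing"
    oil_blending = "oil_blending"
    cleaning = "cleaning"
    pasting = "pasting"


class Automation(str, enum.Enum):
    full = "full"
    semi = "semi"
    manual = "manual"


class Ventilation(str, enum.Enum):
    general = "general"
    local_exhaust = "local_exhaust"


class HealthMgmt(str, enum.Enum):
    good = "good"
    poor = "poor"
    none = "none"


class MethodId(str, enum.Enum):
    """The assessment methods the pipeline can run."""

    icmm = "icmm"
    coshh = "coshh"
    epa = "epa"
    mom_er = "mom_er"
    mom_ei = "mom_ei"
    gbz_er = "gbz_er"
    gbz_ei = "gbz_ei"
    gbz_si = "gbz_si"


#: The seven methods entering the cross-model consistency analysis.  The
#: GBZ exposure-ratio method is implemented but is computationally identical
#: to the MOM exposure-ratio method under identical band tables, so it is not
#: part of the default comparison set.
COMPARED_METHODS: Tuple[MethodId, ...] = (
    MethodId.icmm,
    MethodId.coshh,
    MethodId.epa,
    MethodId.mom_er,
    MethodId.mom_ei,
    MethodId.gbz_ei,
    MethodId.gbz_si,
)

#: Number of ordinal output levels per method (the risk-ratio denominator).
SCALE_SIZES: Dict[MethodId, int] = {
    MethodId.icmm: 4,
    MethodId.coshh: 4,
    MethodId.epa: 5,
    MethodId.mom_er: 5,
    MethodId.mom_ei: 5,
    MethodId.gbz_er: 5,
    MethodId.gbz_ei: 5,
    MethodId.gbz_si: 5,
}

#: Risk vocabulary for five-level scales.
LABELS_5 = {1: "potential", 2: "low", 3: "medium", 4: "high", 5: "very_high"}
#: Four-level scales reuse the same vocabulary with "low" skipped, matching
#: the matrix models' wording (level 3 "high risk", level 4 "very high risk").
LABELS_4 = {1: "potential", 2: "medium", 3: "high", 4: "very_high"}


def label_for(level: int, scale_size: int) -> str:
    table = LABELS_5 if scale_size == 5 else LABELS_4
    if level not in table:
        raise ValueError(f"level {level} outside 1..{scale_size}")
    return table[level]


class SegValidationError(ValueError):
    """A survey row violated the schema; the message names the field."""


class ChemicalProfile(BaseModel):
    """Limits, toxicity and physical properties of the assessed substance.

    oel_twa / oel_stel are the permissible 8-h TWA and short-term limits
    (PC-TWA / PC-STEL) used as compliance thresholds and E/OEL denominators;
    rfc is the chronic inhalation reference concentration of the hazard-
    quotient pathway.
    """

    name: str
    cas_number: str = ""
    oel_twa: float = Field(gt=0, description="PC-TWA, mg/m^3")
    oel_stel: float = Field(gt=0, description="PC-STEL, mg/m^3")
    rfc: Optional[float] = Field(default=None, description="reference concentration, mg/m^3")
    ld50_oral: Optional[float] = Field(default=None, gt=0, description="oral rat LD50, mg/kg")
    lc50_inhalation: Optional[float] = Field(default=None, gt=0, description="4-h rat LC50, mg/L")
    boiling_point: Optional[float] = Field(default=None, description="degC")
    vapor_pressure: Optional[float] = Field(default=None, ge=0, description="kPa at 20 degC")
    risk_phrases: List[str] = Field(default_factory=list)
    carcinogen_class: Optional[str] = None

    @field_validator("rfc")
    @classmethod
    def _rfc_positive(cls, v):
        if v is not None and v <= 0:
            raise ValueError("rfc must be positive when provided")
        return v


def default_hexane_profile() -> ChemicalProfile:
    """Shipped n-hexane profile.

    The exposure limits (PC-TWA 100 mg/m^3, PC-STEL 180 mg/m^3) come from the
    Chinese workplace chemical limits standard; the RfC default of 0.7 mg/m^3
    is the EPA IRIS chronic inhalation value.  All four are configuration, not
    survey data, and are meant to be overridden for other substances.
    """
    return ChemicalProfile(
        name="n-hexane",
        cas_number="110-54-3",
        oel_twa=100.0,
        oel_stel=180.0,
        rfc=0.7,
        ld50_oral=25000.0,
        boiling_point=69.0,
        vapor_pressure=17.6,
        risk_phrases=["R48", "R38", "R65", "R67"],
    )


class SEGRecord(BaseModel):
    """One similar-exposure-group survey row (the unit of assessment)."""

    group_id: str
    category: Category
    n_workers: int = Field(ge=1)
    tenure_months: float = Field(gt=0)
    daily_usage: float = Field(ge=0, description="kg or L per day (unit tag only, never converted)")
    weekly_usage: Optional[float] = Field(default=None, ge=0)
    hours_per_day: float = Field(ge=1, le=24)
    days_per_week: int = Field(ge=1, le=7)
    c_twa: Optional[float] = Field(default=None, ge=0, description="measured 8-h TWA, mg/m^3")
    c_stel: Optional[float] = Field(default=None, ge=0, description="measured short-term conc., mg/m^3")
    automation: Automation
    ventilation: Ventilation
    first_aid: bool
    ppe_equipped: bool
    ppe_used: bool
    emergency_complete: bool
    health_mgmt: HealthMgmt

    @model_validator(mode="after")
    def _derive_and_check(self) -> "SEGRecord":
        if self.weekly_usage is None:
            # one usage block per workday
            self.weekly_usage = self.daily_usage * self.days_per_week
        if self.ppe_used and not self.ppe_equipped:
            raise ValueError("ppe_used requires ppe_equipped")
        return self


class ComplianceResult(BaseModel):
    twa_exceeds: bool
    stel_exceeds: bool
    e_over_oel: float


def validate_seg(record: Union[SEGRecord, Mapping]) -> SEGRecord:
    """Normalize enums and assert the schema invariants of a survey row."""
    try:
        if isinstance(record, SEGRecord):
            return SEGRecord.model_validate(record.model_dump())
        return SEGRecord.model_validate(dict(record))
    except ValidationError as exc:
        fields = ", ".join(".".join(str(p) for p in e["loc"]) or "<record>" for e in exc.errors())
        raise SegValidationError(f"invalid SEG record (field(s): {fields}): {exc}") from exc


def assess_compliance(record: SEGRecord, chem: ChemicalProfile) -> ComplianceResult:
    """Compare measured concentrations against the permissible limits.

    The exceedance flags compare the raw C-TWA / C-STEL against PC-TWA /
    PC-STEL; ``e_over_oel`` is the weekly-adjusted exposure E = F*D*M/W
    divided by the PC-TWA, the ratio every banding model consumes.
    """
    if chem.oel_twa is None or chem.oel_twa <= 0 or chem.oel_stel is None or chem.oel_stel <= 0:
        raise ConfigurationError("chemical profile must define positive oel_twa and oel_stel")
    from .model_semiquant import weekly_exposure  # late import: semiquant owns Eq. E=F*D*M/W

    c_twa = record.c_twa or 0.0
    c_stel = record.c_stel or 0.0
    e = weekly_exposure(f=record.days_per_week, d=record.hours_per_day, m=c_twa)
    return ComplianceResult(
        twa_exceeds=c_twa > chem.oel_twa,
        stel_exceeds=c_stel > chem.oel_stel,
        e_over_oel=e / chem.oel_twa,
    )


class RiskResult(BaseModel):
    """One method's verdict for one SEG, on that method's own ordinal scale."""

    group_id: str
    category: Optional[Category] = None
    method: MethodId
    raw: float
    level: int = Field(ge=1)
    scale_size: int = Field(ge=2)
    label: str

    @model_validator(mode="after")
    def _level_on_scale(self) -> "RiskResult":
        if self.level > self.scale_size:
            raise ValueError(f"level {self.level} exceeds scale size {self.scale_size}")
        return self


_NUMERIC_FIELDS = (
    "n_workers", "tenure_months", "daily_usage", "weekly_usage",
    "hours_per_day", "days_per_week", "c_twa", "c_stel",
)
_CATEGORICAL_FIELDS = (
    "automation", "ventilation", "first_aid", "ppe_equipped", "ppe_used",
    "emergency_complete", "health_mgmt",
)


def summarize_segs(records: Sequence[SEGRecord]) -> Dict[str, Dict]:
    """Per-category median and (min-max) for numeric fields, proportions for
    categoricals — the layout of a survey summary table.

    Even-length medians use the midpoint of the two central order statistics.
    Empty categories are simply absent from the result.
    """
    out: Dict[str, Dict] = {}
    by_cat: Dict[str, List[SEGRecord]] = {}
    for r in records:
        by_cat.setdefault(r.category.value, []).append(r)
    for cat, recs in by_cat.items():
        summary: Dict[str, object] = {"n_groups": len(recs)}
        for f in _NUMERIC_FIELDS:
            vals = [getattr(r, f) for r in recs if getattr(r, f) is not None]
            if not vals:
                continue
            summary[f] = (float(statistics.median(vals)), float(min(vals)), float(max(vals)))
        for f in _CATEGORICAL_FIELDS:
            vals = [getattr(r, f) for r in recs]
            if isinstance(vals[0], bool):
                summary[f] = sum(vals) / len(vals)
            else:
                levels = [v.value for v in vals]
                summary[f] = {lv: levels.count(lv) / len(levels) for lv in sorted(set(levels))}
        out[cat] = summary
    return out


def summary_frame(summary: Dict[str, Dict]) -> pd.DataFrame:
    """Flatten a summary dict into a display table: one row per statistic."""
    rows = []
    for cat, stats in summary.items():
        for field, val in stats.items():
            if isinstance(val, tuple):
                rows.append({"category": cat, "field": field,
                             "value": f"{val[0]:g} ({val[1]:g}-{val[2]:g})"})
            elif isinstance(val, dict):
                for k, p in val.items():
                    rows.append({"category": cat, "field": f"{field}={k}", "value": f"{100 * p:.1f}%"})
            elif isinstance(val, float):
                rows.append({"category": cat, "field": field, "value": f"{100 * val:.1f}%"})
            else:
                rows.append({"category": cat, "field": field, "value": str(val)})
    return pd.DataFrame(rows)
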