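"""Semi-quantitative risk methods: MOM exposure ratio/index and the three
GBZ/T 298-2017 methods (exposure ratio, exposure index, synthesis index).

All five share the same risk matrix,

    risk = sqrt(HR * ER),   rounded half away from zero to an ordinal 1-5,

where HR is the 1-5 hazard rating of the substance and ER the 1-5 exposure
rating.  The square root is the risk-matrix rule of the source MOM guideline:
with HR and ER both on 1-5 scales a literal product could not land on a 1-5
risk scale, and it is the only reading under which a substance of hazard
rating 2 caps out at risk level 3 (round(sqrt(10))) — the ceiling observed
for n-hexane.

Exposure ratings come from two routes:

* ratio methods — band the weekly time-weighted exposure over the limit,
  E/OEL, with E = F*D*M/W (F exposures/week, D hours per exposure, M the
  measured magnitude, W the 40-h reference week);
* index methods — geometric mean of ordinal 1-5 sub-indices (vapour pressure,
  engineering controls, weekly usage, weekly hours; the GBZ variants add
  emergency readiness, PPE and health management, and the synthesis index
  additionally folds the banded E/OEL back in).
"""

from __future__ import annotations

import enum
import math
from typing import Dict, Sequence

from pydantic import BaseModel, Field, model_validator
from scipy.stats import gmean

from .config import BandingConfig, SemiQuantBlock
from .core_types import ChemicalProfile, MethodId, RiskResult, SEGRecord, label_for
from .hazard_rating import HazardRating, hr_from_toxicity

REFERENCE_WEEK_HOURS = 40.0


class ExposureEstimate(BaseModel):
    f: float = Field(ge=0, description="exposures per week F")
    d: float = Field(ge=0, description="hours per exposure D")
    m: float = Field(ge=0, description="measured magnitude M, mg/m^3")
    w: float = Field(default=REFERENCE_WEEK_HOURS, gt=0, description="reference week W, h")
    e: float = Field(default=0.0, ge=0, description="weekly time-weighted exposure E, mg/m^3")

    @model_validator(mode="after")
    def _derive(self) -> "ExposureEstimate":
        self.e = self.f * self.d * self.m / self.w
        return self


class IndexFactorSet(BaseModel):
    """Named ordinal sub-indices EI_1..EI_n, each on 1-5."""

    factors: Dict[str, int]

    @model_validator(mode="after")
    def _check(self) -> "IndexFactorSet":
        if not self.factors:
            raise ValueError("index factor set must contain at least one factor")
        for name, v in self.factors.items():
            if v not in (1, 2, 3, 4, 5):
                raise ValueError(f"factor {name!r} must be an ordinal 1-5, got {v}")
        return self


class SemiQuantResult(BaseModel):
    group_id: str
    method: MethodId
    hr: HazardRating
    er: float
    raw: float
    level: int = Field(ge=1, le=5)
    label: str
    factors: Dict[str, int] | None = None

    def to_risk_result(self, category=None) -> RiskResult:
        return RiskResult(
            group_id=self.group_id, category=category, method=self.method,
            raw=self.raw, level=self.level, scale_size=5, label=self.label,
        )


def weekly_exposure(f: float, d: float, m: float, w: float = REFERENCE_WEEK_HOURS) -> float:
    """Weekly time-weighted exposure E = F*D*M/W (mg/m^3)."""
    if w <= 0:
        raise ValueError("reference week W must be positive")
    if min(f, d, m) < 0:
        raise ValueError("F, D and M must be non-negative")
    return f * d * m / w


def band_exposure_ratio(e_over_oel: float, block: SemiQuantBlock) -> int:
    """Ordinal exposure rating from the E/OEL ratio."""
    return block.er_bands.level(e_over_oel)


def geometric_mean_index(factors: IndexFactorSet) -> float:
    """(prod EI_i)^(1/n): always within [min EI, max EI]."""
    return float(gmean(list(factors.factors.values())))


def round_half_away(x: float) -> int:
    """Round half away from zero (2.5 -> 3), the convention of the matrix."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def risk_rating(hr: HazardRating, er: float, *, method: MethodId, group_id: str,
                factors: Dict[str, int] | None = None) -> SemiQuantResult:
    """Combine hazard and exposure ratings through the risk matrix."""
    if er <= 0:
        raise ValueError("exposure rating must be positive")
    raw = math.sqrt(hr.value * er)
    level = min(5, max(1, round_half_away(raw)))
    return SemiQuantResult(
        group_id=group_id, method=method, hr=hr, er=er, raw=raw,
        level=level, label=label_for(level, 5), factors=factors,
    )


# ---------------------------------------------------------------------------
# Factor banding shared by the index methods

def _exposure_ratio(record: SEGRecord, chem: ChemicalProfile) -> float:
    if record.c_twa is None:
        raise ValueError(
            f"group {record.group_id}: ratio method needs a measured c_twa; "
            "use the exposure index method when monitoring data are absent"
        )
    e = weekly_exposure(f=record.days_per_week, d=record.hours_per_day, m=record.c_twa)
    return e / chem.oel_twa


def _mom_factors(record: SEGRecord, chem: ChemicalProfile, block: SemiQuantBlock) -> Dict[str, int]:
    if chem.vapor_pressure is None:
        raise ValueError("exposure index method needs the chemical's vapor_pressure")
    weekly_hours = record.days_per_week * record.hours_per_day
    return {
        "vapor_pressure": block.vapor_pressure_bands.level(chem.vapor_pressure),
        "controls": block.controls.index(record.ventilation.value, record.automation.value),
        "weekly_usage": block.weekly_usage_bands.level(record.weekly_usage),
        "weekly_hours": block.weekly_hours_bands.level(weekly_hours),
    }


def _gbz_extra_factors(record: SEGRecord, block: SemiQuantBlock) -> Dict[str, int]:
    if record.ppe_used:
        ppe = block.ppe_index["used"]
    elif record.ppe_equipped:
        ppe = block.ppe_index["equipped_unused"]
    else:
        ppe = block.ppe_index["absent"]
    emergency = block.emergency_index["complete" if record.emergency_complete else "incomplete"]
    return {
        "emergency": emergency,
        "ppe": ppe,
        "health_mgmt": block.health_mgmt_index[record.health_mgmt.value],
    }


# ---------------------------------------------------------------------------
# The five methods

def mom_exposure_ratio_method(record: SEGRecord, chem: ChemicalProfile,
                              cfg: BandingConfig) -> SemiQuantResult:
    block = cfg.semiquant.mom
    er = band_exposure_ratio(_exposure_ratio(record, chem), block)
    hr = hr_from_toxicity(chem, cfg)
    return risk_rating(hr, er, method=MethodId.mom_er, group_id=record.group_id)


def mom_exposure_index_method(record: SEGRecord, chem: ChemicalProfile,
                              cfg: BandingConfig) -> SemiQuantResult:
    block = cfg.semiquant.mom
    factors = IndexFactorSet(factors=_mom_factors(record, chem, block))
    er = geometric_mean_index(factors)
    hr = hr_from_toxicity(chem, cfg)
    return risk_rating(hr, er, method=MethodId.mom_ei, group_id=record.group_id,
                       factors=factors.factors)


def gbz_exposure_ratio_method(record: SEGRecord, chem: ChemicalProfile,
                              cfg: BandingConfig) -> SemiQuantResult:
    # identical computation chain to the MOM ratio method, reading the GBZ
    # config block (band edges may be edited independently)
    block = cfg.semiquant.gbz
    er = band_exposure_ratio(_exposure_ratio(record, chem), block)
    hr = hr_from_toxicity(chem, cfg)
    return risk_rating(hr, er, method=MethodId.gbz_er, group_id=record.group_id)


def gbz_exposure_index_method(record: SEGRecord, chem: ChemicalProfile,
                              cfg: BandingConfig) -> SemiQuantResult:
    block = cfg.semiquant.gbz
    factors = dict(_mom_factors(record, chem, block))
    factors.update(_gbz_extra_factors(record, block))
    fs = IndexFactorSet(factors=factors)
    er = geometric_mean_index(fs)
    hr = hr_from_toxicity(chem, cfg)
    return risk_rating(hr, er, method=MethodId.gbz_ei, group_id=record.group_id, factors=factors)


def gbz_synthesis_index_method(record: SEGRecord, chem: ChemicalProfile,
                               cfg: BandingConfig) -> SemiQuantResult:
    """Exposure-index factor set augmented with the banded E/OEL sub-index."""
    block = cfg.semiquant.gbz
    factors = dict(_mom_factors(record, chem, block))
    factors.update(_gbz_extra_factors(record, block))
    factors["e_over_oel"] = band_exposure_ratio(_exposure_ratio(record, chem), block)
    fs = IndexFactorSet(factors=factors)
    er = geometric_mean_index(fs)
    hr = hr_from_toxicity(chem, cfg)
    return risk_rating(hr, er, method=MethodId.gbz_si, group_id=record.group_id, factors=factors)
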