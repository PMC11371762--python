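"""Control-banding models: COSHH (hazard group x exposure potential) and the
ICMM matrix (health consequence x exposure likelihood).

Both models are pure matrix lookups on categorical axes; every axis banding
and both matrices are configuration, validated for completeness and
monotonicity before use.  COSHH grades exposure potential 1-4 from the
quantity handled and the substance's volatility, with open handling (general
ventilation only, or fully manual work) raising the potential one step; ICMM
grades likelihood from the E/OEL ratio (below half the limit counts as low).
"""

from __future__ import annotations

from typing import Optional

from pydantic import BaseModel, Field

from .config import BandingConfig, ConfigurationError, COSHH_GROUPS
from .core_types import (
    Automation, ChemicalProfile, MethodId, RiskResult, SEGRecord, Ventilation, label_for,
)
from .hazard_rating import CoshhHazardGroup, HazardRating, coshh_hazard_group, icmm_consequence


class CoshhAssessment(BaseModel):
    group_id: str
    hazard_group: str
    volatility_band: str
    quantity_band: str
    exposure_potential: int = Field(ge=1, le=4)
    risk_level: int = Field(ge=1, le=4)


class IcmmAssessment(BaseModel):
    group_id: str
    consequence: HazardRating
    likelihood: str
    risk_level: int = Field(ge=1, le=4)
    label: str


def volatility_band(boiling_point: float, cfg: BandingConfig,
                    process_temp: float = 20.0) -> str:
    """COSHH volatility from the boiling point (room-temperature chart).

    The shipped chart applies to processes near room temperature; elevated
    process temperatures would shift the chart but only the ambient chart is
    configured, so ``process_temp`` is accepted for interface completeness.
    """
    lo, hi = cfg.coshh.volatility_edges
    if boiling_point < lo:
        return "high"
    if boiling_point < hi:
        return "medium"
    return "low"


def quantity_band(weekly_usage: float, cfg: BandingConfig) -> str:
    """small (grams/millilitres), medium (kg/L), large (tonnes/m^3)."""
    if weekly_usage < 0:
        raise ValueError("weekly usage cannot be negative")
    lo, hi = cfg.coshh.quantity_edges
    if weekly_usage < lo:
        return "small"
    if weekly_usage < hi:
        return "medium"
    return "large"


def coshh_exposure_potential(quantity: str, volatility: str, cfg: BandingConfig,
                             automation: Optional[Automation] = None,
                             ventilation: Optional[Ventilation] = None) -> int:
    """Exposure potential 1-4; open handling bumps the base band by one."""
    try:
        base = cfg.coshh.potential_matrix[quantity][volatility]
    except KeyError as exc:
        raise ConfigurationError(f"potential matrix has no entry for {exc}") from exc
    if cfg.coshh.open_handling_bump and automation is not None and ventilation is not None:
        open_handling = (ventilation == Ventilation.general) or (automation == Automation.manual)
        if open_handling:
            base = min(4, base + 1)
    return base


def coshh_risk_level(hazard_group: str, exposure_potential: int, cfg: BandingConfig) -> int:
    if hazard_group not in COSHH_GROUPS:
        raise ConfigurationError(f"unknown hazard group {hazard_group!r}")
    if exposure_potential not in (1, 2, 3, 4):
        raise ConfigurationError(f"exposure potential {exposure_potential} outside the matrix")
    return cfg.coshh.risk_matrix[hazard_group][exposure_potential - 1]


def assess_coshh(record: SEGRecord, chem: ChemicalProfile, cfg: BandingConfig) -> CoshhAssessment:
    if chem.boiling_point is None:
        raise ValueError("COSHH volatility banding needs the chemical's boiling point")
    grp = coshh_hazard_group(chem.risk_phrases, cfg).group
    vol = volatility_band(chem.boiling_point, cfg)
    qty = quantity_band(record.weekly_usage, cfg)
    ep = coshh_exposure_potential(qty, vol, cfg, automation=record.automation,
                                  ventilation=record.ventilation)
    return CoshhAssessment(
        group_id=record.group_id, hazard_group=grp, volatility_band=vol,
        quantity_band=qty, exposure_potential=ep,
        risk_level=coshh_risk_level(grp, ep, cfg),
    )


def coshh_risk_result(record: SEGRecord, chem: ChemicalProfile, cfg: BandingConfig) -> RiskResult:
    a = assess_coshh(record, chem, cfg)
    return RiskResult(group_id=record.group_id, category=record.category,
                      method=MethodId.coshh, raw=float(a.risk_level),
                      level=a.risk_level, scale_size=4, label=label_for(a.risk_level, 4))


def icmm_likelihood(e_over_oel: float, cfg: BandingConfig) -> str:
    """Probability-of-exposure band from E/OEL; bands are [lower, upper)."""
    return cfg.icmm.likelihood(e_over_oel)


def icmm_risk_level(consequence: HazardRating, likelihood: str, cfg: BandingConfig) -> IcmmAssessment:
    if likelihood not in ("low", "medium", "high"):
        raise ConfigurationError(f"unknown likelihood band {likelihood!r}")
    col = ("low", "medium", "high").index(likelihood)
    level = cfg.icmm.risk_matrix[consequence.value][col]
    return IcmmAssessment(group_id="", consequence=consequence, likelihood=likelihood,
                          risk_level=level, label=label_for(level, 4))


def assess_icmm(record: SEGRecord, chem: ChemicalProfile, cfg: BandingConfig) -> IcmmAssessment:
    from .core_types import assess_compliance

    consequence = icmm_consequence(chem, cfg)
    e_over_oel = assess_compliance(record, chem).e_over_oel
    out = icmm_risk_level(consequence, icmm_likelihood(e_over_oel, cfg), cfg)
    out.group_id = record.group_id
    return out


def icmm_risk_result(record: SEGRecord, chem: ChemicalProfile, cfg: BandingConfig) -> RiskResult:
    a = assess_icmm(record, chem, cfg)
    return RiskResult(group_id=record.group_id, category=record.category,
                      method=MethodId.icmm, raw=float(a.risk_level),
                      level=a.risk_level, scale_size=4, label=a.label)
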