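"""Ordinal hazard / consequence ratings of a chemical per model family.

Each model family grades the intrinsic severity of a substance before looking
at exposure: the semi-quantitative methods and the ICMM matrix use a 1-5
hazard rating (HR) banded from acute toxicity (LD50 / LC50) or
carcinogenicity class; COSHH maps risk phrases onto hazard groups A-E.  When
several bases are available the conservative maximum wins — standard practice
in all five frameworks.
"""

from __future__ import annotations

import enum
from typing import List, Optional

from pydantic import BaseModel, Field

from .config import BandingConfig, ToxicityTables, COSHH_GROUPS
from .core_types import ChemicalProfile


class RatingUnavailableError(ValueError):
    """No toxicity datum applicable to the requested rating."""


class UnknownPhraseError(KeyError):
    """A risk phrase has no entry in the configured phrase->group map."""


class RatingBasis(str, enum.Enum):
    acute_toxicity = "acute_toxicity"
    carcinogenicity = "carcinogenicity"
    risk_phrase = "risk_phrase"


class HazardRating(BaseModel):
    value: int = Field(ge=1, le=5)
    basis: RatingBasis


class CoshhHazardGroup(BaseModel):
    group: str

    def __init__(self, **data):
        super().__init__(**data)
        if self.group not in COSHH_GROUPS:
            raise ValueError(f"hazard group must be one of {COSHH_GROUPS}, got {self.group!r}")


def _toxicity_ratings(chem: ChemicalProfile, tables: ToxicityTables):
    """All applicable (rating, basis) pairs for a profile under one table set."""
    out = []
    if chem.ld50_oral is not None:
        out.append((tables.ld50_oral.rating(chem.ld50_oral), RatingBasis.acute_toxicity))
    if chem.lc50_inhalation is not None:
        out.append((tables.lc50_inhalation.rating(chem.lc50_inhalation), RatingBasis.acute_toxicity))
    if chem.carcinogen_class is not None:
        code = chem.carcinogen_class
        if code not in tables.carcinogen_map:
            raise RatingUnavailableError(f"carcinogen class {code!r} not in configured map")
        out.append((tables.carcinogen_map[code], RatingBasis.carcinogenicity))
    return out


def hr_from_toxicity(chem: ChemicalProfile, cfg: BandingConfig) -> HazardRating:
    """Hazard rating for the semi-quantitative (MOM/GBZ) methods.

    Conservative rule: the maximum rating over every applicable basis, the
    basis of that maximum recorded.  Acute toxicity takes precedence on ties.
    """
    ratings = _toxicity_ratings(chem, cfg.hazard_rating.mom)
    if not ratings:
        raise RatingUnavailableError(
            f"no toxicity datum (LD50, LC50 or carcinogen class) for {chem.name!r}"
        )
    value, basis = max(ratings, key=lambda rb: (rb[0], rb[1] == RatingBasis.acute_toxicity))
    return HazardRating(value=value, basis=basis)


def coshh_hazard_group(risk_phrases: List[str], cfg: BandingConfig) -> CoshhHazardGroup:
    """Most severe COSHH hazard group (A-E) mapped by any risk phrase."""
    if not risk_phrases:
        raise RatingUnavailableError("COSHH hazard grouping needs at least one risk phrase")
    phrase_map = cfg.hazard_rating.coshh_phrase_map
    unmapped = [p for p in risk_phrases if p not in phrase_map]
    if unmapped:
        raise UnknownPhraseError(f"risk phrase(s) with no configured hazard group: {unmapped}")
    worst = max(phrase_map[p] for p in risk_phrases)  # A < B < ... < E
    return CoshhHazardGroup(group=worst)


def icmm_consequence(chem: ChemicalProfile, cfg: BandingConfig) -> HazardRating:
    """Health-consequence rating on the ICMM matrix's severity axis."""
    ratings = _toxicity_ratings(chem, cfg.hazard_rating.icmm)
    if not ratings:
        raise RatingUnavailableError(
            f"no toxicity datum for ICMM consequence rating of {chem.name!r}"
        )
    value, basis = max(ratings, key=lambda rb: (rb[0], rb[1] == RatingBasis.acute_toxicity))
    return HazardRating(value=value, basis=basis)
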