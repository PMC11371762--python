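"""Editable banding tables and risk matrices shared by every assessment model.

Every threshold that the risk models read — toxicity band edges, exposure-ratio
bands, the COSHH and ICMM matrices, the HQ-to-level mapping — lives here as
validated configuration with documented defaults, never as a constant buried in
model code.  The defaults are drawn from the published model guidelines
(Singapore MOM semi-quantitative method, GBZ/T 298-2017, COSHH Essentials,
ICMM HRA guidance, EPA inhalation dosimetry); none of them is measurement data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from bisect import bisect_left, bisect_right
from typing import Dict, List, Tuple

from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger("ohra")

COSHH_GROUPS = ("A", "B", "C", "D", "E")
VOLATILITY_BANDS = ("low", "medium", "high")
QUANTITY_BANDS = ("small", "medium", "large")
LIKELIHOOD_BANDS = ("low", "medium", "high")


class ConfigurationError(ValueError):
    """A banding table or matrix failed validation."""


class AscendingBands(BaseModel):
    """Ordinal banding of [0, inf) into ``len(edges)+1`` half-open intervals.

    ``level(x)`` returns 1 for x below the first edge and increments at each
    edge; intervals are [lower, upper), so a value equal to an edge falls in
    the higher band.
    """

    edges: Tuple[float, ...]

    @field_validator("edges")
    @classmethod
    def _strictly_increasing(cls, v: Tuple[float, ...]) -> Tuple[float, ...]:
        if len(v) == 0:
            raise ConfigurationError("band table needs at least one edge")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ConfigurationError(
                f"band edges must be strictly increasing (got {list(v)}): "
                "overlapping or unordered bands are not a partition"
            )
        return v

    @property
    def n_levels(self) -> int:
        return len(self.edges) + 1

    def level(self, x: float) -> int:
        if x < 0:
            raise ValueError(f"band lookup expects a non-negative value, got {x}")
        return 1 + bisect_right(self.edges, x)


class DoseBands(BaseModel):
    """Toxicity banding: the *lower* the dose killing half the animals, the
    *higher* the hazard rating.  Intervals are (lower, upper] on the dose axis,
    so a dose exactly at an edge keeps the more severe rating.
    """

    edges: Tuple[float, ...]

    @field_validator("edges")
    @classmethod
    def _strictly_increasing(cls, v: Tuple[float, ...]) -> Tuple[float, ...]:
        if len(v) == 0:
            raise ConfigurationError("dose band table needs at least one edge")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ConfigurationError(f"dose band edges must be strictly increasing: {list(v)}")
        if v[0] <= 0:
            raise ConfigurationError("dose band edges must be positive")
        return v

    @property
    def n_levels(self) -> int:
        return len(self.edges) + 1

    def rating(self, dose: float) -> int:
        if dose <= 0:
            raise ValueError(f"dose must be positive, got {dose}")
        return self.n_levels - bisect_left(self.edges, dose)


class ToxicityTables(BaseModel):
    """Hazard-rating sources for one model family (conservative max applies)."""

    # Oral rat LD50, mg/kg: (0,25]->5, (25,200]->4, (200,2000]->3,
    # (2000,50000]->2, above->1.  n-hexane (25 g/kg) sits in band 2.
    ld50_oral: DoseBands = DoseBands(edges=(25.0, 200.0, 2000.0, 50000.0))
    # Inhalation LC50 (4 h, rat), mg/L.
    lc50_inhalation: DoseBands = DoseBands(edges=(0.25, 1.0, 2.5, 20.0))
    # IARC / ACGIH carcinogenicity classes; either source is accepted and the
    # conservative maximum over all available bases is taken.
    carcinogen_map: Dict[str, int] = Field(
        default_factory=lambda: {
            "1": 5, "2A": 4, "2B": 3, "3": 2, "4": 1,
            "A1": 5, "A2": 4, "A3": 3, "A4": 2, "A5": 1,
        }
    )

    @field_validator("carcinogen_map")
    @classmethod
    def _ratings_in_range(cls, v: Dict[str, int]) -> Dict[str, int]:
        for code, rating in v.items():
            if rating not in (1, 2, 3, 4, 5):
                raise ConfigurationError(f"carcinogen class {code!r} maps to invalid rating {rating}")
        return v


class HazardRatingConfig(BaseModel):
    mom: ToxicityTables = ToxicityTables()
    icmm: ToxicityTables = ToxicityTables()
    # R-phrase -> COSHH hazard group.  R48 (serious damage to health by
    # prolonged exposure) drives group D for n-hexane.
    coshh_phrase_map: Dict[str, str] = Field(
        default_factory=lambda: {
            "R36": "A", "R37": "A", "R38": "A", "R66": "A", "R67": "A",
            "R20": "B", "R21": "B", "R22": "B", "R65": "B",
            "R23": "C", "R24": "C", "R25": "C", "R34": "C", "R35": "C",
            "R41": "C", "R43": "C",
            "R42": "D", "R48": "D",
            "R45": "E", "R46": "E", "R49": "E",
        }
    )

    @field_validator("coshh_phrase_map")
    @classmethod
    def _groups_valid(cls, v: Dict[str, str]) -> Dict[str, str]:
        for phrase, grp in v.items():
            if grp not in COSHH_GROUPS:
                raise ConfigurationError(f"phrase {phrase!r} maps to unknown hazard group {grp!r}")
        return v


class EpaConfig(BaseModel):
    """Knobs of the EPA non-carcinogenic inhalation pathway."""

    # When set, overrides ChemicalProfile.rfc (mg/m^3).
    rfc_override: float | None = None
    # HQ -> ordinal 1-5: <0.1 -> 1, [0.1,0.5) -> 2, [0.5,1) -> 3,
    # [1,10) -> 4, >=10 -> 5.  Every unacceptable HQ (>=1) lands at >=4.
    level_thresholds: AscendingBands = AscendingBands(edges=(0.1, 0.5, 1.0, 10.0))
    # EF is derived from the weekly schedule: days_per_week * weeks worked/yr.
    ef_weeks_per_year: float = 52.0

    @field_validator("rfc_override")
    @classmethod
    def _positive(cls, v):
        if v is not None and v <= 0:
            raise ConfigurationError("rfc_override must be positive")
        return v


class ControlsTable(BaseModel):
    """Exposure sub-index for engineering controls: ventilation x automation."""

    table: Dict[str, Dict[str, int]] = Field(
        default_factory=lambda: {
            "local_exhaust": {"full": 1, "semi": 2, "manual": 3},
            "general": {"full": 3, "semi": 4, "manual": 5},
        }
    )

    @model_validator(mode="after")
    def _validate(self) -> "ControlsTable":
        for vent in ("general", "local_exhaust"):
            if vent not in self.table:
                raise ConfigurationError(f"controls table missing ventilation class {vent!r}")
            for auto in ("full", "semi", "manual"):
                val = self.table[vent].get(auto)
                if val not in (1, 2, 3, 4, 5):
                    raise ConfigurationError(f"controls table ({vent},{auto}) invalid: {val}")
        # local exhaust must never score worse than general ventilation
        for auto in ("full", "semi", "manual"):
            if self.table["local_exhaust"][auto] > self.table["general"][auto]:
                raise ConfigurationError("controls table not monotone: local exhaust scored above general")
        return self

    def index(self, ventilation: str, automation: str) -> int:
        try:
            return self.table[ventilation][automation]
        except KeyError as exc:
            raise ConfigurationError(f"controls table has no entry for {exc}") from exc


class SemiQuantBlock(BaseModel):
    """Exposure-rating tables for one semi-quantitative family (MOM or GBZ).

    ``er_bands`` maps E/OEL onto the ordinal exposure rating; the factor
    tables band the exposure-index sub-indices EI_i.  The GBZ methods read the
    extended factors (emergency, PPE, health management) on top of the four
    MOM factors (vapour pressure, controls, weekly usage, weekly hours).
    """

    er_bands: AscendingBands = AscendingBands(edges=(0.1, 0.5, 1.0, 2.0))
    vapor_pressure_bands: AscendingBands = AscendingBands(edges=(0.1, 1.0, 10.0, 50.0))  # kPa
    weekly_usage_bands: AscendingBands = AscendingBands(edges=(1.0, 10.0, 100.0, 1000.0))  # kg or L
    weekly_hours_bands: AscendingBands = AscendingBands(edges=(10.0, 20.0, 40.0, 50.0))  # h/week
    controls: ControlsTable = ControlsTable()
    # Extended (GBZ) sub-indices
    emergency_index: Dict[str, int] = Field(default_factory=lambda: {"complete": 1, "incomplete": 4})
    ppe_index: Dict[str, int] = Field(
        default_factory=lambda: {"used": 1, "equipped_unused": 3, "absent": 5}
    )
    health_mgmt_index: Dict[str, int] = Field(
        default_factory=lambda: {"good": 1, "poor": 3, "none": 5}
    )

    @model_validator(mode="after")
    def _validate_maps(self) -> "SemiQuantBlock":
        for name, mapping, keys in (
            ("emergency_index", self.emergency_index, ("complete", "incomplete")),
            ("ppe_index", self.ppe_index, ("used", "equipped_unused", "absent")),
            ("health_mgmt_index", self.health_mgmt_index, ("good", "poor", "none")),
        ):
            for k in keys:
                if mapping.get(k) not in (1, 2, 3, 4, 5):
                    raise ConfigurationError(f"{name}[{k!r}] must be an ordinal 1-5")
        return self


class SemiQuantConfig(BaseModel):
    mom: SemiQuantBlock = SemiQuantBlock()
    gbz: SemiQuantBlock = SemiQuantBlock()


def _check_matrix_monotone(rows: List[List[int]], name: str, lo: int, hi: int) -> None:
    for r, row in enumerate(rows):
        for c, val in enumerate(row):
            if not (lo <= val <= hi):
                raise ConfigurationError(f"{name}[{r}][{c}] = {val} outside [{lo}, {hi}]")
            if c > 0 and row[c - 1] > val:
                raise ConfigurationError(f"{name} row {r} not monotone non-decreasing")
            if r > 0 and rows[r - 1][c] > val:
                raise ConfigurationError(f"{name} column {c} not monotone non-decreasing")


class CoshhConfig(BaseModel):
    """COSHH Essentials control-banding tables (room-temperature processes)."""

    # Boiling point (degC) -> volatility: < 50 high, [50, 150) medium, >= 150 low.
    volatility_edges: Tuple[float, float] = (50.0, 150.0)
    # Quantity used per week (kg or L): < 1 small, [1, 1000) medium, >= 1000 large.
    quantity_edges: Tuple[float, float] = (1.0, 1000.0)
    # Base exposure potential, quantity band x volatility band.
    potential_matrix: Dict[str, Dict[str, int]] = Field(
        default_factory=lambda: {
            "small": {"low": 1, "medium": 1, "high": 2},
            "medium": {"low": 1, "medium": 2, "high": 3},
            "large": {"low": 2, "medium": 3, "high": 4},
        }
    )
    # Open handling (general ventilation only, or fully manual operation)
    # raises the exposure potential one step, capped at 4.
    open_handling_bump: bool = True
    # Hazard group (A-E) x exposure potential (1-4) -> risk level 1-4.
    risk_matrix: Dict[str, Tuple[int, int, int, int]] = Field(
        default_factory=lambda: {
            "A": (1, 1, 1, 2),
            "B": (1, 1, 2, 2),
            "C": (1, 2, 3, 3),
            "D": (2, 3, 4, 4),
            "E": (3, 4, 4, 4),
        }
    )

    @model_validator(mode="after")
    def _validate(self) -> "CoshhConfig":
        if not self.volatility_edges[0] < self.volatility_edges[1]:
            raise ConfigurationError("volatility edges must be increasing")
        if not 0 < self.quantity_edges[0] < self.quantity_edges[1]:
            raise ConfigurationError("quantity edges must be positive and increasing")
        rows = []
        for q in QUANTITY_BANDS:
            if q not in self.potential_matrix:
                raise ConfigurationError(f"potential matrix missing quantity band {q!r}")
            rows.append([self.potential_matrix[q][v] for v in VOLATILITY_BANDS])
        _check_matrix_monotone(rows, "coshh.potential_matrix", 1, 4)
        rows = []
        for g in COSHH_GROUPS:
            if g not in self.risk_matrix:
                raise ConfigurationError(f"COSHH risk matrix missing hazard group {g!r}")
            if len(self.risk_matrix[g]) != 4:
                raise ConfigurationError(f"COSHH risk matrix row {g!r} must have 4 entries")
            rows.append(list(self.risk_matrix[g]))
        _check_matrix_monotone(rows, "coshh.risk_matrix", 1, 4)
        return self


class IcmmConfig(BaseModel):
    """ICMM matrix: consequence (1-5) x exposure likelihood -> risk level 1-4."""

    # E/OEL -> likelihood: < 0.5 low, [0.5, 1) medium, >= 1 high.
    likelihood_edges: Tuple[float, float] = (0.5, 1.0)
    risk_matrix: Dict[int, Tuple[int, int, int]] = Field(
        default_factory=lambda: {
            1: (1, 1, 2),
            2: (1, 2, 3),
            3: (2, 2, 3),
            4: (2, 3, 4),
            5: (3, 3, 4),
        }
    )

    @model_validator(mode="after")
    def _validate(self) -> "IcmmConfig":
        if not 0 < self.likelihood_edges[0] < self.likelihood_edges[1]:
            raise ConfigurationError("likelihood edges must be positive and increasing")
        rows = []
        for c in (1, 2, 3, 4, 5):
            if c not in self.risk_matrix:
                raise ConfigurationError(f"ICMM risk matrix missing consequence level {c}")
            if len(self.risk_matrix[c]) != 3:
                raise ConfigurationError(f"ICMM risk matrix row {c} must have 3 entries")
            rows.append(list(self.risk_matrix[c]))
        _check_matrix_monotone(rows, "icmm.risk_matrix", 1, 4)
        return self

    def likelihood(self, e_over_oel: float) -> str:
        if e_over_oel < 0:
            raise ValueError("E/OEL cannot be negative")
        lo, hi = self.likelihood_edges
        if e_over_oel < lo:
            return "low"
        if e_over_oel < hi:
            return "medium"
        return "high"


class BandingConfig(BaseModel):
    """The complete, validated set of tables every model reads."""

    hazard_rating: HazardRatingConfig = HazardRatingConfig()
    epa: EpaConfig = EpaConfig()
    semiquant: SemiQuantConfig = SemiQuantConfig()
    coshh: CoshhConfig = CoshhConfig()
    icmm: IcmmConfig = IcmmConfig()

    @classmethod
    def default(cls) -> "BandingConfig":
        return cls()

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def log_defaults(self, overridden: set[str] | None = None) -> None:
        """Audit trail: record which top-level blocks run on shipped defaults."""
        overridden = overridden or set()
        for block in ("hazard_rating", "epa", "semiquant", "coshh", "icmm"):
            if block not in overridden:
                logger.info("config block %r uses shipped defaults", block)
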