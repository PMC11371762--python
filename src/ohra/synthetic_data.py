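"""Seeded generator of synthetic SEG survey tables.

The surveyed enterprise data behind the published summaries are not deposited
anywhere, so the pipeline is exercised on synthetic tables that emulate the
printed per-category statistics: air concentrations and usage are log-normal
(the standard occupational-hygiene model, and the only simple one consistent
with the right-skewed median-versus-range pattern of the summaries), the
short-term concentration is the TWA times a log-normal excursion factor
floored at 1, schedules are discrete distributions over the printed ranges,
and control measures are independent categoricals at the printed proportions.

``CALIBRATION_SUMMARY`` below is calibration data transcribed from published
per-category summary statistics (medians, ranges, proportions) — it is not a
measurement dataset, and per-group joint structure (e.g. correlation between
PPE and management quality) is invented as independent because it was never
published.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .core_types import SEGRecord, validate_seg

#: z for the central ~99% interval of a normal; the printed (min-max) range of
#: each log-normal field is treated as that interval.
_RANGE_Z = 2.5758293035489004

#: Published per-category summary statistics used to pre-fill the default
#: generator spec (calibration data, not measurements).  Tuples are
#: (median, min, max); bare floats are proportions.
CALIBRATION_SUMMARY: Dict[str, Dict] = {
    "printing": {
        "n_groups": 32,
        "n_workers": (4, 1, 24),
        "tenure_months": (63.5, 9, 148),
        "daily_usage": (3.57, 0.25, 106.94),
        "c_twa": (8.10, 0.07, 91.40),
        "c_stel": (24.70, 0.30, 324.70),
        "hours_per_day": (8, 8, 10),
        "days_per_week": (6, 5, 6),
        "automation": {"full": 0.0, "semi": 31 / 32, "manual": 1 / 32},
        "ventilation": {"general": 16 / 32, "local_exhaust": 16 / 32},
        "first_aid": 13 / 32,
        "ppe_equipped": 15 / 32,
        "ppe_used": 10 / 32,
        "emergency_complete": 5 / 32,
        "health_mgmt": {"good": 5 / 32, "poor": 11 / 32, "none": 16 / 32},
    },
    "oil_blending": {
        "n_groups": 17,
        "n_workers": (2, 1, 5),
        "tenure_months": (64, 8, 136),
        "daily_usage": (2.25, 0.21, 51.39),
        "c_twa": (4.80, 0.07, 88.00),
        "c_stel": (11.90, 0.30, 333.60),
        "hours_per_day": (8, 8, 10),
        "days_per_week": (6, 5, 6),
        "automation": {"full": 0.0, "semi": 1 / 17, "manual": 16 / 17},
        "ventilation": {"general": 13 / 17, "local_exhaust": 4 / 17},
        "first_aid": 6 / 17,
        "ppe_equipped": 7 / 17,
        "ppe_used": 6 / 17,
        "emergency_complete": 3 / 17,
        "health_mgmt": {"good": 3 / 17, "poor": 5 / 17, "none": 9 / 17},
    },
    "cleaning": {
        "n_groups": 14,
        "n_workers": (1, 1, 2),
        "tenure_months": (78.5, 35, 147),
        "daily_usage": (0.51, 0.21, 80),
        "c_twa": (6.15, 0.07, 143.70),
        "c_stel": (13.60, 0.30, 290.60),
        "hours_per_day": (8, 8, 10),
        "days_per_week": (6, 5, 6),
        "automation": {"full": 0.0, "semi": 0.0, "manual": 1.0},
        "ventilation": {"general": 12 / 14, "local_exhaust": 2 / 14},
        "first_aid": 4 / 14,
        "ppe_equipped": 6 / 14,
        "ppe_used": 5 / 14,
        "emergency_complete": 3 / 14,
        "health_mgmt": {"good": 1 / 14, "poor": 6 / 14, "none": 7 / 14},
    },
    "pasting": {
        "n_groups": 21,
        "n_workers": (3, 1, 12),
        "tenure_months": (106, 17, 146),
        "daily_usage": (1.04, 0.35, 90.28),
        "c_twa": (0.10, 0.07, 27.60),
        "c_stel": (0.90, 0.30, 54.10),
        "hours_per_day": (8, 8, 10),
        "days_per_week": (6, 5, 6),
        "automation": {"full": 0.0, "semi": 9 / 21, "manual": 12 / 21},
        "ventilation": {"general": 19 / 21, "local_exhaust": 2 / 21},
        "first_aid": 8 / 21,
        "ppe_equipped": 8 / 21,
        "ppe_used": 5 / 21,
        "emergency_complete": 6 / 21,
        "health_mgmt": {"good": 3 / 21, "poor": 6 / 21, "none": 12 / 21},
    },
}


class LogNormalSpec(BaseModel):
    """Log-normal field: exp(mu) equals the printed median, sigma chosen so
    the central ~99% interval spans the printed range; samples are clipped to
    the range (which leaves the median untouched)."""

    median: float = Field(gt=0)
    lo: float = Field(gt=0)
    hi: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "LogNormalSpec":
        if not self.lo <= self.median <= self.hi:
            raise ValueError(
                f"median {self.median} outside range ({self.lo}, {self.hi})"
            )
        return self

    @property
    def sigma(self) -> float:
        if self.hi == self.lo:
            return 0.0
        return (math.log(self.hi) - math.log(self.lo)) / (2 * _RANGE_Z)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sigma == 0.0:
            return np.full(n, self.median)
        draws = rng.lognormal(mean=math.log(self.median), sigma=self.sigma, size=n)
        return np.clip(draws, self.lo, self.hi)


def _check_probs(mapping: Dict, name: str) -> None:
    total = sum(mapping.values())
    if any(p < 0 or p > 1 for p in mapping.values()) or abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities must lie in [0,1] and sum to 1 (got {mapping})")


class CategorySpec(BaseModel):
    n_groups: int = Field(ge=1)
    n_workers: Tuple[int, int]
    tenure_months: LogNormalSpec
    daily_usage: LogNormalSpec
    c_twa: LogNormalSpec
    stel_ratio_median: float = Field(gt=0)
    stel_ratio_sigma: float = Field(default=0.5, ge=0)
    stel_max: float = Field(gt=0)
    hours_per_day: Dict[int, float]
    days_per_week: Dict[int, float]
    automation: Dict[str, float]
    ventilation: Dict[str, float]
    first_aid: float = Field(ge=0, le=1)
    ppe_equipped: float = Field(ge=0, le=1)
    ppe_used: float = Field(ge=0, le=1)
    emergency_complete: float = Field(ge=0, le=1)
    health_mgmt: Dict[str, float]

    @model_validator(mode="after")
    def _valid_probs(self) -> "CategorySpec":
        for name in ("hours_per_day", "days_per_week", "automation", "ventilation", "health_mgmt"):
            _check_probs(getattr(self, name), name)
        if self.ppe_used > self.ppe_equipped + 1e-12:
            raise ValueError("ppe_used proportion cannot exceed ppe_equipped")
        if self.n_workers[0] < 1 or self.n_workers[1] < self.n_workers[0]:
            raise ValueError(f"invalid worker range {self.n_workers}")
        return self


class GeneratorSpec(BaseModel):
    categories: Dict[str, CategorySpec]

    @property
    def total_groups(self) -> int:
        return sum(c.n_groups for c in self.categories.values())


def _discrete_from_median_range(median: float, lo: float, hi: float) -> Dict[int, float]:
    """Discrete schedule distribution: 70% mass at the printed median, the
    rest spread evenly over the remaining integers of the printed range."""
    support = list(range(int(lo), int(hi) + 1))
    med = int(median)
    if med not in support:
        raise ValueError(f"median {median} outside range ({lo}, {hi})")
    if len(support) == 1:
        return {med: 1.0}
    rest = [v for v in support if v != med]
    return {med: 0.7, **{v: 0.3 / len(rest) for v in rest}}


def spec_from_summary(summary: Dict[str, Dict]) -> GeneratorSpec:
    """Build a generator spec from per-category medians/ranges/proportions."""
    cats = {}
    for cat, s in summary.items():
        twa = LogNormalSpec(median=s["c_twa"][0], lo=s["c_twa"][1], hi=s["c_twa"][2])
        stel_med, _, stel_hi = s["c_stel"]
        cats[cat] = CategorySpec(
            n_groups=s["n_groups"],
            n_workers=(int(s["n_workers"][1]), int(s["n_workers"][2])),
            tenure_months=LogNormalSpec(
                median=s["tenure_months"][0], lo=s["tenure_months"][1], hi=s["tenure_months"][2]),
            daily_usage=LogNormalSpec(
                median=s["daily_usage"][0], lo=s["daily_usage"][1], hi=s["daily_usage"][2]),
            c_twa=twa,
            stel_ratio_median=max(1.0, stel_med / twa.median),
            stel_max=stel_hi,
            hours_per_day=_discrete_from_median_range(*s["hours_per_day"]),
            days_per_week=_discrete_from_median_range(*s["days_per_week"]),
            automation=dict(s["automation"]),
            ventilation=dict(s["ventilation"]),
            first_aid=float(s["first_aid"]),
            ppe_equipped=float(s["ppe_equipped"]),
            ppe_used=float(s["ppe_used"]),
            emergency_complete=float(s["emergency_complete"]),
            health_mgmt=dict(s["health_mgmt"]),
        )
    return GeneratorSpec(categories=cats)


def default_generator_spec() -> GeneratorSpec:
    return spec_from_summary(CALIBRATION_SUMMARY)


def _choice(rng: np.random.Generator, dist: Dict) -> object:
    keys = list(dist)
    return keys[rng.choice(len(keys), p=np.array([dist[k] for k in keys]))]


def generate_segs(spec: GeneratorSpec, seed: int,
                  n_override: Dict[str, int] | None = None) -> List[SEGRecord]:
    """Draw a reproducible synthetic SEG table.

    One sub-stream per category (keyed by seed and category position) so that
    editing one category's spec never perturbs the draws of another.
    ``n_override`` scales a category's group count (for large-n checks).
    """
    records: List[SEGRecord] = []
    for idx, (cat, cs) in enumerate(spec.categories.items()):
        rng = np.random.default_rng([int(seed), idx])
        n = (n_override or {}).get(cat, cs.n_groups)
        twa = cs.c_twa.sample(rng, n)
        ratio = np.maximum(1.0, rng.lognormal(math.log(cs.stel_ratio_median),
                                              cs.stel_ratio_sigma, size=n))
        stel = np.minimum(twa * ratio, cs.stel_max)
        tenure = cs.tenure_months.sample(rng, n)
        usage = cs.daily_usage.sample(rng, n)
        for i in range(n):
            equipped = bool(rng.random() < cs.ppe_equipped)
            p_used = cs.ppe_used / cs.ppe_equipped if cs.ppe_equipped > 0 else 0.0
            used = equipped and bool(rng.random() < p_used)
            rec = SEGRecord(
                group_id=f"{cat}-{i + 1:04d}",
                category=cat,
                n_workers=int(rng.integers(cs.n_workers[0], cs.n_workers[1] + 1)),
                tenure_months=float(tenure[i]),
                daily_usage=float(usage[i]),
                hours_per_day=float(_choice(rng, cs.hours_per_day)),
                days_per_week=int(_choice(rng, cs.days_per_week)),
                c_twa=float(twa[i]),
                c_stel=float(max(stel[i], twa[i])),
                automation=_choice(rng, cs.automation),
                ventilation=_choice(rng, cs.ventilation),
                first_aid=bool(rng.random() < cs.first_aid),
                ppe_equipped=equipped,
                ppe_used=used,
                emergency_complete=bool(rng.random() < cs.emergency_complete),
                health_mgmt=_choice(rng, cs.health_mgmt),
            )
            records.append(validate_seg(rec))
    return records
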