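"""Risk-ratio (RR) standardization making heterogeneous model outputs
comparable.

Each model grades risk on its own ordinal scale (4 levels for the matrix
models, 5 for the others), so raw levels are not comparable across models.
The risk ratio divides the assigned level by the model's total number of
levels, RR = level / scale_size in (0, 1], and RR is then banded onto five
standard intervals:

    band 1  [0, 0.2)   potential risk
    band 2  [0.2, 0.4) low risk
    band 3  [0.4, 0.6) medium risk
    band 4  [0.6, 0.8) high risk
    band 5  [0.8, 1]   very high risk

Bands are half-open with the top band closed at 1 — the only convention under
which a level-1 result on a 5-level scale (RR = 0.2) lands in band 2 and a
maximal result (RR = 1) lands in band 5.
"""

from __future__ import annotations

from typing import Dict, List, Literal, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .core_types import Category, MethodId, RiskResult, label_for

RR_BAND_EDGES = (0.2, 0.4, 0.6, 0.8)


class HarmonizedResult(BaseModel):
    group_id: str
    category: Category | None = None
    method: MethodId
    level: int = Field(ge=1)
    scale_size: int = Field(ge=2)
    rr: float = Field(gt=0, le=1)
    rr_band: int = Field(ge=1, le=5)
    band_label: str


def risk_ratio(level: int, scale_size: int) -> float:
    """RR = assessed level / total levels of the model."""
    if not 1 <= level <= scale_size:
        raise ValueError(f"level {level} outside 1..{scale_size}")
    return level / scale_size


def rr_band(rr: float) -> int:
    """Five-level band of an RR value; intervals [lower, upper), top closed."""
    if not 0 < rr <= 1:
        raise ValueError(f"risk ratio must lie in (0, 1], got {rr}")
    band = 1
    for edge in RR_BAND_EDGES:
        if rr >= edge:
            band += 1
    return band


def harmonize(results: Sequence[RiskResult]) -> List[HarmonizedResult]:
    """Apply RR conversion and banding to every model verdict (one per input)."""
    out = []
    for r in results:
        if r.method not in MethodId.__members__.values():
            raise ValueError(f"unknown method {r.method!r}")
        rr = risk_ratio(r.level, r.scale_size)
        band = rr_band(rr)
        out.append(HarmonizedResult(
            group_id=r.group_id, category=r.category, method=r.method,
            level=r.level, scale_size=r.scale_size,
            rr=rr, rr_band=band, band_label=label_for(band, 5),
        ))
    return out


class FrequencyTable(BaseModel):
    """Band x method counts (and percentages) per category or in total."""

    model_config = {"arbitrary_types_allowed": True}

    counts: pd.DataFrame
    formatted: pd.DataFrame
    n_groups: Dict[str, int]

    def to_csv(self, path) -> None:
        self.formatted.to_csv(path)


def _table_for(harmonized: Sequence[HarmonizedResult]) -> pd.DataFrame:
    methods = sorted({h.method.value for h in harmonized})
    bands = sorted({h.rr_band for h in harmonized})
    counts = pd.DataFrame(0, index=pd.Index(bands, name="rr_band"),
                          columns=pd.Index(methods, name="method"))
    for h in harmonized:
        counts.loc[h.rr_band, h.method.value] += 1
    return counts


def frequency_table(harmonized: Sequence[HarmonizedResult],
                    by: Literal["total", "category"] = "total") -> FrequencyTable:
    """Counts and "pct% (k/n)" cells per RR band per method."""
    if not harmonized:
        empty = pd.DataFrame()
        return FrequencyTable(counts=empty, formatted=empty, n_groups={})

    if by == "total":
        groups = {"total": list(harmonized)}
    elif by == "category":
        groups = {}
        for h in harmonized:
            key = h.category.value if h.category is not None else "uncategorized"
            groups.setdefault(key, []).append(h)
    else:
        raise ValueError(f"unknown grouping {by!r}")

    count_frames, fmt_frames, n_groups = [], [], {}
    for key, hs in groups.items():
        counts = _table_for(hs)
        n = len({h.group_id for h in hs})
        n_groups[key] = n
        fmt = counts.map(lambda k: f"{100 * k / n:.1f}% ({k}/{n})" if n else "0")
        counts.index = pd.MultiIndex.from_product([[key], counts.index],
                                                  names=["group", "rr_band"])
        fmt.index = counts.index
        count_frames.append(counts)
        fmt_frames.append(fmt)
    counts = pd.concat(count_frames).fillna(0).astype(int)
    formatted = pd.concat(fmt_frames).fillna("0.0% (0/0)")
    return FrequencyTable(counts=counts, formatted=formatted, n_groups=n_groups)
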