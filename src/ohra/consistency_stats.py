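"""Cross-method consistency statistics.

Two questions are asked of the harmonized risk ratios: do the methods differ
systematically (Kruskal-Wallis H with tie correction, followed by Dunn-type
pairwise rank comparisons under a family-wise adjustment), and do pairs of
methods agree beyond chance (unweighted Cohen's kappa on the five RR bands,
with the conventional interpretation bands: below 0.2 poor, 0.2-0.4 general,
0.4-0.6 medium, 0.6-0.8 strong, 0.8 and above very strong).
"""

from __future__ import annotations

import enum
import itertools
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa
from statsmodels.stats.multitest import multipletests

from .harmonization import HarmonizedResult

KAPPA_INTERPRETATION_EDGES = (0.2, 0.4, 0.6, 0.8)


class KappaInterpretation(str, enum.Enum):
    poor = "poor"
    general = "general"
    medium = "medium"
    strong = "strong"
    very_strong = "very_strong"


def interpret_kappa(kappa: float) -> KappaInterpretation:
    if not -1 <= kappa <= 1:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    names = list(KappaInterpretation)
    idx = sum(kappa >= e for e in KAPPA_INTERPRETATION_EDGES)
    return names[idx]


class KWResult(BaseModel):
    model_config = {"arbitrary_types_allowed": True}

    h_statistic: float = Field(ge=0)
    p_value: float = Field(ge=0, le=1)
    group_mean_ranks: Dict[str, float]
    pairwise: pd.DataFrame  # columns: a, b, z, p_raw, p_adj, significant


class KappaResult(BaseModel):
    kappa: float = Field(ge=-1, le=1)
    p_value: float | None
    interpretation: KappaInterpretation


def _dunn_pairwise(samples: Mapping[str, Sequence[float]], adjust: str) -> pd.DataFrame:
    """Dunn-type z-tests on mean ranks with tie correction."""
    names = list(samples)
    pooled = np.concatenate([np.asarray(samples[n], dtype=float) for n in names])
    sizes = {n: len(samples[n]) for n in names}
    ranks = stats.rankdata(pooled)
    mean_ranks, start = {}, 0
    for n in names:
        mean_ranks[n] = float(ranks[start:start + sizes[n]].mean())
        start += sizes[n]
    n_tot = len(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12 * (n_tot - 1)))
    base_var = n_tot * (n_tot + 1) / 12.0 - tie_term

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1 / sizes[a] + 1 / sizes[b]))
        z = 0.0 if se == 0 else (mean_ranks[a] - mean_ranks[b]) / se
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"a": a, "b": b, "z": z, "p_raw": p})
    table = pd.DataFrame(rows)
    if len(table):
        reject, p_adj, _, _ = multipletests(table["p_raw"], alpha=0.05, method=adjust)
        table["p_adj"] = p_adj
        table["significant"] = reject
    return table


def kruskal_wallis(samples: Mapping[str, Sequence[float]],
                   adjust: str = "bonferroni") -> KWResult:
    """Tie-corrected Kruskal-Wallis H across methods plus pairwise stage.

    Degenerate case: if every pooled value is identical the test is vacuous
    and (H=0, p=1) is returned by convention.
    """
    if len(samples) < 2:
        raise ValueError("Kruskal-Wallis needs at least two method samples")
    for name, vals in samples.items():
        if len(vals) < 2:
            raise ValueError(f"method {name!r} has fewer than two values")
    pooled = np.concatenate([np.asarray(v, dtype=float) for v in samples.values()])
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*[np.asarray(v, dtype=float) for v in samples.values()])
    pairwise = _dunn_pairwise(samples, adjust)
    ranks = stats.rankdata(pooled)
    mean_ranks, start = {}, 0
    for name, vals in samples.items():
        mean_ranks[name] = float(ranks[start:start + len(vals)].mean())
        start += len(vals)
    return KWResult(h_statistic=float(h), p_value=float(p),
                    group_mean_ranks=mean_ranks, pairwise=pairwise)


def cohens_kappa(labels_a: Sequence[int], labels_b: Sequence[int],
                 label_space: Sequence[int] = (1, 2, 3, 4, 5)) -> KappaResult:
    """Unweighted Cohen's kappa between two ordinal label vectors.

    Computed from the contingency table over the shared label space with a
    large-sample two-sided p-value against kappa = 0.  Two identical constant
    vectors are perfect agreement by construction (kappa = 1, no sampling
    distribution, p undefined).
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length ({len(a)} vs {len(b)})")
    if len(a) < 2:
        raise ValueError("kappa needs at least two paired labels")
    space = list(label_space)
    for v in itertools.chain(a, b):
        if v not in space:
            raise ValueError(f"label {v!r} outside the shared label space {space}")
    if a == b:
        # perfect agreement: no sampling variance under the null of interest
        return KappaResult(kappa=1.0, p_value=None,
                           interpretation=KappaInterpretation.very_strong)
    table = pd.crosstab(
        pd.Categorical(a, categories=space), pd.Categorical(b, categories=space), dropna=False
    ).to_numpy()
    res = _sm_kappa(table, return_results=True)
    kappa = float(res.kappa)
    p = float(res.pvalue_two_sided)
    if np.isnan(kappa):  # degenerate marginals
        kappa, p = (1.0, None) if a == b else (0.0, None)
    return KappaResult(kappa=max(-1.0, min(1.0, kappa)),
                       p_value=None if p is None or np.isnan(p) else p,
                       interpretation=interpret_kappa(max(-1.0, min(1.0, kappa))))


def kappa_matrix(harmonized: Sequence[HarmonizedResult]) -> pd.DataFrame:
    """Pairwise kappa over all methods on matched group ids (diagonal 1)."""
    by_method: Dict[str, Dict[str, int]] = {}
    for h in harmonized:
        by_method.setdefault(h.method.value, {})[h.group_id] = h.rr_band
    methods = sorted(by_method)
    group_sets = {m: set(by_method[m]) for m in methods}
    common = set.intersection(*group_sets.values()) if methods else set()
    for m in methods:
        if group_sets[m] != common:
            raise ValueError(
                f"method {m!r} covers a different group set; kappa needs matched groups"
            )
    order = sorted(common)
    mat = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for a, b in itertools.combinations(methods, 2):
        k = cohens_kappa([by_method[a][g] for g in order],
                         [by_method[b][g] for g in order]).kappa
        mat.loc[a, b] = mat.loc[b, a] = k
    return mat


def rr_samples(harmonized: Sequence[HarmonizedResult]) -> Dict[str, List[float]]:
    """Per-method RR value lists, the input to the difference test."""
    out: Dict[str, List[float]] = {}
    for h in harmonized:
        out.setdefault(h.method.value, []).append(h.rr)
    return out
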