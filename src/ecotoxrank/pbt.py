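"""PBT hazard scoring and concentration-weighted PBTr site ranking.

Per-substance persistence (P), bioaccumulation (B) and toxicity (T)
scores in [0, 1] — obtained upstream from QSAR software and taken here
as given inputs — are aggregated geometrically,

    PBT = P^0.4 · B^0.4 · T^0.2,

so persistence and bioaccumulation weigh equally and toxicity half as
much, and any zero score annihilates the product. Per site, each
detected compound gets a rank R_i = PBT × concentration (ng/L), and the
site statistic PBTr is the weighted mean of the R_i; with the default
unit weights this is the arithmetic mean. Sites are then binned into
none / low / medium / high cumulative-rank classes.
"""

from __future__ import annotations

import enum
import logging
import math
from typing import Mapping, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .data_model import MeasurementRecord
from .occurrence import summarize_occurrence

logger = logging.getLogger(__name__)

__all__ = [
    "PBT_EXPONENTS",
    "PbtScores",
    "PbtrResult",
    "RankClass",
    "MecStatistic",
    "pbt_score",
    "compound_rank",
    "pbtr",
    "classify_pbtr",
    "site_pbtr",
]

#: geometric-aggregation exponents for (P, B, T)
PBT_EXPONENTS = (0.4, 0.4, 0.2)


class RankClass(str, enum.Enum):
    none = "none"
    low = "low"
    medium = "medium"
    high = "high"


class MecStatistic(str, enum.Enum):
    """Which per-(site, substance) concentration statistic feeds R_i."""

    median = "median"
    max = "max"


class PbtScores(BaseModel):
    substance: str
    p_score: float = Field(ge=0, le=1)
    b_score: float = Field(ge=0, le=1)
    t_score: float = Field(ge=0, le=1)
    pbt: float = Field(ge=0, le=1)
    reliability: Optional[str] = None


class PbtrResult(BaseModel):
    site: str
    compound_ranks: dict[str, float]   # CAS -> R_i, ng/L-scaled
    weights: dict[str, float]
    pbtr: float
    n: int = Field(ge=1)
    rank_class: Optional[RankClass] = None


def pbt_score(p: float, b: float, t: float) -> float:
    """Aggregate P, B, T scores: p^0.4 · b^0.4 · t^0.2, in [0, 1]."""
    for name, v in (("p", p), ("b", b), ("t", t)):
        if v is None:
            raise ValueError(f"missing {name} score")
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} score {v} outside [0, 1]")
    ep, eb, et = PBT_EXPONENTS
    return p**ep * b**eb * t**et


def compound_rank(pbt: float, concentration: float) -> float:
    """R_i = PBT score × measured concentration (ng/L)."""
    if concentration < 0:
        raise ValueError(f"negative concentration: {concentration}")
    return pbt * concentration


def pbtr(ranks: Sequence[float], weights: Sequence[float] | None = None) -> float:
    """Weighted mean of compound ranks; unit weights give the plain mean."""
    if len(ranks) == 0:
        raise ValueError("PBTr undefined for an empty rank collection")
    if weights is None:
        weights = [1.0] * len(ranks)
    if len(weights) != len(ranks):
        raise ValueError("ranks and weights differ in length")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be strictly positive")
    num = sum(r * w for r, w in zip(ranks, weights))
    return num / sum(weights)


def classify_pbtr(
    site_values: Mapping[str, float],
    cutoffs: tuple[float, float] | None = None,
) -> dict[str, RankClass]:
    """Bin per-site PBTr values into none / low / medium / high.

    A PBTr of exactly zero means nothing ranked at the site -> none.
    Explicit ``cutoffs`` (c1 < c2) bound low (< c1), medium ([c1, c2))
    and high (>= c2); by default the cutoffs are terciles of the nonzero
    site values. With a single nonzero site the terciles collapse onto
    the value itself and that site classifies as high.
    """
    nonzero = [v for v in site_values.values() if v > 0]
    if cutoffs is not None:
        c1, c2 = cutoffs
        if not c1 < c2:
            raise ValueError(f"cutoffs must increase strictly: {cutoffs}")
    elif nonzero:
        c1, c2 = np.quantile(nonzero, [1 / 3, 2 / 3])
    out: dict[str, RankClass] = {}
    for site, v in site_values.items():
        if v < 0 or math.isnan(v):
            raise ValueError(f"invalid PBTr for site {site}: {v}")
        if v == 0:
            out[site] = RankClass.none
        elif v < c1:
            out[site] = RankClass.low
        elif v < c2:
            out[site] = RankClass.medium
        else:
            out[site] = RankClass.high
    return out


def site_pbtr(
    measurements: Sequence[MeasurementRecord],
    scores: Mapping[str, PbtScores],
    statistic: MecStatistic = MecStatistic.median,
    weights: Mapping[str, float] | None = None,
    cutoffs: tuple[float, float] | None = None,
) -> list[PbtrResult]:
    """Compute R_i and PBTr per site from measurements and PBT scores.

    The concentration entering R_i is a per-(site, substance) statistic
    over detects (median by default, maximum for worst-case screening).
    Substances never detected at a site are excluded from that site's
    sum, and substances lacking a PBT score are excluded everywhere with
    a logged warning — never imputed.
    """
    summaries = summarize_occurrence(measurements, by_site=True)
    per_site: dict[str, dict[str, float]] = {}
    skipped: set[str] = set()
    for s in summaries:
        if s.n_detects == 0:
            continue
        if s.substance not in scores:
            skipped.add(s.substance)
            continue
        conc = s.conc_median if statistic is MecStatistic.median else s.conc_max
        r_i = compound_rank(scores[s.substance].pbt, conc)
        per_site.setdefault(s.site, {})[s.substance] = r_i
    for cas in sorted(skipped):
        logger.warning("substance %s lacks P/B/T scores; excluded from PBT ranking", cas)

    results = []
    for site in sorted(per_site):
        ranks = per_site[site]
        w = {cas: (weights or {}).get(cas, 1.0) for cas in ranks}
        value = pbtr(list(ranks.values()), list(w.values()))
        results.append(
            PbtrResult(site=site, compound_ranks=ranks, weights=w,
                       pbtr=value, n=len(ranks))
        )
    classes = classify_pbtr({r.site: r.pbtr for r in results}, cutoffs=cutoffs)
    for r in results:
        r.rank_class = classes[r.site]
    return results
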