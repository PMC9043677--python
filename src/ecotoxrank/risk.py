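"""Risk-quotient screening: RQ = MEC / PNEC and site-level aggregation.

Each detected concentration (MEC, ng/L) is divided by the lowest
available predicted no-effect concentration (PNEC) for that substance.
RQ values classify into four bands — negligible (< 0.01), low
(0.01–0.1), moderate (0.1–1) and high (>= 1); boundaries are
lower-inclusive so every nonnegative RQ has a class. The site-specific
quotient RQ_site is the sum of RQs over all compounds detected at the
location, a concentration-addition screen for cumulative risk.

A small built-in PNEC reference ships with the package (ibuprofen,
lowest literature PNEC 1.65 µg/L); user tables override or extend it,
and multiple PNECs for one substance collapse to the minimum.
"""

from __future__ import annotations

import enum
import logging
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, Field

from .data_model import MeasurementRecord, PnecRecord, convert_units

logger = logging.getLogger(__name__)

__all__ = [
    "RiskClass",
    "RiskResult",
    "SiteRisk",
    "RqThresholds",
    "BUILTIN_PNEC",
    "builtin_pnec_table",
    "merge_pnec_tables",
    "compute_rq",
    "classify_rq",
    "rq_site",
    "compute_risk",
    "aggregate_site_risk",
]


class RiskClass(str, enum.Enum):
    negligible = "negligible"
    low = "low"
    moderate = "moderate"
    high = "high"


_CLASS_ORDER = {c: i for i, c in enumerate(RiskClass)}


class RqThresholds(BaseModel):
    """Risk-class boundaries; lower bound of each class is inclusive."""

    low: float = 0.01
    moderate: float = 0.1
    high: float = 1.0

    def ordered(self) -> "RqThresholds":
        if not 0 < self.low < self.moderate < self.high:
            raise ValueError(
                f"risk thresholds must increase strictly: "
                f"{self.low}, {self.moderate}, {self.high}"
            )
        return self


class RiskResult(BaseModel):
    site: str
    campaign: str
    substance: str
    mec: float = Field(ge=0)       # ng/L
    pnec: float = Field(gt=0)      # ng/L
    rq: float = Field(ge=0)
    risk_class: RiskClass


class SiteRisk(BaseModel):
    site: str
    campaign: str = "all"
    rq_site: float = Field(ge=0)
    n_compounds: int = Field(ge=0)
    dominant_substance: Optional[str] = None


# lowest literature PNEC for ibuprofen, 1.65 µg/L = 1650 ng/L
BUILTIN_PNEC: dict[str, PnecRecord] = {
    "15687-27-1": PnecRecord(
        cas="15687-27-1",
        pnec=convert_units(1.65, "µg/L", "ng/L"),
        source="literature (lowest published PNEC)",
        basis="ibuprofen, lowest across trophic levels",
    ),
}


def builtin_pnec_table() -> dict[str, PnecRecord]:
    """A fresh copy of the built-in PNEC reference table (ng/L)."""
    return {cas: rec.model_copy() for cas, rec in BUILTIN_PNEC.items()}


def merge_pnec_tables(
    records: Iterable[PnecRecord], base: Mapping[str, PnecRecord] | None = None
) -> dict[str, PnecRecord]:
    """Merge PNEC records over a base table, keeping the lowest per substance."""
    table = {cas: rec.model_copy() for cas, rec in (base or {}).items()}
    for rec in records:
        cur = table.get(rec.cas)
        if cur is None or rec.pnec < cur.pnec:
            table[rec.cas] = rec
    return table


def compute_rq(mec: float, pnec: float) -> float:
    """RQ = MEC / PNEC, both in ng/L; dimensionless."""
    if pnec <= 0:
        raise ValueError(f"PNEC must be positive, got {pnec}")
    if mec < 0:
        raise ValueError(f"MEC must be nonnegative, got {mec}")
    return mec / pnec


def classify_rq(rq: float, thresholds: RqThresholds | None = None) -> RiskClass:
    """Bin an RQ into negligible / low / moderate / high risk."""
    th = (thresholds or RqThresholds()).ordered()
    if rq < 0:
        raise ValueError(f"RQ must be nonnegative, got {rq}")
    if rq < th.low:
        return RiskClass.negligible
    if rq < th.moderate:
        return RiskClass.low
    if rq < th.high:
        return RiskClass.moderate
    return RiskClass.high


def rq_site(results: Sequence[RiskResult], campaign: str = "all") -> SiteRisk:
    """Sum RQs over the compounds of one site (and optionally campaign).

    The dominant substance is the argmax RQ, ties broken by CAS order.
    An empty collection yields RQ_site = 0 with no dominant substance.
    """
    if not results:
        return SiteRisk(site="", campaign=campaign, rq_site=0.0, n_compounds=0)
    sites = {r.site for r in results}
    if len(sites) != 1:
        raise ValueError(f"results span multiple sites: {sorted(sites)}")
    total = sum(r.rq for r in results)
    dominant = min(sorted(results, key=lambda r: r.substance),
                   key=lambda r: -r.rq)
    return SiteRisk(
        site=results[0].site,
        campaign=campaign,
        rq_site=total,
        n_compounds=len({r.substance for r in results}),
        dominant_substance=dominant.substance,
    )


def compute_risk(
    measurements: Sequence[MeasurementRecord],
    pnec_table: Mapping[str, PnecRecord] | None = None,
    thresholds: RqThresholds | None = None,
    include_nondetects_at_lod: bool = False,
) -> list[RiskResult]:
    """Per-(site, campaign, substance) risk quotients for detected compounds.

    Detected substances lacking a PNEC are excluded with a logged
    warning. The optional censored-sensitivity mode scores non-detects
    at their LOD (an upper bound); it is off by default because the
    screen is defined over detected compounds.
    """
    table = pnec_table if pnec_table is not None else builtin_pnec_table()
    th = (thresholds or RqThresholds()).ordered()
    out: list[RiskResult] = []
    missing: set[str] = set()
    for m in measurements:
        if m.detected:
            mec = m.concentration
        elif include_nondetects_at_lod:
            mec = m.lod
        else:
            continue
        rec = table.get(m.substance)
        if rec is None:
            missing.add(m.substance)
            continue
        rq = compute_rq(mec, rec.pnec)
        out.append(
            RiskResult(site=m.site, campaign=m.campaign, substance=m.substance,
                       mec=mec, pnec=rec.pnec, rq=rq,
                       risk_class=classify_rq(rq, th))
        )
    for cas in sorted(missing):
        logger.warning("no PNEC for detected substance %s; excluded from RQ", cas)
    return out


def aggregate_site_risk(
    results: Sequence[RiskResult], per_campaign: bool = True
) -> list[SiteRisk]:
    """RQ_site per (site, campaign), or pooled over campaigns."""
    groups: dict[tuple[str, str], list[RiskResult]] = {}
    for r in results:
        key = (r.site, r.campaign if per_campaign else "all")
        groups.setdefault(key, []).append(r)
    return [
        rq_site(group, campaign=key[1])
        for key, group in sorted(groups.items())
    ]
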