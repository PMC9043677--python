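"""REACH PMT/vPvM weight-of-evidence screening.

Persistence, mobility and toxicity are concluded per substance from a
hazard-evidence bundle, then combined into one of six screening
categories. Every conclusion carries a rationale trail naming the
evidence or fallback rule that fired, so the assessment is auditable.

Criteria (screening thresholds, configurable via :class:`PmtThresholds`):

* persistence — degradation half-life in water or sediment: P at
  >= 40 days, vP at > 180 days (worst case across compartments);
  screening/QSAR-only evidence of non-biodegradability yields a
  *potential P/vP* conclusion, and two or more independent such lines
  with no measured half-life yield *potential P/vP++*;
* mobility — log K_OC restricted to the pH 4–9 window, experimental
  records preferred over predicted, minimum (most mobile) value used:
  M at <= 4.0, vM at <= 3.0;
* toxicity — long-term NOEC or EC10 < 0.01 mg/L for freshwater
  organisms, or a CMR classification, or specific target-organ toxicity
  after repeated exposure; otherwise Cramer class III marks a potential
  toxicant (pT) and class I/II marks not-T.
"""

from __future__ import annotations

import enum
import itertools
import logging
from typing import Iterable, Optional

from pydantic import BaseModel, Field

from .data_model import EvidenceKind, HazardEvidenceRow

logger = logging.getLogger(__name__)

__all__ = [
    "Compartment",
    "BiodegCall",
    "CramerClass",
    "CmrFlag",
    "Persistence",
    "Mobility",
    "Toxicity",
    "Category",
    "HalfLife",
    "BiodegScreen",
    "KocRecord",
    "HazardEvidence",
    "PmtThresholds",
    "PmtConclusion",
    "assess_persistence",
    "assess_mobility",
    "assess_toxicity",
    "assign_category",
    "assess_substance",
    "bundle_evidence",
]


class Compartment(str, enum.Enum):
    water = "water"
    sediment = "sediment"


class BiodegCall(str, enum.Enum):
    readily = "readily"
    inherently = "inherently"
    not_biodegradable = "not_biodegradable"


class CramerClass(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"


class CmrFlag(str, enum.Enum):
    carcinogenic = "carcinogenic"
    germ_cell_mutagenic = "germ_cell_mutagenic"
    reproductive_toxicant = "reproductive_toxicant"


class Persistence(str, enum.Enum):
    not_P = "not_P"
    potential_P_vP = "potential_P_vP"
    potential_P_vP_plus_plus = "potential_P_vP_plus_plus"
    P = "P"
    vP = "vP"


class Mobility(str, enum.Enum):
    not_M = "not_M"
    M = "M"
    vM = "vM"


class Toxicity(str, enum.Enum):
    not_T = "not_T"
    pT = "pT"
    T = "T"


class Category(str, enum.Enum):
    vPvM_and_PMT = "vPvM_and_PMT"
    vPvM = "vPvM"
    PMT = "PMT"
    PM = "PM"
    potential_PMT_vPvM = "potential_PMT_vPvM"
    not_PMT_vPvM = "not_PMT_vPvM"


class HalfLife(BaseModel):
    value: float = Field(gt=0)  # days
    compartment: Compartment
    provenance: str = "measured"  # measured | qsar


class BiodegScreen(BaseModel):
    call: BiodegCall
    provenance: str = "test"  # test | qsar


class KocRecord(BaseModel):
    log_koc: float
    ph: Optional[float] = None
    provenance: str = "experimental"  # experimental | predicted


class HazardEvidence(BaseModel):
    """Per-substance evidence bundle feeding the rule engine."""

    substance: str
    half_lives: list[HalfLife] = Field(default_factory=list)
    biodeg_screens: list[BiodegScreen] = Field(default_factory=list)
    koc_records: list[KocRecord] = Field(default_factory=list)
    noec_or_ec10: Optional[float] = Field(default=None, gt=0)  # mg/L
    cmr_flags: set[CmrFlag] = Field(default_factory=set)
    stot_re: bool = False
    cramer_class: Optional[CramerClass] = None
    detected_in_raw_water: bool = False


class PmtThresholds(BaseModel):
    """Screening thresholds; defaults follow the REACH guidance values."""

    p_half_life_days: float = 40.0     # P at >= this
    vp_half_life_days: float = 180.0   # vP at > this
    m_log_koc: float = 4.0             # M at <=
    vm_log_koc: float = 3.0            # vM at <=
    t_noec_mg_per_L: float = 0.01      # T at <
    koc_ph_window: tuple[float, float] = (4.0, 9.0)
    plus_plus_min_lines: int = 2       # screening lines for potential P/vP++
    pt_routes_to_potential: bool = True


class PmtConclusion(BaseModel):
    substance: str
    persistence: Persistence
    mobility: Mobility
    toxicity: Toxicity
    category: Category
    rationale: list[str]
    caveats: list[str] = Field(default_factory=list)


# ---------------------------------------------------------------------------
# Criterion assessments


def assess_persistence(
    evidence: HazardEvidence, thresholds: PmtThresholds | None = None
) -> tuple[Persistence, list[str]]:
    """Conclude the persistence criterion from half-lives and screens.

    Measured half-lives are decisive (maximum across water and sediment,
    worst case). Without a measured value, screening or QSAR lines that
    indicate non-biodegradability give a *potential P/vP* conclusion —
    or *potential P/vP++* when at least ``plus_plus_min_lines``
    independent lines agree. Screens indicating biodegradability and
    nothing else conclude not-P. No evidence at all falls back to
    *potential P/vP* with a logged caveat.
    """
    th = thresholds or PmtThresholds()
    trail: list[str] = []

    measured = [h for h in evidence.half_lives if h.provenance == "measured"]
    if measured:
        worst = max(measured, key=lambda h: h.value)
        trail.append(
            f"max measured half-life {worst.value:g} d in {worst.compartment.value}"
        )
        if worst.value > th.vp_half_life_days:
            trail.append(f"> {th.vp_half_life_days:g} d -> vP")
            return Persistence.vP, trail
        if worst.value >= th.p_half_life_days:
            trail.append(f">= {th.p_half_life_days:g} d -> P")
            return Persistence.P, trail
        trail.append(f"< {th.p_half_life_days:g} d -> not P")
        return Persistence.not_P, trail

    # screening / QSAR tier
    persistent_lines = [
        s for s in evidence.biodeg_screens if s.call is BiodegCall.not_biodegradable
    ]
    qsar_hl = [
        h for h in evidence.half_lives
        if h.provenance == "qsar" and h.value >= th.p_half_life_days
    ]
    degradable_lines = [
        s for s in evidence.biodeg_screens
        if s.call in (BiodegCall.readily, BiodegCall.inherently)
    ]
    n_lines = len(persistent_lines) + len(qsar_hl)
    if n_lines >= th.plus_plus_min_lines:
        trail.append(
            f"{n_lines} independent screening/QSAR lines indicate "
            "non-biodegradability, no measured half-life -> potential P/vP++"
        )
        return Persistence.potential_P_vP_plus_plus, trail
    if n_lines >= 1:
        trail.append(
            "screening/QSAR evidence indicates potential persistence "
            "-> potential P/vP"
        )
        return Persistence.potential_P_vP, trail
    if degradable_lines:
        trail.append("screening indicates biodegradability -> not P")
        return Persistence.not_P, trail

    trail.append(
        "insufficient persistence evidence; conservative fallback -> potential P/vP"
    )
    logger.warning("%s: no persistence evidence, fallback to potential P/vP",
                   evidence.substance)
    return Persistence.potential_P_vP, trail


def assess_mobility(
    evidence: HazardEvidence, thresholds: PmtThresholds | None = None
) -> tuple[Mobility, list[str]]:
    """Conclude mobility from log K_OC records in the pH 4–9 window.

    Experimental records take precedence over predicted ones; within the
    preferred tier the minimum (most mobile, most conservative) value is
    classified. Records with no stated pH are assumed environmentally
    relevant and kept.
    """
    th = thresholds or PmtThresholds()
    lo, hi = th.koc_ph_window
    trail: list[str] = []

    in_window = [
        r for r in evidence.koc_records if r.ph is None or lo <= r.ph <= hi
    ]
    if not in_window:
        trail.append(
            f"no log K_OC record within pH {lo:g}-{hi:g}; "
            "insufficient data -> not M (caveat)"
        )
        logger.warning("%s: no usable log K_OC evidence", evidence.substance)
        return Mobility.not_M, trail

    experimental = [r for r in in_window if r.provenance == "experimental"]
    tier = experimental if experimental else in_window
    tier_name = "experimental" if experimental else "predicted"
    best = min(tier, key=lambda r: r.log_koc)
    trail.append(f"min {tier_name} log K_OC = {best.log_koc:g}")

    if best.log_koc <= th.vm_log_koc:
        trail.append(f"<= {th.vm_log_koc:g} -> vM")
        return Mobility.vM, trail
    if best.log_koc <= th.m_log_koc:
        trail.append(f"<= {th.m_log_koc:g} -> M")
        return Mobility.M, trail
    trail.append(f"> {th.m_log_koc:g} -> not M")
    return Mobility.not_M, trail


def assess_toxicity(
    evidence: HazardEvidence, thresholds: PmtThresholds | None = None
) -> tuple[Toxicity, list[str]]:
    """Conclude toxicity from chronic endpoints, CMR/STOT flags and Cramer class.

    T when the long-term NOEC/EC10 is below 0.01 mg/L, or any CMR flag is
    set, or specific target-organ toxicity after repeated exposure is
    recorded. Otherwise Cramer class III marks a potential toxicant (pT)
    and class I/II not-T; with no evidence at all the fallback is pT with
    a logged caveat.
    """
    th = thresholds or PmtThresholds()
    trail: list[str] = []

    if evidence.noec_or_ec10 is not None and evidence.noec_or_ec10 < th.t_noec_mg_per_L:
        trail.append(
            f"NOEC/EC10 {evidence.noec_or_ec10:g} mg/L < {th.t_noec_mg_per_L:g} -> T"
        )
        return Toxicity.T, trail
    if evidence.cmr_flags:
        flags = ", ".join(sorted(f.value for f in evidence.cmr_flags))
        trail.append(f"CMR classification ({flags}) -> T")
        return Toxicity.T, trail
    if evidence.stot_re:
        trail.append("specific target organ toxicity (repeated exposure) -> T")
        return Toxicity.T, trail

    if evidence.cramer_class is CramerClass.III:
        trail.append("Cramer class III -> potential toxicant (pT)")
        return Toxicity.pT, trail
    if evidence.cramer_class in (CramerClass.I, CramerClass.II):
        trail.append(f"Cramer class {evidence.cramer_class.value} -> not T")
        return Toxicity.not_T, trail

    trail.append("no toxicity evidence; conservative fallback -> pT")
    logger.warning("%s: no toxicity evidence, fallback to pT", evidence.substance)
    return Toxicity.pT, trail


# ---------------------------------------------------------------------------
# Category assignment


def assign_category(
    persistence: Persistence,
    mobility: Mobility,
    toxicity: Toxicity,
    detected_in_raw_water: bool = False,
    thresholds: PmtThresholds | None = None,
) -> Category:
    """Map the three criterion conclusions to one of six categories.

    Evaluated in precedence order: vPvM&PMT, vPvM (including the
    potential P/vP++ plus raw-water detection route), PMT, PM, then the
    screening-grade *potential PMT/vPvM* bucket, with not-P or not-M
    short-circuiting to *not PMT/vPvM*. A pT conclusion never satisfies
    T; by default it routes an otherwise-PMT substance to
    *potential PMT/vPvM* because its toxicity is unresolved, not absent.
    The function is total over all criterion combinations.
    """
    th = thresholds or PmtThresholds()
    is_vP = persistence is Persistence.vP
    is_P = persistence in (Persistence.P, Persistence.vP)
    is_vM = mobility is Mobility.vM
    is_M = mobility in (Mobility.M, Mobility.vM)
    is_T = toxicity is Toxicity.T

    if is_vP and is_vM and is_T:
        return Category.vPvM_and_PMT
    if (is_vP and is_vM) or (
        persistence is Persistence.potential_P_vP_plus_plus and detected_in_raw_water
    ):
        return Category.vPvM
    if is_P and is_M:
        if is_T:
            return Category.PMT
        if toxicity is Toxicity.pT and th.pt_routes_to_potential:
            return Category.potential_PMT_vPvM
        return Category.PM
    if persistence is Persistence.not_P or mobility is Mobility.not_M:
        return Category.not_PMT_vPvM
    # remaining: screening-grade persistence (potential P/vP or ++) with M/vM
    return Category.potential_PMT_vPvM


def all_criterion_combinations() -> Iterable[
    tuple[Persistence, Mobility, Toxicity, bool]
]:
    """Every (persistence, mobility, toxicity, raw-water) combination."""
    return itertools.product(Persistence, Mobility, Toxicity, (False, True))


# ---------------------------------------------------------------------------
# Whole-substance assessment and evidence bundling


def assess_substance(
    evidence: HazardEvidence, thresholds: PmtThresholds | None = None
) -> PmtConclusion:
    """Run all three criteria and assign the category, with audit trail."""
    th = thresholds or PmtThresholds()
    p, p_trail = assess_persistence(evidence, th)
    m, m_trail = assess_mobility(evidence, th)
    t, t_trail = assess_toxicity(evidence, th)
    category = assign_category(p, m, t, evidence.detected_in_raw_water, th)
    rationale = (
        [f"[P] {s}" for s in p_trail]
        + [f"[M] {s}" for s in m_trail]
        + [f"[T] {s}" for s in t_trail]
    )
    if persistence_route_used(p, category) and evidence.detected_in_raw_water:
        rationale.append("[cat] potential P/vP++ detected in raw water -> vPvM")
    caveats = [s for s in rationale if "insufficient" in s or "fallback" in s]
    return PmtConclusion(
        substance=evidence.substance,
        persistence=p,
        mobility=m,
        toxicity=t,
        category=category,
        rationale=rationale,
        caveats=caveats,
    )


def persistence_route_used(p: Persistence, category: Category) -> bool:
    return p is Persistence.potential_P_vP_plus_plus and category is Category.vPvM


def bundle_evidence(
    rows: Iterable[HazardEvidenceRow], raw_water_cas: set[str] | None = None
) -> dict[str, HazardEvidence]:
    """Assemble long-format hazard rows into per-substance evidence bundles.

    ``raw_water_cas`` marks substances detected in raw (spring or
    borehole) water, which feeds the potential P/vP++ -> vPvM route.
    P/B/T score rows are ignored here; they belong to the PBT ranking.
    """
    raw_water_cas = raw_water_cas or set()
    bundles: dict[str, HazardEvidence] = {}
    for row in rows:
        ev = bundles.setdefault(
            row.cas,
            HazardEvidence(
                substance=row.cas,
                detected_in_raw_water=row.cas in raw_water_cas,
            ),
        )
        k = row.evidence
        if k is EvidenceKind.half_life:
            ev.half_lives.append(
                HalfLife(
                    value=row.value,
                    compartment=Compartment(row.qualifier or "water"),
                    provenance=row.provenance or "measured",
                )
            )
        elif k is EvidenceKind.biodeg_screen:
            ev.biodeg_screens.append(
                BiodegScreen(call=BiodegCall(row.qualifier),
                             provenance=row.provenance or "test")
            )
        elif k is EvidenceKind.log_koc:
            ev.koc_records.append(
                KocRecord(
                    log_koc=row.value,
                    ph=float(row.qualifier) if row.qualifier else None,
                    provenance=row.provenance or "experimental",
                )
            )
        elif k is EvidenceKind.noec:
            # lowest chronic endpoint wins when several are ingested
            if ev.noec_or_ec10 is None or row.value < ev.noec_or_ec10:
                ev.noec_or_ec10 = row.value
        elif k is EvidenceKind.cmr:
            ev.cmr_flags.add(CmrFlag(row.qualifier))
        elif k is EvidenceKind.stot_re:
            ev.stot_re = bool(row.value)
        elif k is EvidenceKind.cramer:
            ev.cramer_class = CramerClass(row.qualifier)
    return bundles
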