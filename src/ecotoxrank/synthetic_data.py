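"""Seeded generator for synthetic monitoring campaigns.

Emulates the tabular structure of a small karst-catchment monitoring
study: a catalog of 21 emerging contaminants split 11/4/2/3/1 across
pharmaceutical, lifestyle, personal-care, agricultural and industrial
use groups; four sampling sites (two springs, a river, a deep
borehole); per-substance physicochemical and hazard-evidence tables;
and a site × campaign × substance concentration matrix with
left-censored non-detects.

Detected concentrations are log-normal — the standard occurrence model
for trace contaminants, whose reported ranges span orders of magnitude
— and detection is an independent Bernoulli event per (site, campaign,
substance). Detected draws falling below the analyte's LOD are floored
at the LOD so every generated record satisfies the censoring invariant.
One integer seed drives all tables through a splittable stream, so the
whole fixture is reproducible from a single number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .data_model import (
    Lab,
    MeasurementRecord,
    Medium,
    PhysChemProperty,
    PnecRecord,
    PropertyKind,
    Provenance,
    SiteRecord,
    SubstanceRecord,
    UseGroup,
    cas_check_digit,
    parse_dms,
    write_table,
)
from .data_model import HazardEvidenceRow

__all__ = [
    "GeneratorConfig",
    "generate_sites",
    "generate_catalog",
    "generate_hazard",
    "generate_measurements",
    "generate_pnec",
    "simulate_tables",
    "DEFAULT_GROUP_COUNTS",
]

DEFAULT_GROUP_COUNTS: dict[UseGroup, int] = {
    UseGroup.pharmaceutical: 11,
    UseGroup.lifestyle: 4,
    UseGroup.personal_care: 2,
    UseGroup.agricultural: 3,
    UseGroup.industrial: 1,
}

# default site table: a typical four-point karst-catchment design
# (two spring captures, the sinking river feeding them, one deep borehole)
_DEFAULT_SITES = [
    ("Jadro", Medium.spring, "43°32′34.6″N", "16°31′20.6″E"),
    ("Zrnovnica", Medium.spring, "43°31′24.5″N", "16°34′28.4″E"),
    ("Cetina", Medium.river, "43°37′02.4″N", "16°43′44.6″E"),
    ("Gizdavac", Medium.borehole, "43°38′43.7″N", "16°29′07.6″E"),
]


class GeneratorConfig(BaseModel):
    """Study-design knobs for the synthetic fixture.

    Defaults mirror the emulated study design where stated (substance
    counts, use-group partition, four sites); occurrence parameters are
    set to field-realistic values: a detection probability of 0.6, a
    detected-concentration median of ~30 ng/L (``conc_log_mean`` on the
    natural-log scale) with a ln-scale SD of 1, and LODs of 0.5–2 ng/L
    as typical for LC-MS/MS multiresidue methods. The campaign count
    (12, a monthly year) is an arbitrary testing default, not a
    study-derived value.
    """

    n_substances: int = Field(default=21, ge=1)
    group_counts: dict[UseGroup, int] = Field(
        default_factory=lambda: dict(DEFAULT_GROUP_COUNTS)
    )
    n_sites: int = Field(default=4, ge=1)
    n_campaigns: int = Field(default=12, ge=1)
    detection_prob: float = Field(default=0.6, ge=0, le=1)
    conc_log_mean: float = 3.4      # ln ng/L; median exp(3.4) ~ 30 ng/L
    conc_log_sd: float = Field(default=1.0, gt=0)
    lod_range: tuple[float, float] = (0.5, 2.0)  # ng/L
    seed: int = 0
    # hazard-evidence knobs
    half_life_median_days: float = Field(default=60.0, gt=0)
    half_life_log_sd: float = Field(default=1.0, gt=0)
    half_life_fixed_days: Optional[float] = Field(default=None, gt=0)
    cmr_prob: float = Field(default=0.08, ge=0, le=1)
    stot_prob: float = Field(default=0.05, ge=0, le=1)
    noec_present_prob: float = Field(default=0.7, ge=0, le=1)
    force_persistence_tier: Optional[
        Literal["measured", "screening_only", "none"]
    ] = None

    @model_validator(mode="after")
    def _consistent(self) -> "GeneratorConfig":
        total = sum(self.group_counts.values())
        if total != self.n_substances:
            raise ValueError(
                f"group_counts sums to {total}, expected n_substances="
                f"{self.n_substances}"
            )
        lo, hi = self.lod_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid lod_range: {self.lod_range}")
        return self


def _streams(config: GeneratorConfig) -> dict[str, np.random.Generator]:
    """Independent child streams per table, all derived from one seed."""
    root = np.random.SeedSequence(config.seed)
    names = ["catalog", "properties", "hazard", "measurements", "sites", "pnec"]
    return {n: np.random.default_rng(s) for n, s in zip(names, root.spawn(len(names)))}


def _synthetic_cas(rng: np.random.Generator, taken: set[str]) -> str:
    """A well-formed CAS-style identifier with a valid check digit (synthetic)."""
    while True:
        body1 = str(rng.integers(10, 10_000_000))
        body2 = f"{rng.integers(0, 100):02d}"
        cas = f"{body1}-{body2}-{cas_check_digit(body1 + body2)}"
        if cas not in taken:
            taken.add(cas)
            return cas


def generate_sites(config: GeneratorConfig) -> list[SiteRecord]:
    """The four-site catchment design; extra sites get jittered coordinates."""
    rng = _streams(config)["sites"]
    records = []
    for i in range(config.n_sites):
        if i < len(_DEFAULT_SITES):
            name, medium, lat, lon = _DEFAULT_SITES[i]
            records.append(
                SiteRecord(site_id=name, medium=medium,
                           latitude=parse_dms(lat), longitude=parse_dms(lon))
            )
        else:
            records.append(
                SiteRecord(
                    site_id=f"Site{i + 1:02d}",
                    medium=Medium(rng.choice([m.value for m in Medium])),
                    latitude=43.5 + rng.uniform(-0.2, 0.2),
                    longitude=16.5 + rng.uniform(-0.2, 0.2),
                )
            )
    return records


def generate_catalog(
    config: GeneratorConfig,
) -> tuple[list[SubstanceRecord], list[PhysChemProperty]]:
    """Synthetic substance catalog plus physicochemical property table.

    Properties are drawn from broad screening-relevant ranges:
    log K_OW ~ U(-1, 7), log K_OC ~ U(0, 6), pK_a ~ U(0, 12) and water
    solubility log-uniform over 1e-3 to 1e5 mg/L, each flagged
    experimental or predicted at random. Deterministic given the seed.
    """
    streams = _streams(config)
    rng_cat, rng_prop = streams["catalog"], streams["properties"]
    taken: set[str] = set()
    substances: list[SubstanceRecord] = []
    idx = 1
    for group in UseGroup:
        for _ in range(config.group_counts.get(group, 0)):
            substances.append(
                SubstanceRecord(
                    name=f"EC-{idx:03d}",
                    cas=_synthetic_cas(rng_cat, taken),
                    use_group=group,
                    molecular_weight=float(np.round(rng_cat.uniform(100, 600), 1)),
                )
            )
            idx += 1

    properties: list[PhysChemProperty] = []
    for sub in substances:
        draws = {
            PropertyKind.log_kow: rng_prop.uniform(-1, 7),
            PropertyKind.log_koc: rng_prop.uniform(0, 6),
            PropertyKind.pka: rng_prop.uniform(0, 12),
            PropertyKind.solubility_mg_per_L: 10.0 ** rng_prop.uniform(-3, 5),
        }
        for kind, value in draws.items():
            properties.append(
                PhysChemProperty(
                    cas=sub.cas,
                    kind=kind,
                    value=float(np.round(value, 4)),
                    provenance=Provenance.experimental
                    if rng_prop.random() < 0.5
                    else Provenance.predicted,
                    source="synthetic",
                )
            )
    return substances, properties


def generate_hazard(
    config: GeneratorConfig, catalog: list[SubstanceRecord]
) -> list[HazardEvidenceRow]:
    """Long-format hazard-evidence rows for every catalog substance.

    Each substance is assigned a persistence-evidence tier — measured
    half-lives, screening/QSAR calls only, or no persistence evidence —
    with the first three substances pinned to the three tiers so all
    occur in any fixture. Half-lives are log-normal around the
    configured median; NOEC values are log-uniform over 1e-4–10 mg/L;
    CMR and STOT-RE flags are rare Bernoulli events; Cramer class is
    uniform over I–III; log K_OC evidence lands on 1–3 pH points in
    [2, 11]; and P/B/T scores are uniform on [0, 1].
    """
    rng = _streams(config)["hazard"]
    rows: list[HazardEvidenceRow] = []
    tiers = ["measured", "screening_only", "none"]
    for i, sub in enumerate(catalog):
        if config.force_persistence_tier is not None:
            tier = config.force_persistence_tier
        elif i < 3:
            tier = tiers[i]
        else:
            tier = rng.choice(tiers, p=[0.6, 0.3, 0.1])

        def half_life() -> float:
            if config.half_life_fixed_days is not None:
                return config.half_life_fixed_days
            return float(
                np.round(
                    rng.lognormal(np.log(config.half_life_median_days),
                                  config.half_life_log_sd),
                    2,
                )
            )

        if tier == "measured":
            for compartment in ("water", "sediment")[: int(rng.integers(1, 3))]:
                rows.append(
                    HazardEvidenceRow(
                        cas=sub.cas, evidence="half_life", value=half_life(),
                        qualifier=compartment, provenance="measured",
                    )
                )
        elif tier == "screening_only":
            n_lines = int(rng.integers(1, 4))
            for _ in range(n_lines):
                call = rng.choice(
                    ["not_biodegradable", "readily", "inherently"], p=[0.6, 0.25, 0.15]
                )
                rows.append(
                    HazardEvidenceRow(
                        cas=sub.cas, evidence="biodeg_screen",
                        qualifier=str(call), provenance="qsar",
                    )
                )

        # mobility evidence: 1-3 log K_OC points at pH values in [2, 11]
        for _ in range(int(rng.integers(1, 4))):
            rows.append(
                HazardEvidenceRow(
                    cas=sub.cas, evidence="log_koc",
                    value=float(np.round(rng.uniform(0, 6), 3)),
                    qualifier=f"{rng.uniform(2, 11):.1f}",
                    provenance="experimental" if rng.random() < 0.5 else "predicted",
                )
            )

        if rng.random() < config.noec_present_prob:
            rows.append(
                HazardEvidenceRow(
                    cas=sub.cas, evidence="noec",
                    value=float(np.round(10.0 ** rng.uniform(-4, 1), 6)),
                )
            )
        for flag in ("carcinogenic", "germ_cell_mutagenic", "reproductive_toxicant"):
            if rng.random() < config.cmr_prob:
                rows.append(
                    HazardEvidenceRow(cas=sub.cas, evidence="cmr", qualifier=flag)
                )
        if rng.random() < config.stot_prob:
            rows.append(
                HazardEvidenceRow(cas=sub.cas, evidence="stot_re", value=1.0)
            )
        rows.append(
            HazardEvidenceRow(
                cas=sub.cas, evidence="cramer",
                qualifier=str(rng.choice(["I", "II", "III"])),
            )
        )
        for score in ("p_score", "b_score", "t_score"):
            rows.append(
                HazardEvidenceRow(
                    cas=sub.cas, evidence=score,
                    value=float(np.round(rng.uniform(0, 1), 4)),
                    provenance="good" if rng.random() < 0.7 else "moderate",
                )
            )
    return rows


def generate_measurements(
    config: GeneratorConfig,
    catalog: list[SubstanceRecord],
    sites: list[SiteRecord],
) -> list[MeasurementRecord]:
    """Site × campaign × substance concentration records with censoring.

    Each (substance, lab) pair gets one LOD drawn from ``lod_range``;
    sites alternate between the two commissioned labs. Detection is
    Bernoulli(``detection_prob``); a detected concentration is
    exp(N(conc_log_mean, conc_log_sd)) ng/L floored at the LOD, and a
    non-detect is recorded as censored at the LOD with no value.
    """
    rng = _streams(config)["measurements"]
    lo, hi = config.lod_range
    lods = {
        (sub.cas, lab): float(np.round(rng.uniform(lo, hi), 3))
        for sub in catalog
        for lab in Lab
    }
    records: list[MeasurementRecord] = []
    for s_idx, site in enumerate(sites):
        lab = Lab.lab_A if s_idx % 2 == 0 else Lab.lab_B
        for c in range(1, config.n_campaigns + 1):
            campaign = f"C{c:03d}"
            for sub in catalog:
                lod = lods[(sub.cas, lab)]
                detected = bool(rng.random() < config.detection_prob)
                if detected:
                    conc = float(
                        np.exp(rng.normal(config.conc_log_mean, config.conc_log_sd))
                    )
                    conc = max(conc, lod)  # floor at LOD, keeps censoring invariant
                    records.append(
                        MeasurementRecord(
                            site=site.site_id, campaign=campaign,
                            substance=sub.cas, concentration=round(conc, 4),
                            lod=lod, lab=lab, detected=True,
                        )
                    )
                else:
                    records.append(
                        MeasurementRecord(
                            site=site.site_id, campaign=campaign,
                            substance=sub.cas, concentration=None,
                            lod=lod, lab=lab, detected=False,
                        )
                    )
    return records


def generate_pnec(
    config: GeneratorConfig, catalog: list[SubstanceRecord]
) -> list[PnecRecord]:
    """Per-substance lowest-PNEC table, log-uniform over 10–10^4 ng/L."""
    rng = _streams(config)["pnec"]
    return [
        PnecRecord(
            cas=sub.cas,
            pnec=float(np.round(10.0 ** rng.uniform(1, 4), 2)),
            source="synthetic",
            basis="lowest across trophic levels (synthetic)",
        )
        for sub in catalog
    ]


def simulate_tables(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write all six CSV tables; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sites = generate_sites(config)
    substances, properties = generate_catalog(config)
    hazard = generate_hazard(config, substances)
    measurements = generate_measurements(config, substances, sites)
    pnec = generate_pnec(config, substances)
    paths = {
        "sites": write_table(sites, outdir / "sites.csv"),
        "substances": write_table(substances, outdir / "substances.csv"),
        "properties": write_table(properties, outdir / "properties.csv"),
        "hazard": write_table(hazard, outdir / "hazard.csv"),
        "measurements": write_table(measurements, outdir / "measurements.csv"),
        "pnec": write_table(pnec, outdir / "pnec.csv"),
    }
    return paths
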