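"""End-to-end orchestration: read tables, run all stages, write reports.

Every printed constant of the method — RQ class boundaries, persistence
and mobility thresholds, the chronic-toxicity cutoff — lives in
:class:`PipelineConfig` defaults rather than in stage logic, so a run
can sweep them. Outputs are six CSV tables plus a Markdown summary
report collecting per-site risk ranking, screening-category counts and
every caveat emitted by any stage.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import occurrence, pbt, pmt, risk
from .data_model import (
    HazardEvidenceRow,
    Medium,
    PnecRecord,
    read_table,
)
from .data_model import EvidenceKind

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "extract_pbt_scores"]


class PipelineConfig(BaseModel):
    """Paths, thresholds and mode switches for a full run."""

    measurements: Path
    hazard: Path
    sites: Optional[Path] = None
    substances: Optional[Path] = None
    pnec: Optional[Path] = None
    outdir: Path = Path("ecotoxrank_out")

    rq_thresholds: risk.RqThresholds = Field(default_factory=risk.RqThresholds)
    pmt_thresholds: pmt.PmtThresholds = Field(default_factory=pmt.PmtThresholds)
    pbtr_cutoffs: Optional[tuple[float, float]] = None  # None -> terciles
    mec_statistic: pbt.MecStatistic = pbt.MecStatistic.median
    rq_per_campaign: bool = True
    occurrence_by_site: bool = True

    @model_validator(mode="after")
    def _ordered_thresholds(self) -> "PipelineConfig":
        self.rq_thresholds.ordered()
        th = self.pmt_thresholds
        if not 0 < th.p_half_life_days < th.vp_half_life_days:
            raise ValueError("persistence thresholds must satisfy 0 < P < vP days")
        if not 0 < th.vm_log_koc < th.m_log_koc:
            raise ValueError("mobility thresholds must satisfy 0 < vM < M")
        if th.t_noec_mg_per_L <= 0:
            raise ValueError("toxicity NOEC threshold must be positive")
        if self.pbtr_cutoffs is not None and not (
            self.pbtr_cutoffs[0] < self.pbtr_cutoffs[1]
        ):
            raise ValueError("PBTr cutoffs must increase strictly")
        return self


class PipelineResult(BaseModel):
    outputs: dict[str, Path]
    caveats: list[str]
    n_measurements: int
    n_substances_ranked: int


def extract_pbt_scores(rows: list[HazardEvidenceRow]) -> dict[str, pbt.PbtScores]:
    """Pull per-substance P/B/T scores out of the hazard table.

    Substances missing any of the three scores are excluded with a
    logged warning (never imputed).
    """
    raw: dict[str, dict[str, float]] = {}
    for row in rows:
        if row.evidence in (EvidenceKind.p_score, EvidenceKind.b_score,
                            EvidenceKind.t_score):
            raw.setdefault(row.cas, {})[row.evidence.value] = row.value
    scores: dict[str, pbt.PbtScores] = {}
    for cas, d in raw.items():
        if {"p_score", "b_score", "t_score"} <= set(d):
            scores[cas] = pbt.PbtScores(
                substance=cas,
                p_score=d["p_score"], b_score=d["b_score"], t_score=d["t_score"],
                pbt=pbt.pbt_score(d["p_score"], d["b_score"], d["t_score"]),
            )
        else:
            logger.warning("substance %s has incomplete P/B/T scores; excluded", cas)
    return scores


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, index=False)
    return path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute occurrence, PBT/PBTr, PMT/vPvM and RQ stages end to end."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    caveats: list[str] = []

    measurements = read_table(config.measurements, "measurements")
    hazard_rows = read_table(config.hazard, "hazard")
    sites = read_table(config.sites, "sites") if config.sites else []
    outputs: dict[str, Path] = {}

    # occurrence (Table 2 shape)
    summaries = occurrence.summarize_occurrence(
        measurements, by_site=config.occurrence_by_site
    )
    outputs["occurrence"] = _write_csv(
        occurrence.occurrence_frame(summaries), outdir / "occurrence.csv"
    )

    # PBT scores and PBTr per site (Table 5 shape)
    scores = extract_pbt_scores(hazard_rows)
    ranked_cas = set()
    for s in summaries:
        if s.n_detects and s.substance not in scores:
            caveats.append(f"pbt: {s.substance} detected but has no P/B/T scores")
        elif s.n_detects:
            ranked_cas.add(s.substance)
    score_df = pd.DataFrame([v.model_dump() for v in scores.values()])
    outputs["pbt_scores"] = _write_csv(
        score_df.sort_values("substance") if len(score_df) else score_df,
        outdir / "pbt_scores.csv",
    )
    pbtr_results = pbt.site_pbtr(
        measurements, scores,
        statistic=config.mec_statistic, cutoffs=config.pbtr_cutoffs,
    )
    pbtr_rows = []
    for r in pbtr_results:
        for cas, ri in sorted(r.compound_ranks.items()):
            pbtr_rows.append(
                {"site": r.site, "substance": cas, "R_i": ri,
                 "weight": r.weights[cas], "PBTr": r.pbtr, "n": r.n,
                 "rank_class": r.rank_class.value}
            )
    outputs["pbtr_by_site"] = _write_csv(
        pd.DataFrame(
            pbtr_rows,
            columns=["site", "substance", "R_i", "weight", "PBTr", "n", "rank_class"],
        ),
        outdir / "pbtr_by_site.csv",
    )

    # PMT/vPvM (Table 6 shape); raw water = springs and boreholes
    raw_media = {Medium.spring, Medium.borehole}
    raw_sites = {s.site_id for s in sites if s.medium in raw_media}
    raw_cas = {
        m.substance for m in measurements if m.detected and m.site in raw_sites
    }
    bundles = pmt.bundle_evidence(hazard_rows, raw_water_cas=raw_cas)
    conclusions = [
        pmt.assess_substance(ev, config.pmt_thresholds)
        for _, ev in sorted(bundles.items())
    ]
    for c in conclusions:
        caveats.extend(f"pmt: {c.substance}: {s}" for s in c.caveats)
    outputs["pmt_conclusions"] = _write_csv(
        pd.DataFrame(
            [
                {
                    "substance": c.substance,
                    "persistence": c.persistence.value,
                    "mobility": c.mobility.value,
                    "toxicity": c.toxicity.value,
                    "category": c.category.value,
                    "rationale": "; ".join(c.rationale),
                }
                for c in conclusions
            ]
        ),
        outdir / "pmt_conclusions.csv",
    )

    # risk quotients (Table 7 shape)
    pnec_table = risk.builtin_pnec_table()
    if config.pnec:
        user_pnec: list[PnecRecord] = read_table(config.pnec, "pnec")
        pnec_table = risk.merge_pnec_tables(user_pnec, base=pnec_table)
    detected_cas = {m.substance for m in measurements if m.detected}
    for cas in sorted(detected_cas - set(pnec_table)):
        caveats.append(f"rq: no PNEC for detected substance {cas}; excluded")
    rq_results = risk.compute_risk(
        measurements, pnec_table, thresholds=config.rq_thresholds
    )
    outputs["rq_results"] = _write_csv(
        pd.DataFrame(
            [
                {**r.model_dump(exclude={"risk_class"}),
                 "risk_class": r.risk_class.value}
                for r in rq_results
            ]
        ),
        outdir / "rq_results.csv",
    )
    site_risks = risk.aggregate_site_risk(rq_results,
                                          per_campaign=config.rq_per_campaign)
    outputs["rq_site"] = _write_csv(
        pd.DataFrame([s.model_dump() for s in site_risks]),
        outdir / "rq_site.csv",
    )

    outputs["report"] = _write_report(
        outdir / "report.md", summaries, pbtr_results, conclusions,
        site_risks, caveats,
    )
    return PipelineResult(
        outputs=outputs,
        caveats=caveats,
        n_measurements=len(measurements),
        n_substances_ranked=len(ranked_cas & set(scores)),
    )


def _write_report(path, summaries, pbtr_results, conclusions, site_risks, caveats):
    lines = ["# Ecotoxicological screening report", ""]

    lines += ["## Per-site cumulative PBT rank", ""]
    for r in sorted(pbtr_results, key=lambda r: -r.pbtr):
        lines.append(
            f"- {r.site}: PBTr = {r.pbtr:.4g} (n = {r.n}, class {r.rank_class.value})"
        )

    lines += ["", "## PMT/vPvM category counts", ""]
    counts: dict[str, int] = {}
    for c in conclusions:
        counts[c.category.value] = counts.get(c.category.value, 0) + 1
    for cat in pmt.Category:
        lines.append(f"- {cat.value}: {counts.get(cat.value, 0)}")

    lines += ["", "## Site risk ranking (RQ_site)", ""]
    pooled: dict[str, float] = {}
    for s in site_risks:
        pooled[s.site] = max(pooled.get(s.site, 0.0), s.rq_site)
    for site, v in sorted(pooled.items(), key=lambda kv: -kv[1]):
        lines.append(f"- {site}: worst-campaign RQ_site = {v:.4g}")

    n_detect_groups = sum(1 for s in summaries if s.n_detects)
    lines += ["", f"Summaries with detections: {n_detect_groups} of {len(summaries)}", ""]

    lines += ["## Caveats", ""]
    if caveats:
        lines += [f"- {c}" for c in dict.fromkeys(caveats)]
    else:
        lines.append("- none")
    lines.append("")
    path.write_text("\n".join(lines), encoding="utf-8")
    return path
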