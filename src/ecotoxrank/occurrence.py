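"""Occurrence summaries: detection frequency and concentration statistics.

Statistics (min, max, median) are computed over detected records only;
non-detects count toward the sample denominator but are never
substituted with LOD fractions. The even-count median is the arithmetic
mean of the central pair.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field

from .data_model import MeasurementRecord

__all__ = ["OccurrenceSummary", "summarize_occurrence", "occurrence_frame"]


class OccurrenceSummary(BaseModel):
    substance: str
    site: str = "all"
    n_samples: int = Field(ge=0)
    n_detects: int = Field(ge=0)
    detection_frequency: float = Field(ge=0, le=1)
    conc_min: Optional[float] = None   # ng/L
    conc_max: Optional[float] = None
    conc_median: Optional[float] = None


def measurements_frame(measurements: Sequence[MeasurementRecord]) -> pd.DataFrame:
    rows = [m.model_dump() for m in measurements]
    df = pd.DataFrame(
        rows,
        columns=["site", "campaign", "substance", "concentration",
                 "lod", "lab", "detected"],
    )
    df["lab"] = df["lab"].map(lambda v: getattr(v, "value", v))
    return df


def summarize_occurrence(
    measurements: Sequence[MeasurementRecord], by_site: bool = False
) -> list[OccurrenceSummary]:
    """One summary per substance (or per substance-site when ``by_site``).

    Empty input yields an empty list. Row order of the input never
    affects any summary.
    """
    if not measurements:
        return []
    df = measurements_frame(measurements)
    keys = ["substance", "site"] if by_site else ["substance"]
    out: list[OccurrenceSummary] = []
    for group_key, g in sorted(df.groupby(keys, sort=True)):
        if not isinstance(group_key, tuple):
            group_key = (group_key,)
        detects = g.loc[g["detected"], "concentration"]
        n, k = len(g), int(g["detected"].sum())
        summary = OccurrenceSummary(
            substance=group_key[0],
            site=group_key[1] if by_site else "all",
            n_samples=n,
            n_detects=k,
            detection_frequency=k / n,
            conc_min=float(detects.min()) if k else None,
            conc_max=float(detects.max()) if k else None,
            conc_median=float(detects.median()) if k else None,
        )
        out.append(summary)
    return out


def occurrence_frame(summaries: Sequence[OccurrenceSummary]) -> pd.DataFrame:
    """Tabular view of occurrence summaries for CSV export."""
    return pd.DataFrame([s.model_dump() for s in summaries])
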