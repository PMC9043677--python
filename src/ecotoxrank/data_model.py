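"""Domain types, validation and CSV I/O for water-monitoring tables.

The pipeline works on six tidy CSV tables: a substance catalog, a
physicochemical property table, a site table, a measurement table
(left-censored at the limit of detection), a long-format hazard-evidence
table and a PNEC reference table. All concentrations are held internally
in ng/L; PNECs may arrive in µg/L or mg/L and are converted on ingest.

Non-detects are stored as censored records — a row with ``detected=False``
carries only its LOD, never an imputed value such as LOD/2. Downstream
statistics decide explicitly how censoring is treated.
"""

from __future__ import annotations

import enum
import logging
import re
from pathlib import Path
from typing import Optional, Sequence, Type

import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "UseGroup",
    "Medium",
    "Lab",
    "Provenance",
    "PropertyKind",
    "SubstanceRecord",
    "PhysChemProperty",
    "MeasurementRecord",
    "SiteRecord",
    "HazardEvidenceRow",
    "PnecRecord",
    "SchemaError",
    "RowValidationError",
    "validate_cas",
    "convert_units",
    "parse_dms",
    "read_table",
    "write_table",
    "read_xlsx_workbook",
    "TABLE_SCHEMAS",
]


# ---------------------------------------------------------------------------
# Enumerations

class UseGroup(str, enum.Enum):
    pharmaceutical = "pharmaceutical"
    lifestyle = "lifestyle"
    personal_care = "personal_care"
    agricultural = "agricultural"
    industrial = "industrial"


class Medium(str, enum.Enum):
    spring = "spring"
    river = "river"
    borehole = "borehole"


class Lab(str, enum.Enum):
    lab_A = "lab_A"
    lab_B = "lab_B"


class Provenance(str, enum.Enum):
    experimental = "experimental"
    predicted = "predicted"


class PropertyKind(str, enum.Enum):
    log_kow = "log_kow"
    log_koc = "log_koc"
    pka = "pka"
    solubility_mg_per_L = "solubility_mg_per_L"


# ---------------------------------------------------------------------------
# CAS registry numbers

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")


def validate_cas(cas: str) -> bool:
    """Check a CAS registry number: format ``N{2,7}-NN-N`` plus check digit.

    The check digit is the weighted sum of the body digits — rightmost
    body digit × 1, next × 2, and so on — modulo 10. Malformed input
    returns False rather than raising.
    """
    if not isinstance(cas, str):
        return False
    m = _CAS_RE.match(cas.strip())
    if not m:
        return False
    body = m.group(1) + m.group(2)
    check = int(m.group(3))
    total = sum(int(d) * w for w, d in enumerate(reversed(body), start=1))
    return total % 10 == check


def cas_check_digit(body: str) -> int:
    """Check digit for a CAS body (catalog digits without the final digit)."""
    return sum(int(d) * w for w, d in enumerate(reversed(body), start=1)) % 10


# ---------------------------------------------------------------------------
# Units

_UNIT_FACTORS_NG_PER_L = {
    "ng/L": 1.0,
    "µg/L": 1e3,
    "ug/L": 1e3,  # ASCII alias
    "mg/L": 1e6,
}


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Exact power-of-ten conversion between ng/L, µg/L and mg/L."""
    try:
        f = _UNIT_FACTORS_NG_PER_L[from_unit]
        t = _UNIT_FACTORS_NG_PER_L[to_unit]
    except KeyError as exc:
        raise ValueError(f"unknown concentration unit: {exc.args[0]!r}") from None
    return value * (f / t)


# ---------------------------------------------------------------------------
# Coordinates

_DMS_RE = re.compile(
    r"""^\s*(\d{1,3})\s*[°]\s*(\d{1,2})\s*[′']\s*([\d.]+)\s*[″"]\s*([NSEW])\s*$"""
)


def parse_dms(text: str) -> float:
    """Parse a degrees-minutes-seconds string like ``43°32′34.6″N``.

    Returns signed decimal degrees (S and W negative).
    """
    m = _DMS_RE.match(text)
    if not m:
        raise ValueError(f"not a DMS coordinate: {text!r}")
    deg, minutes, seconds, hemi = m.groups()
    value = int(deg) + int(minutes) / 60.0 + float(seconds) / 3600.0
    return -value if hemi in "SW" else value


def _coerce_coordinate(value) -> float:
    if isinstance(value, str):
        try:
            return float(value)
        except ValueError:
            return parse_dms(value)
    return float(value)


# ---------------------------------------------------------------------------
# Records

class SubstanceRecord(BaseModel):
    """One catalog entry: identity plus use group."""

    name: str
    cas: str
    use_group: UseGroup
    molecular_formula: Optional[str] = None
    molecular_weight: Optional[float] = Field(default=None, gt=0)

    @field_validator("cas")
    @classmethod
    def _cas_checks(cls, v: str) -> str:
        if not validate_cas(v):
            raise ValueError(f"invalid CAS registry number: {v!r}")
        return v


class PhysChemProperty(BaseModel):
    """A single physicochemical property value with provenance."""

    cas: str
    kind: PropertyKind
    value: float
    provenance: Provenance
    ph: Optional[float] = Field(default=None, ge=0, le=14)
    source: Optional[str] = None

    @model_validator(mode="after")
    def _positive_solubility(self) -> "PhysChemProperty":
        if self.kind is PropertyKind.solubility_mg_per_L and self.value <= 0:
            raise ValueError("solubility must be > 0 mg/L")
        return self


class MeasurementRecord(BaseModel):
    """One analyte concentration at one site/campaign, censoring-aware.

    ``detected=True`` requires a concentration at or above the LOD;
    ``detected=False`` means left-censored at the LOD and carries no
    concentration.
    """

    site: str
    campaign: str
    substance: str
    concentration: Optional[float] = None  # ng/L, absent when non-detect
    lod: float = Field(gt=0)  # ng/L, per (analyte, lab)
    lab: Lab
    detected: bool

    @model_validator(mode="after")
    def _censoring_invariant(self) -> "MeasurementRecord":
        if self.detected:
            if self.concentration is None:
                raise ValueError("detected record lacks a concentration")
            if self.concentration < self.lod:
                raise ValueError(
                    f"detected concentration {self.concentration} ng/L is below "
                    f"LOD {self.lod} ng/L"
                )
        elif self.concentration is not None:
            raise ValueError("non-detect must not carry a concentration")
        return self


class SiteRecord(BaseModel):
    """A sampling location; coordinates in decimal degrees WGS84.

    DMS strings (``43°32′34.6″N``) are accepted and parsed on ingest.
    Water temperature and conductivity are optional pass-through fields.
    """

    site_id: str
    medium: Medium
    latitude: float = Field(ge=-90, le=90)
    longitude: float = Field(ge=-180, le=180)
    water_temperature: Optional[float] = None
    conductivity: Optional[float] = None

    @field_validator("latitude", "longitude", mode="before")
    @classmethod
    def _parse_coord(cls, v):
        return _coerce_coordinate(v)


class EvidenceKind(str, enum.Enum):
    half_life = "half_life"
    biodeg_screen = "biodeg_screen"
    log_koc = "log_koc"
    noec = "noec"
    cmr = "cmr"
    stot_re = "stot_re"
    cramer = "cramer"
    p_score = "p_score"
    b_score = "b_score"
    t_score = "t_score"


class HazardEvidenceRow(BaseModel):
    """One line of the long-format hazard-evidence table.

    The qualifier column is overloaded by evidence kind: compartment for
    half-lives, biodegradability call for screens, pH for log K_OC rows,
    CMR flag name for ``cmr`` rows and Cramer class for ``cramer`` rows.
    """

    cas: str
    evidence: EvidenceKind
    value: Optional[float] = None
    qualifier: Optional[str] = None
    provenance: Optional[str] = None

    @model_validator(mode="after")
    def _kind_specific(self) -> "HazardEvidenceRow":
        k = self.evidence
        if k in (EvidenceKind.half_life, EvidenceKind.noec):
            if self.value is None or self.value <= 0:
                raise ValueError(f"{k.value} requires a positive value")
        if k in (EvidenceKind.p_score, EvidenceKind.b_score, EvidenceKind.t_score):
            if self.value is None or not 0 <= self.value <= 1:
                raise ValueError(f"{k.value} must lie in [0, 1]")
        if k is EvidenceKind.log_koc and self.value is None:
            raise ValueError("log_koc requires a value")
        return self


class PnecRecord(BaseModel):
    """Lowest predicted no-effect concentration for one substance, ng/L."""

    cas: str
    pnec: float = Field(gt=0)  # ng/L canonical
    source: Optional[str] = None
    basis: Optional[str] = None


# ---------------------------------------------------------------------------
# Table I/O

class SchemaError(ValueError):
    """A mandatory column is missing or the table kind is unknown."""


class RowValidationError(ValueError):
    """One or more rows violated a record invariant; message lists row indices."""


TABLE_SCHEMAS: dict[str, Type[BaseModel]] = {
    "substances": SubstanceRecord,
    "properties": PhysChemProperty,
    "sites": SiteRecord,
    "measurements": MeasurementRecord,
    "hazard": HazardEvidenceRow,
    "pnec": PnecRecord,
}

# columns that may legitimately be empty per-row
_OPTIONAL_NA = {"concentration", "molecular_formula", "molecular_weight",
                "ph", "source", "value", "qualifier", "provenance", "basis",
                "water_temperature", "conductivity"}


def _mandatory_columns(model: Type[BaseModel]) -> list[str]:
    return [n for n, f in model.model_fields.items() if f.is_required()]


def read_table(path: str | Path, schema: str) -> list[BaseModel]:
    """Read and validate one CSV table into typed records.

    Extra columns are ignored (pass-through happens at the DataFrame level
    if needed); a missing mandatory column raises :class:`SchemaError`, and
    invariant violations raise :class:`RowValidationError` naming the rows.
    """
    if schema not in TABLE_SCHEMAS:
        raise SchemaError(f"unknown table kind: {schema!r}")
    model = TABLE_SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"campaign": str, "site": str, "qualifier": str})
    missing = [c for c in _mandatory_columns(model) if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s) {', '.join(missing)} "
            f"for schema {schema!r}"
        )
    known = [c for c in df.columns if c in model.model_fields]
    records: list[BaseModel] = []
    errors: list[str] = []
    for idx, row in df[known].iterrows():
        payload = {k: (None if pd.isna(v) else v) for k, v in row.items()}
        try:
            records.append(model(**payload))
        except Exception as exc:  # pydantic ValidationError
            errors.append(f"row {idx}: {exc}")
    if errors:
        raise RowValidationError(
            f"{path.name} ({schema}): {len(errors)} invalid row(s)\n"
            + "\n".join(errors[:20])
        )
    logger.info("read %d %s record(s) from %s", len(records), schema, path)
    return records


def write_table(records: Sequence[BaseModel], path: str | Path) -> Path:
    """Write typed records to CSV (UTF-8, comma, header row)."""
    path = Path(path)
    if not records:
        raise ValueError("refusing to write an empty table without a schema")
    cols = list(type(records[0]).model_fields)
    rows = []
    for r in records:
        d = r.model_dump()
        rows.append({c: (v.value if isinstance(v, enum.Enum) else v)
                     for c, v in d.items()})
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return path


def read_xlsx_workbook(path: str | Path, sheet_schemas: dict[str, str]) -> dict[str, list[BaseModel]]:
    """Optional convenience: read a workbook with one logical table per sheet.

    ``sheet_schemas`` maps worksheet name to a table kind from
    :data:`TABLE_SCHEMAS`. Requires openpyxl.
    """
    import tempfile

    out: dict[str, list[BaseModel]] = {}
    for sheet, schema in sheet_schemas.items():
        df = pd.read_excel(path, sheet_name=sheet)
        with tempfile.NamedTemporaryFile("w", suffix=".csv", delete=False) as fh:
            df.to_csv(fh.name, index=False)
            out[sheet] = read_table(fh.name, schema)
    return out
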