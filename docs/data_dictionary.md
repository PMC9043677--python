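# Data dictionary

All tables are UTF-8, comma-separated CSV with a header row. Extra
columns are ignored on read. An optional XLSX reader
(`read_xlsx_workbook`) accepts a workbook with one logical table per
worksheet.

## substances.csv

| column | type | required | notes |
|---|---|---|---|
| name | text | yes | display name |
| cas | text | yes | CAS registry number; check digit validated |
| use_group | enum | yes | pharmaceutical, lifestyle, personal_care, agricultural, industrial |
| molecular_formula | text | no | |
| molecular_weight | g/mol | no | > 0 |

## properties.csv

| column | type | required | notes |
|---|---|---|---|
| cas | text | yes | |
| kind | enum | yes | log_kow, log_koc, pka, solubility_mg_per_L |
| value | number | yes | solubility > 0 (mg/L at 25 °C) |
| provenance | enum | yes | experimental or predicted |
| ph | pH | no | in [0, 14]; relevant for log_koc |
| source | text | no | citation key |

## sites.csv

| column | type | required | notes |
|---|---|---|---|
| site_id | text | yes | |
| medium | enum | yes | spring, river, borehole |
| latitude | degrees | yes | decimal degrees or DMS (`43°32′34.6″N`) |
| longitude | degrees | yes | decimal degrees or DMS |
| water_temperature | °C | no | pass-through |
| conductivity | µS/cm | no | pass-through |

## measurements.csv

| column | type | required | notes |
|---|---|---|---|
| site | text | yes | matches sites.csv site_id |
| campaign | text | yes | date or ordinal label |
| substance | text | yes | CAS |
| concentration | ng/L | no | empty when detected is False |
| lod | ng/L | yes | > 0; per (analyte, lab) |
| lab | enum | yes | lab_A or lab_B |
| detected | bool | yes | True requires concentration ≥ lod |

## hazard.csv (long format: one evidence line per row)

| column | type | required | notes |
|---|---|---|---|
| cas | text | yes | |
| evidence | enum | yes | half_life, biodeg_screen, log_koc, noec, cmr, stot_re, cramer, p_score, b_score, t_score |
| value | number | kind-dependent | half_life days; noec mg/L; log_koc value; scores in [0,1]; stot_re 1 |
| qualifier | text | kind-dependent | half_life: water/sediment; biodeg_screen: readily/inherently/not_biodegradable; log_koc: pH; cmr: carcinogenic/germ_cell_mutagenic/reproductive_toxicant; cramer: I/II/III |
| provenance | text | no | half_life: measured/qsar; biodeg_screen: test/qsar; log_koc: experimental/predicted; scores: reliability flag |

## pnec.csv

| column | type | required | notes |
|---|---|---|---|
| cas | text | yes | |
| pnec | ng/L | yes | > 0; lowest value retained on duplicates |
| source | text | no | citation key |
| basis | text | no | e.g. lowest across trophic levels |

## Outputs

`occurrence.csv` (per substance[, site]: n_samples, n_detects,
detection_frequency, conc_min/median/max), `pbt_scores.csv` (P, B, T,
PBT per substance), `pbtr_by_site.csv` (R_i per detected compound,
PBTr, n, rank_class per site), `pmt_conclusions.csv` (three criterion
conclusions, category, semicolon-joined rationale), `rq_results.csv`
(MEC, PNEC, RQ, risk_class per site/campaign/substance), `rq_site.csv`
(RQ_site, n_compounds, dominant substance) and `report.md`.
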