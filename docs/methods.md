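# Methods

`ecotoxrank` implements a four-stage prioritization workflow for
emerging contaminants (ECs) measured in surface water and groundwater:
occurrence summaries, PBT scoring with a concentration-weighted site
rank, REACH-style PMT/vPvM screening, and risk-quotient assessment.
This note describes each model, its assumptions, the tunable
parameters, and the design choices made where the methodology leaves
the design open.

## Data model and censoring

Concentrations are held internally in ng/L; PNECs may be supplied in
µg/L or mg/L and are converted on ingest (exact power-of-ten scaling),
which removes the classic silent 10³ error between PNEC tables and
measurement tables. A measurement is either *detected* (a concentration
at or above its limit of detection, LOD) or *censored* (no value, only
the LOD). No stage ever substitutes LOD/2 or any other imputation;
statistics over concentrations are statistics over detects, and
non-detects enter only detection-frequency denominators. The LOD is a
per-(analyte, lab) attribute because two commissioned laboratories with
different instruments legitimately assign different LODs to the same
analyte. CAS registry numbers are validated with the standard
check-digit algorithm; site coordinates accept either decimal degrees
or printed DMS strings.

## Occurrence summaries

Per substance (optionally per substance-site): sample count, detect
count, detection frequency (a fraction internally; percent is a
formatting concern), and min/median/max over detected concentrations.
The even-count median is the arithmetic mean of the central pair — the
dominant convention. Summaries are permutation-invariant, and counts
are additive under merging of campaign subsets.

## PBT score and PBTr site rank

Persistence, bioaccumulation and toxicity scores P, B, T ∈ [0, 1] are
*inputs*: they come from upstream QSAR prediction and are never
recomputed or imputed here (a substance missing any score is excluded
with a logged warning). They aggregate geometrically,

    PBT = P^0.4 · B^0.4 · T^0.2,

so the exponents sum to one, persistence and bioaccumulation weigh
equally and twice as much as toxicity, and a zero in any dimension
annihilates the score. Per site, each detected compound i contributes a
rank R_i = PBT_i × c_i, where c_i is a per-(site, substance)
concentration statistic over detects — median by default (the headline
occurrence statistic), maximum in worst-case mode. The site statistic
is the weighted mean

    PBTr = Σ R_i w_i / Σ w_i,

with all weights w_i = 1 by default, treating hazard and exposure as
equally relevant; weights are exposed for sensitivity analyses. PBTr
therefore carries ng/L units scaled by a dimensionless score.
Substances never detected at a site do not enter that site's sum (they
are not zero-concentration observations, they are absent evidence).

Sites are binned into none/low/medium/high cumulative-rank classes. A
PBTr of exactly zero maps to *none*. The low/medium/high boundaries are
not fixed by the methodology, so the default is terciles of the nonzero
site values with an explicit override: low below the first tercile,
medium from the first to below the second, high at or above the second.
With a single nonzero site the terciles collapse onto the value itself
and that site classifies as *high* — the conservative reading of a
degenerate quantile rule, and documented behaviour rather than an
accident.

## PMT/vPvM screening

The rule engine concludes three criteria per substance from an evidence
bundle, then assigns one of six categories. All thresholds live in
`PmtThresholds` (defaults in parentheses).

**Persistence.** Measured degradation half-lives in water or sediment
are decisive: vP above 180 days (strict), P at 40 days or longer
(inclusive), not-P below. With several measured values the maximum
across compartments is used — worst case, since the guidance names the
compartments without an aggregation rule. Without measured half-lives,
screening or QSAR lines indicating non-biodegradability conclude
*potential P/vP*; at least two independent such lines (configurable)
conclude *potential P/vP++* — the "sufficient weight of evidence that P
or vP is met, but unclear which" tier, operationalized as a line count
because the guidance does not quantify it. Screens indicating ready or
inherent biodegradability, with nothing pointing the other way,
conclude not-P. No persistence evidence at all falls back to
*potential P/vP* with a logged caveat — never a silent default.

**Mobility.** log K_OC records are restricted to the pH 4–9 window
(records with no stated pH are kept as environmentally relevant);
experimental records take precedence over predicted ones, and within
the preferred tier the minimum — most mobile, most conservative — value
is classified: vM at ≤ 3.0, M at ≤ 4.0, both inclusive as printed.
No usable record concludes not-M with a logged caveat.

**Toxicity.** T when the long-term NOEC or EC10 for freshwater
organisms is strictly below 0.01 mg/L, or any CMR classification
(carcinogenic, germ-cell mutagenic, reproductive toxicant) applies, or
specific target-organ toxicity after repeated exposure is recorded.
Otherwise the Cramer structural classification differentiates potential
toxicants (class III → pT) from non-toxic (class I/II → not-T). No
toxicity evidence falls back to pT with a caveat.

**Categories.** Evaluated in precedence order: *vPvM & PMT*
(vP ∧ vM ∧ T); *vPvM* (vP ∧ vM without T, and also the potential
P/vP++ route when the substance is detected in raw water — here,
springs and boreholes); *PMT* (P/vP ∧ M/vM ∧ T); *PM* (P/vP ∧ M/vM
without T); *potential PMT/vPvM* (screening-grade persistence with
mobile conclusions); *not PMT/vPvM* (not-P or not-M concluded). Two
choices the guidance leaves open: a not-P or not-M conclusion
short-circuits the potential bucket, and a pT conclusion never
satisfies T but routes an otherwise-PMT substance to *potential
PMT/vPvM* rather than PM (Cramer III signals unresolved toxicity, not
absence; configurable via `pt_routes_to_potential`). The category map
is total over all 5×3×3×2 = 90 criterion combinations — verified by
exhaustive enumeration — and every conclusion carries a rationale trail
citing the evidence or fallback rule that fired.

## Risk quotients

RQ = MEC / PNEC, dimensionless, computed per (site, campaign, detected
substance). The ratio — not a product — is the only reading consistent
with the dimensionless class boundaries and with the universal
MEC/PNEC screening convention, even though prioritization write-ups
sometimes loosely say "multiplying". Classes: negligible below 0.01,
low 0.01–0.1, moderate 0.1–1, high at 1 and above. The published
boundaries are strict inequalities that leave the boundary points
unassigned; lower-inclusive half-open intervals are adopted so every
nonnegative RQ has a class. Multiple PNECs per substance collapse to
the minimum (the lowest-PNEC convention); the built-in reference table
ships ibuprofen at 1.65 µg/L (1650 ng/L), user tables override it. The
site aggregate RQ_site = Σ RQ_i sums over compounds detected at the
location (concentration addition), per campaign by default with a
pooled mode exposed; the dominant substance is the argmax RQ with ties
broken by CAS order. An optional sensitivity mode scores non-detects at
their LOD (an upper bound) and is off by default.

## Synthetic-data generator

The generator emulates the tabular structure of a small karst-catchment
monitoring study: 21 substances partitioned 11/4/2/3/1 across
pharmaceutical, lifestyle, personal-care, agricultural and industrial
groups; four sites (two spring captures, the river feeding the system,
a deep borehole); and site × campaign × substance measurements.
Defaults and rationale:

| parameter | default | why |
|---|---|---|
| `n_campaigns` | 12 | a monthly year; arbitrary testing default, not study-derived |
| `detection_prob` | 0.6 | mid-range detection frequency typical of EC monitoring |
| `conc_log_mean` | 3.4 (ln ng/L) | detected-concentration median ≈ 30 ng/L |
| `conc_log_sd` | 1.0 | detected ranges spanning ~2 orders of magnitude |
| `lod_range` | 0.5–2 ng/L | LC-MS/MS multiresidue LODs; low enough that LOD-flooring is negligible |
| `half_life_median_days` | 60 | centres evidence across the P boundary |

Detected concentrations are log-normal — the standard occurrence model
for trace contaminants — and detection is an independent Bernoulli
event per (site, campaign, substance); a detected draw below the LOD is
floored at the LOD so every record satisfies the censoring invariant.
Hazard evidence covers all persistence-evidence tiers (measured,
screening-only, none — the first three substances are pinned to the
three tiers so every fixture exercises all rule branches), log K_OC
points at 1–3 pH values in [2, 11], log-uniform NOECs, rare Bernoulli
CMR/STOT flags, uniform Cramer classes and uniform P/B/T scores. One
integer seed drives every table through `numpy` `SeedSequence`
spawning, so the whole fixture reproduces byte-for-byte from one
number.

What the generator does *not* emulate: karst hydrodynamics (spring
discharge, event-driven concentration pulses), temporal autocorrelation
across campaigns, spatial correlation between sites, or correlations
between a substance's properties and its occurrence. Passing tests
therefore demonstrate that the pipeline's arithmetic, rules and
invariants are correct under the stated statistical model — not that
any real catchment behaves like the fixture.

## Numerical choices and degenerate inputs

- PBT/PBTr and RQ/RQ_site agree with brute-force loop implementations
  to 1e-12 relative tolerance (tested on 1000 random instances).
- Threshold boundary semantics follow the printed inequalities exactly:
  P at ≥ 40 d, vP at > 180 d, M at ≤ 4.0, vM at ≤ 3.0, T at < 0.01
  mg/L, and RQ class lower bounds inclusive.
- Empty inputs: occurrence of an empty measurement set is an empty
  summary list; RQ_site of an empty collection is 0 with no dominant
  substance; PBTr of an empty rank set is an explicit error (a mean of
  nothing), and a site with no detections simply produces no PBTr row.
- All config models validate threshold ordering (0.01 < 0.1 < 1,
  40 < 180, 3.0 < 4.0) before any computation runs.
- Problem sizes in the test suite: grid probes run over a few hundred
  points; oracle equivalence uses 1000 random instances; parameter
  recovery uses 4 sites × 500 campaigns × 21 substances (42 000
  records), comfortably enough for 3σ binomial bounds and 10%
  recovery of the log-normal parameters.

## Known limitations

- P, B, T scores and all QSAR predictions are trusted inputs; the
  package deliberately contains no predictive chemistry.
- The none/low/medium/high PBTr classes depend on the chosen cutoffs;
  the tercile default is relative to the analysed site set and not
  comparable across studies without fixed cutoffs.
- The weight-of-evidence operationalization (line counts, max-over-
  compartments, pT routing) is one defensible reading of screening
  guidance that is not fully prescriptive; all such knobs are exposed
  in `PmtThresholds` and surfaced in the audit trail.
- RQ_site assumes concentration addition across compounds, which
  ignores interaction effects.
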