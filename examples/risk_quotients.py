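"""Risk-quotient screening: RQ = MEC / PNEC and per-site sums.

Uses the built-in ibuprofen PNEC (1.65 µg/L, i.e. 1650 ng/L) against a
few measured concentrations, then aggregates to RQ_site.
"""

from ecotoxrank.data_model import MeasurementRecord
from ecotoxrank.risk import aggregate_site_risk, builtin_pnec_table, compute_risk

measurements = [
    MeasurementRecord(site="Spring-1", campaign="C1", substance="15687-27-1",
                      concentration=165.0, lod=1.0, lab="lab_A", detected=True),
    MeasurementRecord(site="Spring-1", campaign="C1", substance="15687-27-1",
                      concentration=None, lod=1.0, lab="lab_A", detected=False),
    MeasurementRecord(site="Spring-1", campaign="C2", substance="15687-27-1",
                      concentration=3300.0, lod=1.0, lab="lab_A", detected=True),
]

results = compute_risk(measurements, builtin_pnec_table())
for r in results:
    print(f"{r.site} {r.campaign}: MEC {r.mec:7.1f} ng/L / PNEC {r.pnec:.0f} "
          f"-> RQ {r.rq:.3f} ({r.risk_class.value})")

for s in aggregate_site_risk(results):
    print(f"RQ_site {s.site} {s.campaign}: {s.rq_site:.3f} "
          f"(dominant: {s.dominant_substance})")

# RQ below 0.01 is negligible, 0.01-0.1 low, 0.1-1 moderate and above 1
# high ecotoxicological risk; RQ_site adds the quotients of all detected
# compounds at a location (concentration addition).
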