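"""Classify substances into the six REACH PMT/vPvM screening categories.

Three hand-built evidence bundles show the main routes: a measured
half-life with low log K_OC and chronic toxicity (vPvM & PMT), a
screening-only persistence call (potential PMT/vPvM), and a readily
biodegradable substance (not PMT/vPvM).
"""

from ecotoxrank.pmt import (
    BiodegScreen,
    HalfLife,
    HazardEvidence,
    KocRecord,
    assess_substance,
)

bundles = [
    HazardEvidence(
        substance="worst-case",
        half_lives=[HalfLife(value=200.0, compartment="water")],
        koc_records=[KocRecord(log_koc=2.5, ph=7.0)],
        noec_or_ec10=0.005,
    ),
    HazardEvidence(
        substance="screening-only",
        biodeg_screens=[BiodegScreen(call="not_biodegradable", provenance="qsar")],
        koc_records=[KocRecord(log_koc=3.5, ph=7.0)],
        cramer_class="III",
    ),
    HazardEvidence(
        substance="degradable",
        biodeg_screens=[BiodegScreen(call="readily")],
        koc_records=[KocRecord(log_koc=2.0, ph=7.0)],
        cramer_class="I",
    ),
]

for ev in bundles:
    c = assess_substance(ev)
    print(f"{ev.substance:>14}: P={c.persistence.value:<24} "
          f"M={c.mobility.value:<6} T={c.toxicity.value:<6} -> {c.category.value}")
    for line in c.rationale:
        print(f"                  {line}")
    print()

# The rationale trail records every rule that fired, so a screening
# decision can be audited back to its evidence.
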