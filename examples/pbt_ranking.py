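"""Score substances with the geometric PBT aggregate and rank sites by PBTr.

PBT = P^0.4 · B^0.4 · T^0.2 combines persistence, bioaccumulation and
toxicity scores in [0, 1]; per site each detected compound contributes
R_i = PBT × median detected concentration, and PBTr is the mean of the
R_i. Sites then fall into none/low/medium/high cumulative-rank classes.
"""

from ecotoxrank.pbt import pbt_score, site_pbtr
from ecotoxrank.pipeline import extract_pbt_scores
from ecotoxrank.synthetic_data import (
    GeneratorConfig,
    generate_catalog,
    generate_hazard,
    generate_measurements,
    generate_sites,
)

print(f"PBT(0.8, 0.6, 0.4) = {pbt_score(0.8, 0.6, 0.4):.4f}\n")

cfg = GeneratorConfig(seed=42)
substances, _ = generate_catalog(cfg)
hazard = generate_hazard(cfg, substances)
measurements = generate_measurements(cfg, substances, generate_sites(cfg))

scores = extract_pbt_scores(hazard)
for result in site_pbtr(measurements, scores):
    print(f"{result.site:>10}: PBTr = {result.pbtr:7.2f} "
          f"(n = {result.n} compounds, class {result.rank_class.value})")

# PBTr carries the units of concentration (ng/L) scaled by the
# dimensionless PBT score; larger values mean a heavier cumulative
# hazard-weighted load at the site.
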