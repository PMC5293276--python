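"""Classical small-area variation battery for the three archetypes.

Prints, per condition and year: total cases, the age/sex-standardized rate
per 10,000 person-years, the extremal quotient after trimming the 5th/95th
percentile tails (EQ5-95; how many-fold the highest-rate surviving area
exceeds the lowest), and the systematic coefficient of variation (SCV; the
between-area variance of observed/expected ratios in excess of Poisson
noise — values above ~0.1 are conventionally read as high variation).
"""

import areavar as av

for name in ("PCI_like", "CCC_like", "COPD_like"):
    geo, pop, panel, _ = av.preset_scenario(
        name, seed=3, J=8, areas_per_region=14, T=12, with_geometry=False
    )
    vt = av.variation_table(panel, pop)
    print(f"\n=== {name} ===")
    print(vt[["year", "cases", "rate_per_10k", "eq5_95", "scv"]]
          .round(3).to_string(index=False))
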