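"""Derived glycan traits and the CDX1-high vs CDX1-low group comparison.

Computes the derived-trait table of a simulated 8+8 cohort and tests each
trait between groups with an exact two-sided Mann-Whitney U test and
Bonferroni correction, as in composition-level glycomics studies.
"""

import glycotrait as gt
from glycotrait.stats import mann_whitney_traits, results_frame

profiles, truth = gt.generate_profiles(gt.paper_like_design(seed=7))
traits = gt.trait_table(profiles)

results = results_frame(mann_whitney_traits(traits, truth.groups))
print(results[["statistic", "p_raw", "p_bonferroni", "mean_high", "mean_low"]]
      .round(3).to_string())
# Multi-fucosylation (~54% vs ~33%), overall and alpha2,3-sialylation
# (lower in the high group), galactosylation per antenna and HexNAc>=Hex
# separate the groups after Bonferroni correction; HexNAc>=7 (27% vs 20%)
# is a trend that usually does not survive correction at n=8/8.
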