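"""Two-tier cross-context DE sharing and the purity-scenario scan.

Classifies interspecies DE genes as shared between heart and iPSC-derived
cardiomyocytes or specific to one context (FDR 5% primary / nominal p 0.05
secondary threshold), computes the heart-set recapitulation fraction, then
reruns the cardiomyocyte analysis over sample subsets of varying culture
purity to show how contamination erodes the detectable overlap.
"""

from orthomex.de import contrast_vector, de_contrast, design_matrix
from orthomex.sharing import (
    classify_sharing,
    enumerate_purity_scenarios,
    overlap_summary,
    scenario_recapitulation,
)
from orthomex.simulate import purity_scan_config, simulate_counts

fx = simulate_counts(purity_scan_config(seed=23))
meta = fx.metadata


def interspecies(group):
    ids = meta.index[meta["group"] == group]
    sub = meta.loc[ids]
    design = design_matrix(sub, factors=["species"], numeric=["RIN"])
    return de_contrast(fx.counts[ids], sub, design,
                       contrast_vector(design, {"species_human": 1.0}))


heart = interspecies("heart")
cm = interspecies("CM_day27_T3")

calls = classify_sharing(heart, cm)
print("two-tier sharing calls (A = heart, B = day-27 cardiomyocytes):")
print(calls["label"].value_counts().to_string())

summ = overlap_summary(heart, cm)
print(f"\nheart interspecies DE set: {summ['reference_size']} genes at FDR < 5%; "
      f"{summ['overlap']} recapitulated in cardiomyocytes at nominal p < 0.05 "
      f"(fraction {summ['fraction']:.2f})")

scenarios = enumerate_purity_scenarios(meta, min_per_species=3, max_scenarios=25, seed=23)
table = scenario_recapitulation(scenarios, fx.counts, meta, heart)
print(f"\npurity scan over {len(table)} cardiomyocyte sample subsets "
      f"(>= 3 samples per species each):")
for lo, hi in ((0.0, 0.5), (0.5, 0.8), (0.8, 1.0)):
    sel = table[(table.mean_purity > lo) & (table.mean_purity <= hi)]
    if len(sel):
        print(f"  mean purity {lo:.1f}-{hi:.1f}: median recapitulation "
              f"{sel['fraction'].median():.2f} over {len(sel)} scenarios")
print("lower-purity subsets recapitulate fewer heart interspecies DE genes: "
      "the contaminant profile carries no species signal and dilutes it")
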