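"""Normalize a simulated two-species count matrix and explore its structure.

Runs the normalization chain (log2 CPM -> expression filter -> TMM ->
cyclic loess) and the two descriptive analyses: PCA with covariate
association, and the pairwise-correlation comparison asking whether
day-27 cardiomyocytes resemble hearts more than day-15 cardiomyocytes do.
"""

import numpy as np
import pandas as pd

from orthomex.expression import (
    correlation_group_test,
    cyclic_loess,
    filter_expressed,
    log2_cpm,
    pca_with_association,
    tmm_factors,
)
from orthomex.simulate import CountsConfig, simulate_counts

config = CountsConfig(
    seed=5,
    n_genes=1500,
    groups={"iPSC": (4, 4), "CM_day15": (5, 5), "CM_day27_T3": (7, 7), "heart": (8, 8)},
)
fx = simulate_counts(config)
counts, meta = fx.counts, fx.metadata
print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples")

kept = filter_expressed(log2_cpm(counts), meta)
counts = counts.loc[kept]
print(f"expression filter (mean log2 CPM > 2 in >= 1 group): {len(kept)} genes kept")

factors = tmm_factors(counts)
print(f"TMM factors span {factors.min():.3f}-{factors.max():.3f} "
      "(composition-corrected effective library sizes)")
norm = log2_cpm(counts, lib_sizes=counts.sum(axis=0) * factors)
norm = cyclic_loess(norm, mode="reference")

scores, var_frac, pvals = pca_with_association(norm, meta, ["group", "species"])
print(f"PC1 explains {100 * var_frac.iloc[0]:.1f}% of variance, "
      f"PC2 {100 * var_frac.iloc[1]:.1f}%")
print(f"PC1 association: group p = {pvals.loc['PC1', 'group']:.2e}, "
      f"species p = {pvals.loc['PC1', 'species']:.2e}")
print("cell/tissue type, not species, dominates the leading components")

res = correlation_group_test(norm, meta, "heart", ("CM_day27_T3", "CM_day15"))
print(f"mean heart correlation: day-27 CM {res['mean_correlations']['CM_day27_T3'].mean():.4f}"
      f" vs day-15 CM {res['mean_correlations']['CM_day15'].mean():.4f} "
      f"(paired t = {res['t_statistic']:.2f}, p = {res['p_value']:.2e})")
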