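"""Two-tier DE-sharing classification, overlap summaries and purity scenarios.

Cross-context comparisons of differential expression lose power when both
contexts must clear a stringent cutoff independently: a gene truly DE in
both may reach FDR significance in only one. The two-tier rule compensates:
a gene DE at FDR < 0.05 in one context is called *shared* if it reaches a
relaxed nominal p < 0.05 in the other, and *context-specific* otherwise.

The recapitulation fraction applies the same logic to sets: of the genes DE
between species in a reference tissue (heart) at FDR 5%, what fraction is
nominally significant in a surrogate cell type (iPSC-derived
cardiomyocytes)? The purity-scenario analysis reruns that question over
many subsets of the cardiomyocyte samples, each subset defining a different
mean culture purity, to show how contaminating cell types dilute the
detectable interspecies signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

FDR_CUTOFF = 0.05
NOMINAL_P_CUTOFF = 0.05
LFC_FLOOR = 1.5
GO_TERM_MIN_GENES = 3   # term-size window recorded in the export manifest
GO_TERM_MAX_GENES = 3000


def classify_sharing(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    fdr: float = FDR_CUTOFF,
    nominal_p: float = NOMINAL_P_CUTOFF,
) -> pd.DataFrame:
    """Label each gene shared / A_specific / B_specific / not_DE.

    A gene significant at FDR < ``fdr`` in context A is shared when its
    nominal p in context B is < ``nominal_p``, A_specific otherwise; the
    rule is symmetric from B. Significance at FDR level in both contexts is
    shared. Both tables must cover the same (orthologous) gene universe.
    """
    if not results_a.index.equals(results_b.index):
        if set(results_a.index) != set(results_b.index):
            raise ValueError("gene universes of the two contexts differ")
        results_b = results_b.reindex(results_a.index)
    sig_a = results_a["fdr"] < fdr
    sig_b = results_b["fdr"] < fdr
    nom_a = results_a["p"] < nominal_p
    nom_b = results_b["p"] < nominal_p
    label = np.select(
        [
            sig_a & sig_b,
            sig_a & nom_b,
            sig_a & ~nom_b,
            sig_b & nom_a,
            sig_b & ~nom_a,
        ],
        ["shared", "shared", "A_specific", "shared", "B_specific"],
        default="not_DE",
    )
    return pd.DataFrame(
        {
            "fdr_A": results_a["fdr"],
            "p_A": results_a["p"],
            "fdr_B": results_b["fdr"],
            "p_B": results_b["p"],
            "label": label,
        },
        index=results_a.index,
    )


def overlap_summary(
    reference_results: pd.DataFrame,
    target_results: pd.DataFrame,
    fdr: float = FDR_CUTOFF,
    nominal_p: float = NOMINAL_P_CUTOFF,
) -> dict:
    """Fraction of reference-context DE genes recapitulated in the target.

    Reference set: genes at FDR < ``fdr`` in the reference context. A
    reference gene is recapitulated when its nominal p in the target context
    is < ``nominal_p`` (the relaxed secondary threshold). The fraction is
    NaN when the reference set is empty.
    """
    ref_genes = reference_results.index[reference_results["fdr"] < fdr]
    target = target_results.reindex(ref_genes)
    n_overlap = int((target["p"] < nominal_p).sum())
    n_ref = len(ref_genes)
    return {
        "reference_size": n_ref,
        "overlap": n_overlap,
        "fraction": (n_overlap / n_ref) if n_ref else float("nan"),
    }


def enrichment_gene_lists(
    contrast_results: pd.DataFrame,
    expressed_a: pd.Index,
    expressed_b: pd.Index,
    lfc_floor: float = LFC_FLOOR,
    fdr: float = FDR_CUTOFF,
) -> dict:
    """Gene lists for an external GO-enrichment tool, plus a manifest.

    Four lists: genes expressed in both contexts with a significant contrast
    and |log2FC| strictly above ``lfc_floor`` split by sign (higher-in-A /
    higher-in-B), and genes passing the expression filter in exactly one
    context (above-threshold-only). The manifest records the term-size
    window the downstream tool should apply (> 3 and < 3000 annotated
    genes) and the background (all expressed genes).
    """
    both = expressed_a.intersection(expressed_b)
    res = contrast_results.reindex(both)
    sig = res[(res["fdr"] < fdr) & (res["logFC"].abs() > lfc_floor)]
    lists = {
        "higher_in_A": sig.index[sig["logFC"] > 0].tolist(),
        "higher_in_B": sig.index[sig["logFC"] < 0].tolist(),
        "above_threshold_only_in_A": expressed_a.difference(expressed_b).tolist(),
        "above_threshold_only_in_B": expressed_b.difference(expressed_a).tolist(),
    }
    manifest = {
        "lfc_floor": lfc_floor,
        "fdr": fdr,
        "background": "all expressed genes (union of both contexts)",
        "go_term_size_min_exclusive": GO_TERM_MIN_GENES,
        "go_term_size_max_exclusive": GO_TERM_MAX_GENES,
        "list_sizes": {k: len(v) for k, v in lists.items()},
    }
    return {"lists": lists, "manifest": manifest}


@dataclass
class PurityScenario:
    """One subset of cardiomyocyte samples with its purity summary."""

    sample_ids: tuple[str, ...]
    purity_by_species: dict[str, float] = field(default_factory=dict)
    mean_purity: float = float("nan")


def enumerate_purity_scenarios(
    metadata: pd.DataFrame,
    min_per_species: int = 3,
    group: str = "CM_day27_T3",
    group_col: str = "group",
    species_col: str = "species",
    purity_col: str = "purity",
    max_scenarios: int | None = None,
    seed: int | None = None,
) -> list[PurityScenario]:
    """All sample subsets with >= ``min_per_species`` per species.

    Each scenario records its per-species and overall mean purity. With
    ``max_scenarios`` set, a seeded subsample stratified by mean purity is
    returned instead of the full (combinatorially large) enumeration; the
    full-sample scenario is always included.
    """
    cm = metadata[metadata[group_col] == group]
    if cm[purity_col].isna().any():
        raise ValueError("purity missing for some candidate samples")
    by_species = {sp: sub.index.tolist() for sp, sub in cm.groupby(species_col)}
    for sp, ids in by_species.items():
        if len(ids) < min_per_species:
            raise ValueError(f"species {sp!r} has {len(ids)} samples < {min_per_species}")
    species = sorted(by_species)
    per_species_subsets = {
        sp: [
            tuple(sub)
            for k in range(min_per_species, len(ids) + 1)
            for sub in combinations(ids, k)
        ]
        for sp, ids in by_species.items()
    }
    scenarios: list[PurityScenario] = []
    seen: set[tuple[str, ...]] = set()

    def add(sample_ids: tuple[str, ...]) -> None:
        key = tuple(sorted(sample_ids))
        if key in seen:
            return
        seen.add(key)
        purities = cm.loc[list(key), purity_col]
        sp_means = {
            sp: float(purities[cm.loc[list(key), species_col] == sp].mean())
            for sp in species
        }
        scenarios.append(
            PurityScenario(
                sample_ids=key,
                purity_by_species=sp_means,
                mean_purity=float(purities.mean()),
            )
        )

    if len(species) == 1:
        combos = [(s,) for s in per_species_subsets[species[0]]]
    else:
        combos = [
            (sa, sb)
            for sa in per_species_subsets[species[0]]
            for sb in per_species_subsets[species[1]]
        ]
    for combo in combos:
        add(tuple(x for sub in combo for x in sub))
    scenarios.sort(key=lambda s: (s.mean_purity, s.sample_ids))
    full = tuple(sorted(cm.index))
    if max_scenarios is not None and len(scenarios) > max_scenarios:
        # quota thinning across equal-width mean-purity bins: the scan
        # compares purity strata, so every stratum needs representatives
        # even when most subsets cluster at intermediate purity
        purities = np.array([s.mean_purity for s in scenarios])
        n_bins = min(10, max_scenarios)
        edges = np.linspace(purities.min(), purities.max(), n_bins + 1)
        bin_of = np.clip(np.searchsorted(edges, purities, side="right") - 1, 0, n_bins - 1)
        rng = np.random.default_rng(seed if seed is not None else 0)
        chosen: list[PurityScenario] = []
        members = [np.flatnonzero(bin_of == b) for b in range(n_bins)]
        members = [m for m in members if m.size]
        quota = int(np.ceil((max_scenarios - 1) / len(members)))
        for m in members:
            if m.size <= quota:
                picks = m
            else:
                offset = int(rng.integers(0, max(1, m.size // quota)))
                picks = m[
                    np.minimum(
                        np.round(np.linspace(0, m.size - 1, quota)).astype(int) + offset,
                        m.size - 1,
                    )
                ]
            chosen.extend(scenarios[i] for i in np.unique(picks))
        chosen = chosen[: max(max_scenarios - 1, len(members))]
        if full not in {s.sample_ids for s in chosen}:
            chosen.append(next(s for s in scenarios if s.sample_ids == full))
        scenarios = sorted(
            {s.sample_ids: s for s in chosen}.values(),
            key=lambda s: (s.mean_purity, s.sample_ids),
        )
    return scenarios


def scenario_recapitulation(
    scenarios: list[PurityScenario],
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    reference_results: pd.DataFrame,
    covariates: list[str] = ("RIN",),
    species_col: str = "species",
    fdr: float = FDR_CUTOFF,
    nominal_p: float = NOMINAL_P_CUTOFF,
) -> pd.DataFrame:
    """Rerun the interspecies cardiomyocyte DE per scenario and score overlap.

    Each scenario's sample subset gets its own species + covariates model
    (no cell-type term — one cell type per scenario); the fixed heart
    reference set is then scored with :func:`overlap_summary`. A scenario
    whose model fails is marked failed and the rest proceed.
    """
    from .de import contrast_vector, de_contrast, design_matrix

    rows = []
    for k, sc in enumerate(scenarios):
        cols = list(sc.sample_ids)
        sub_counts = counts[cols]
        sub_meta = metadata.loc[cols]
        try:
            design = design_matrix(sub_meta, factors=[species_col], numeric=list(covariates))
            sp_cols = [c for c in design.columns if c.startswith(species_col + "_")]
            contrast = contrast_vector(design, {sp_cols[0]: 1.0})
            res = de_contrast(sub_counts, sub_meta, design, contrast)
            summ = overlap_summary(reference_results, res, fdr=fdr, nominal_p=nominal_p)
            rows.append(
                {
                    "scenario": k,
                    "n_samples": len(cols),
                    "mean_purity": sc.mean_purity,
                    "reference_size": summ["reference_size"],
                    "overlap": summ["overlap"],
                    "fraction": summ["fraction"],
                    "failed": False,
                }
            )
        except Exception:  # noqa: BLE001 - one bad scenario must not kill the scan
            rows.append(
                {
                    "scenario": k,
                    "n_samples": len(cols),
                    "mean_purity": sc.mean_purity,
                    "reference_size": np.nan,
                    "overlap": np.nan,
                    "fraction": np.nan,
                    "failed": True,
                }
            )
    return pd.DataFrame(rows).set_index("scenario")
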