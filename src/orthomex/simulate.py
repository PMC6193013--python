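"""Synthetic fixtures with planted truth for every downstream module.

Two generators:

* :func:`simulate_genome_pair` / :func:`simulate_psl` — a divergent genome
  pair (an ancestral sequence and a descendant mutated at a configurable
  per-base substitution rate), a GTF of exon annotations, and the three
  alignment-hit files (forward, reverse, back) a reciprocal-alignment run
  would produce, with deliberately planted confounders: paralogous copies
  above the ambiguity identity floor, hits containing a large single indel,
  and queries whose reverse hit lands away from home. The truth table
  records, per metaexon, its true coordinates in both genomes and which
  confounder (if any) should eliminate it.

* :func:`simulate_counts` — negative-binomial count matrices over a
  two-species, multi-group design with planted per-gene interspecies
  effects (shared between heart and cardiomyocytes, heart-specific,
  CM-specific, or null), cell-type effects, an individual random intercept
  with a configurable intra-class correlation, an RNA-quality (RIN) slope,
  and cardiomyocyte purity modeled as a convex mixture of the pure
  cardiomyocyte expression profile and a species-shared contaminant profile
  on the linear expression scale. Because the contaminant carries no
  species effect, lowering purity shrinks the detectable interspecies
  signal — the mechanism the purity-scenario analysis measures.

Everything is driven by a single integer seed through one
``numpy.random.default_rng`` stream per generator call; outputs are
byte-identical across runs for a fixed configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ExonRecord, MetaExon, condense
from .intervals import GenomicInterval

BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# genome pair + alignment hits
# ---------------------------------------------------------------------------


@dataclass
class GenomeConfig:
    """Parameters of the genome-pair fixture.

    divergence is the per-base substitution probability separating the two
    descendants (0.012 mimics the human-chimpanzee autosomal distance);
    paralog_identity is the sequence identity of planted duplicate copies —
    above 0.90 a paralog makes its query ambiguous and must eliminate it.
    """

    seed: int = 0
    genome_length: int = 60_000
    n_genes: int = 20
    exons_per_gene: int = 3
    exon_length: tuple[int, int] = (80, 240)
    intron_length: tuple[int, int] = (50, 150)
    intergenic: tuple[int, int] = (100, 300)
    divergence: float = 0.012
    n_paralog_queries: int = 0
    paralog_identity: float = 0.95
    n_indel_queries: int = 0
    indel_size: int = 40
    n_reciprocal_fail_queries: int = 0


@dataclass
class GenomePair:
    source_seq: str
    target_seq: str
    exons: list[ExonRecord]
    metaexons: list[MetaExon]
    truth: pd.DataFrame  # per metaexon
    config: GenomeConfig


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` to a different base."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    idx = np.flatnonzero(hit)
    if idx.size:
        # shift by 1..3 in base space guarantees a different base
        shifts = rng.integers(1, 4, size=idx.size)
        base_idx = np.searchsorted(BASES, seq[idx])
        out[idx] = BASES[(base_idx + shifts) % 4]
    return out


def simulate_genome_pair(config: GenomeConfig) -> GenomePair:
    """Build the two genomes, exon annotation, metaexons and truth table."""
    rng = np.random.default_rng(config.seed)
    n_exon_bases = config.n_genes * config.exons_per_gene * config.exon_length[1]
    n_spacer = config.n_genes * (
        config.exons_per_gene * config.intron_length[1] + config.intergenic[1]
    )
    if n_exon_bases + n_spacer > config.genome_length:
        raise ValueError(
            "infeasible placement: genome too short for the requested gene layout"
        )
    ancestor = rng.choice(BASES, size=config.genome_length)
    target = _mutate(ancestor, config.divergence, rng)

    exons: list[ExonRecord] = []
    pos = int(rng.integers(*config.intergenic))
    for g in range(config.n_genes):
        gid = f"g{g+1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        for e in range(config.exons_per_gene):
            length = int(rng.integers(*config.exon_length))
            exons.append(
                ExonRecord(
                    interval=GenomicInterval("chr1", pos, pos + length, strand),
                    gene_id=gid,
                    exon_id=f"{gid}.e{e+1}",
                )
            )
            pos += length + int(rng.integers(*config.intron_length))
        pos += int(rng.integers(*config.intergenic))
    metaexons = condense(exons)

    # realized identity per metaexon from the actual sequences
    rows = []
    for m in metaexons:
        s, e = m.interval.start, m.interval.end
        ident = float(np.mean(ancestor[s:e] == target[s:e]))
        rows.append(
            {
                "metaexon": m.name,
                "gene_id": m.gene_id,
                "chrom": m.interval.chrom,
                "start": s,
                "end": e,
                "strand": m.interval.strand,
                "length": e - s,
                "identity": ident,
                "is_paralog_confounded": False,
                "has_large_indel": False,
                "reciprocal_fail": False,
            }
        )
    truth = pd.DataFrame(rows).set_index("metaexon")

    names = truth.index.to_numpy()
    confounded = rng.choice(
        names,
        size=min(
            len(names),
            config.n_paralog_queries
            + config.n_indel_queries
            + config.n_reciprocal_fail_queries,
        ),
        replace=False,
    )
    k = 0
    truth.loc[confounded[k : k + config.n_paralog_queries], "is_paralog_confounded"] = True
    k += config.n_paralog_queries
    truth.loc[confounded[k : k + config.n_indel_queries], "has_large_indel"] = True
    k += config.n_indel_queries
    truth.loc[confounded[k : k + config.n_reciprocal_fail_queries], "reciprocal_fail"] = True

    return GenomePair(
        source_seq="".join(ancestor),
        target_seq="".join(target),
        exons=exons,
        metaexons=metaexons,
        truth=truth,
        config=config,
    )


def _psl_line(
    matches: int,
    mismatches: int,
    strand: str,
    q_name: str,
    q_size: int,
    t_name: str,
    t_size: int,
    blocks: list[tuple[int, int, int]],  # (size, q_start, t_start)
) -> str:
    sizes = [b[0] for b in blocks]
    q_starts = [b[1] for b in blocks]
    t_starts = [b[2] for b in blocks]
    q_gaps = [q_starts[i + 1] - (q_starts[i] + sizes[i]) for i in range(len(blocks) - 1)]
    t_gaps = [t_starts[i + 1] - (t_starts[i] + sizes[i]) for i in range(len(blocks) - 1)]
    q_num_ins = sum(1 for g in q_gaps if g > 0)
    q_base_ins = sum(g for g in q_gaps if g > 0)
    t_num_ins = sum(1 for g in t_gaps if g > 0)
    t_base_ins = sum(g for g in t_gaps if g > 0)
    fields = [
        matches, mismatches, 0, 0,
        q_num_ins, q_base_ins, t_num_ins, t_base_ins,
        strand, q_name, q_size, q_starts[0], q_starts[-1] + sizes[-1],
        t_name, t_size, t_starts[0], t_starts[-1] + sizes[-1],
        len(blocks),
        ",".join(map(str, sizes)) + ",",
        ",".join(map(str, q_starts)) + ",",
        ",".join(map(str, t_starts)) + ",",
    ]
    return "\t".join(map(str, fields))


def simulate_psl(pair: GenomePair, out_dir: str | Path) -> dict[str, Path]:
    """Write forward / reverse / back PSL files consistent with the truth.

    Forward: each source metaexon sequence hits its true target locus at the
    realized identity. Paralog-confounded queries gain a second forward hit
    (and a matching back-direction hit) at a fabricated locus on the
    paralog scaffold at the configured paralog identity. Large-indel queries
    have their forward hit split into two blocks separated by a target-side
    gap of ``indel_size``. Reciprocal-fail queries keep a clean forward hit
    but their reverse hit lands at a shifted, non-overlapping location.
    """
    cfg = pair.config
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t_size = len(pair.target_seq)
    s_size = len(pair.source_seq)
    paralog_scaffold = "chr_par"
    paralog_pos = 0
    fwd_lines, rev_lines, back_lines = [], [], []
    for name, row in pair.truth.iterrows():
        L = int(row.length)
        ident = float(row.identity)
        m = int(round(ident * L))
        mm = L - m
        t0 = int(row.start)  # descendant keeps ancestral coordinates
        if row.has_large_indel:
            half = L // 2
            blocks = [(half, 0, t0), (L - half, half, t0 + half + cfg.indel_size)]
            fwd_lines.append(
                _psl_line(m, mm, "+", name, L, "chr1", t_size, blocks)
            )
        else:
            fwd_lines.append(
                _psl_line(m, mm, "+", name, L, "chr1", t_size, [(L, 0, t0)])
            )
        if row.is_paralog_confounded:
            pm = int(round(cfg.paralog_identity * L))
            fwd_lines.append(
                _psl_line(pm, L - pm, "+", name, L, paralog_scaffold, 10**6,
                          [(L, 0, paralog_pos)])
            )
            back_lines.append(
                _psl_line(pm, L - pm, "+", name, L, paralog_scaffold, 10**6,
                          [(L, 0, paralog_pos)])
            )
            paralog_pos += L + 100
        # reverse: target sequence back onto the source genome
        if row.reciprocal_fail:
            shift = 10 * L + 1000
            r0 = (int(row.start) + shift) % max(1, s_size - L)
            rev_lines.append(
                _psl_line(m, mm, "+", name, L, "chr1", s_size, [(L, 0, r0)])
            )
        else:
            rev_lines.append(
                _psl_line(m, mm, "+", name, L, "chr1", s_size, [(L, 0, int(row.start))])
            )
        # back: target sequence onto its own genome — exact self hit
        back_lines.append(
            _psl_line(L, 0, "+", name, L, "chr1", t_size, [(L, 0, t0)])
        )
    paths = {}
    for tag, lines in (("fwd", fwd_lines), ("rev", rev_lines), ("back", back_lines)):
        path = out_dir / f"{tag}.psl"
        path.write_text("\n".join(lines) + "\n")
        paths[tag] = path
    return paths


def write_genome_fixture(pair: GenomePair, out_dir: str | Path) -> dict[str, Path]:
    """Write FASTA pair, GTF, metaexon truth JSON and the config."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tag, seq in (("source", pair.source_seq), ("target", pair.target_seq)):
        p = out_dir / f"{tag}.fa"
        SeqIO.write([SeqRecord(Seq(seq), id="chr1", description="")], str(p), "fasta")
        paths[tag] = p
    gtf = out_dir / "annotation.gtf"
    with open(gtf, "w") as fh:
        for rec in pair.exons:
            iv = rec.interval
            fh.write(
                f"{iv.chrom}\tsim\texon\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t"
                f'gene_id "{rec.gene_id}"; exon_id "{rec.exon_id}";\n'
            )
    paths["gtf"] = gtf
    truth_path = out_dir / "genome_truth.json"
    truth_path.write_text(pair.truth.reset_index().to_json(orient="records", indent=1))
    paths["truth"] = truth_path
    cfg_path = out_dir / "genome_config.json"
    cfg_path.write_text(json.dumps(asdict(pair.config), indent=1))
    paths["config"] = cfg_path
    paths.update(simulate_psl(pair, out_dir))
    return paths


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


@dataclass
class CountsConfig:
    """Parameters of the count-matrix fixture.

    The default design is a typical two-species cardiomyocyte-vs-heart
    comparison: 7 + 7 T3-treated day-27 cardiomyocyte individuals and
    11 + 21 hearts (human + chimpanzee), ~2,000 genes for desk-scale runs. Effect
    categories partition genes by where an interspecies expression
    difference was planted; ``effect_size`` is its magnitude in log2 units
    (sign random per gene). ``icc`` is the intra-class (within-individual)
    correlation of the log-scale residual; ``purity`` values, when given,
    override the uniform draw from ``purity_range`` for cardiomyocyte
    samples in listed order (human then chimpanzee).
    """

    seed: int = 0
    n_genes: int = 2000
    groups: dict = field(
        default_factory=lambda: {"CM_day27_T3": (7, 7), "heart": (11, 21)}
    )
    replicates_per_individual: int = 1
    baseline_log2_mean: float = 6.0
    baseline_log2_sd: float = 1.5
    lib_size: float = 2e6
    lib_size_cv: float = 0.15
    dispersion: float = 0.05
    effect_size: float = 1.0
    prop_shared: float = 0.10
    prop_heart_specific: float = 0.07
    prop_cm_specific: float = 0.07
    celltype_effect_sd: float = 0.8
    # how far along the iPSC -> heart expression axis each group sits;
    # cardiomyocytes mature toward but never reach the adult-heart profile
    group_maturity: dict = field(
        default_factory=lambda: {
            "iPSC": 0.0,
            "CM_day15": 0.35,
            "CM_day27_noT3": 0.5,
            "CM_day27_T3": 0.6,
            "heart": 1.0,
        }
    )
    residual_log2_sd: float = 0.30
    icc: float = 0.30
    rin_slope_sd: float = 0.03
    rin_range_cells: tuple[float, float] = (8.0, 10.0)
    rin_range_tissue: tuple[float, float] = (5.0, 9.0)
    purity_range: tuple[float, float] = (0.5, 0.95)
    purity: tuple[float, ...] | None = None
    contaminant_corr: float = 0.4
    contaminant_sd: float = 1.5


@dataclass
class CountsFixture:
    counts: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame
    config: CountsConfig


def simulate_counts(config: CountsConfig) -> CountsFixture:
    """Generate counts, metadata and the per-gene effect truth table."""
    rng = np.random.default_rng(config.seed)
    G = config.n_genes
    species = ("human", "chimpanzee")

    # --- sample sheet -----------------------------------------------------
    rows = []
    purity_iter = iter(config.purity) if config.purity is not None else None
    for group, counts_per_species in config.groups.items():
        is_cell = group != "heart"
        for sp, n_ind in zip(species, counts_per_species):
            for i in range(n_ind):
                # cultured samples (iPSC and its cardiomyocyte derivatives)
                # from index i come from the same individual; hearts are
                # unrelated donors
                ind = f"{sp[:1]}ind{i+1}" if is_cell else f"{sp[:1]}heart{i+1}"
                for r in range(config.replicates_per_individual):
                    sid = f"{sp[:1]}_{group}_{i+1}" + (
                        f"_r{r+1}" if config.replicates_per_individual > 1 else ""
                    )
                    rin_lo, rin_hi = (
                        config.rin_range_cells if is_cell else config.rin_range_tissue
                    )
                    purity = np.nan
                    if group.startswith("CM"):
                        if purity_iter is not None:
                            purity = float(next(purity_iter))
                        else:
                            purity = float(rng.uniform(*config.purity_range))
                    rows.append(
                        {
                            "sample_id": sid,
                            "species": sp,
                            "group": group,
                            "individual": ind,
                            "RIN": float(np.round(rng.uniform(rin_lo, rin_hi), 2)),
                            "purity": purity,
                        }
                    )
    metadata = pd.DataFrame(rows).set_index("sample_id")

    # --- per-gene truth ---------------------------------------------------
    genes = [f"gene{i+1:05d}" for i in range(G)]
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, G)
    # exact category counts (randomly placed): the planted composition is a
    # design constant of the fixture, not a sampled quantity
    n_shared = int(round(config.prop_shared * G))
    n_hs = int(round(config.prop_heart_specific * G))
    n_cs = int(round(config.prop_cm_specific * G))
    cats = np.array(
        ["shared"] * n_shared
        + ["heart_specific"] * n_hs
        + ["cm_specific"] * n_cs
        + ["null"] * (G - n_shared - n_hs - n_cs)
    )
    rng.shuffle(cats)
    sign = rng.choice([-1.0, 1.0], size=G)
    eff_heart = np.where(
        np.isin(cats, ["shared", "heart_specific"]), sign * config.effect_size, 0.0
    )
    eff_cm = np.where(
        np.isin(cats, ["shared", "cm_specific"]), sign * config.effect_size, 0.0
    )
    celltype_eff = rng.normal(0.0, config.celltype_effect_sd, G)  # heart vs cell shift
    rin_slope = rng.normal(0.0, config.rin_slope_sd, G)
    # contaminant profile: species-shared, correlated with the CM baseline
    z = rng.normal(0.0, 1.0, G)
    b_std = (baseline - baseline.mean()) / max(baseline.std(), 1e-9)
    contaminant = (
        baseline.mean()
        + config.contaminant_sd
        * (config.contaminant_corr * b_std + np.sqrt(1 - config.contaminant_corr**2) * z)
    )
    truth = pd.DataFrame(
        {
            "category": cats,
            "baseline_log2": baseline,
            "effect_heart": eff_heart,
            "effect_cm": eff_cm,
            "celltype_effect": celltype_eff,
        },
        index=pd.Index(genes, name="gene_id"),
    )

    # --- expression and counts -------------------------------------------
    tau = np.sqrt(config.icc) * config.residual_log2_sd
    eps_sd = np.sqrt(1 - config.icc) * config.residual_log2_sd
    indiv_intercepts: dict[str, np.ndarray] = {}
    mean_rin = metadata["RIN"].mean()
    cols = {}
    lib_targets = {}
    for sid, s in metadata.iterrows():
        if s.individual not in indiv_intercepts:
            indiv_intercepts[s.individual] = rng.normal(0.0, tau, G)
        is_heart = s.group == "heart"
        sp_eff = eff_heart if is_heart else eff_cm
        # species coded +eff for human, 0 for chimpanzee
        species_term = sp_eff if s.species == "human" else 0.0
        maturity = config.group_maturity.get(s.group, 1.0 if is_heart else 0.5)
        expr = (
            baseline
            + maturity * celltype_eff
            + species_term
            + indiv_intercepts[s.individual]
            + rin_slope * (s.RIN - mean_rin)
            + rng.normal(0.0, eps_sd, G)
        )
        if s.group.startswith("CM") and np.isfinite(s.purity) and s.purity < 1.0:
            expr = np.log2(s.purity * 2.0**expr + (1 - s.purity) * 2.0**contaminant)
        cols[sid] = expr
        lib_targets[sid] = config.lib_size * float(
            np.exp(rng.normal(0.0, config.lib_size_cv))
        )
    counts = {}
    for sid in metadata.index:
        lam = 2.0 ** cols[sid]
        mu = lam / lam.sum() * lib_targets[sid]
        if (mu <= 0).any():
            raise ValueError("non-positive expected count")
        if config.dispersion > 0:
            r = 1.0 / config.dispersion
            counts[sid] = rng.negative_binomial(r, r / (r + mu))
        else:
            counts[sid] = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=truth.index)
    return CountsFixture(counts=counts_df, metadata=metadata, truth=truth, config=config)


def write_counts_fixture(fx: CountsFixture, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out_dir / "counts.tsv",
        "metadata": out_dir / "metadata.tsv",
        "truth": out_dir / "counts_truth.tsv",
        "config": out_dir / "counts_config.json",
    }
    fx.counts.to_csv(paths["counts"], sep="\t")
    fx.metadata.to_csv(paths["metadata"], sep="\t")
    fx.truth.to_csv(paths["truth"], sep="\t")
    cfg = asdict(fx.config)
    paths["config"].write_text(json.dumps(cfg, indent=1, default=str))
    return paths


def random_annotation(
    rng: np.random.Generator,
    genome_length: int = 10_000,
    max_genes: int = 20,
    max_exons_per_gene: int = 6,
    p_duplicate: float = 0.15,
) -> list[ExonRecord]:
    """An adversarial random exon annotation for stress-testing condensation.

    Unlike :func:`simulate_genome_pair` this deliberately produces messy
    input: genes overlap each other freely, exons duplicate, and exon
    lengths range down to 1 bp so the 10 bp retention and 1 bp collapse
    thresholds are exercised at their boundaries.
    """
    n_genes = int(rng.integers(1, max_genes + 1))
    exons: list[ExonRecord] = []
    for g in range(n_genes):
        gid = f"g{g+1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, max_exons_per_gene + 1))
        for e in range(n_exons):
            start = int(rng.integers(0, genome_length - 1))
            length = int(rng.integers(1, min(400, genome_length - start) + 1))
            rec = ExonRecord(
                interval=GenomicInterval("chr1", start, start + length, strand),
                gene_id=gid,
                exon_id=f"{gid}.e{e+1}",
            )
            exons.append(rec)
            if rng.random() < p_duplicate:
                exons.append(rec)  # exact duplicate record
    return exons


def planted_overlap_config(seed: int = 0, n_genes: int = 2000) -> CountsConfig:
    """Study conditions for the planted-overlap (recapitulation) recovery check.

    60% of the genes carrying a heart interspecies effect carry the same
    effect in cardiomyocytes (shared 0.12 / heart-specific 0.08 of all
    genes); cardiomyocyte samples are fully pure and the noise scales are
    set so detection at the relaxed nominal threshold is near-complete —
    the recapitulation fraction then measures the set-overlap rule itself
    rather than residual detection power. Purity dilution is studied
    separately under :func:`purity_scan_config`.
    """
    return CountsConfig(
        seed=seed,
        n_genes=n_genes,
        prop_shared=0.12,
        prop_heart_specific=0.08,
        prop_cm_specific=0.05,
        purity=tuple([1.0] * 14),
        dispersion=0.02,
        residual_log2_sd=0.20,
        icc=0.20,
    )


def purity_scan_config(seed: int = 0, n_genes: int = 1500) -> CountsConfig:
    """Study conditions for the purity-scenario analysis.

    The 7 + 7 T3-treated day-27 cardiomyocyte samples span purities from
    0.30 to 0.95 per species, so sample subsets realize mean purities from
    about 0.4 to 0.9 — low-purity scenarios mix in a majority contaminant
    signal and should recapitulate fewer heart interspecies DE genes.
    """
    purities = (0.30, 0.40, 0.50, 0.80, 0.85, 0.90, 0.95)
    return CountsConfig(
        seed=seed,
        n_genes=n_genes,
        prop_shared=0.12,
        prop_heart_specific=0.08,
        prop_cm_specific=0.05,
        purity=purities + purities,
        dispersion=0.02,
        residual_log2_sd=0.20,
        icc=0.20,
    )


def simulate_composition_pair(
    n_genes: int = 2000,
    frac_up: float = 0.10,
    fold: float = 8.0,
    depth: float = 200.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-sample fixture with a planted compositional shift, plus the
    closed-form TMM factors it implies.

    Sample B expresses a fraction ``frac_up`` of genes at ``fold`` times
    sample A's level; all other genes are equal. The unchanged genes'
    log-ratio on the proportion scale is -log2(1 + frac_up*(fold-1)), so the
    expected factors (geometric mean 1) are sqrt(k) and 1/sqrt(k) with
    k = 1 + frac_up*(fold-1).
    """
    rng = np.random.default_rng(seed)
    base = rng.gamma(shape=2.0, scale=depth / 2.0, size=n_genes) + 1.0
    up = np.zeros(n_genes, dtype=bool)
    up[: int(round(frac_up * n_genes))] = True
    mu_a = base
    mu_b = np.where(up, base * fold, base)
    counts = pd.DataFrame(
        {
            "A": rng.poisson(mu_a),
            "B": rng.poisson(mu_b),
        },
        index=[f"gene{i+1:05d}" for i in range(n_genes)],
    )
    k = 1.0 + frac_up * (fold - 1.0)
    expected = pd.Series({"A": np.sqrt(k), "B": 1.0 / np.sqrt(k)}, name="tmm_factor")
    return counts, expected
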