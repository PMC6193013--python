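# Methods

This note records the models, rules and numerical choices behind
`orthomex`, the reasoning where the design was genuinely open, and what
the synthetic fixtures do and do not establish about real data.

## Coordinates and interval rules

All internal coordinates are 0-based half-open; GTF/GFF3 input (1-based
inclusive) is converted at parse time and BED output is native. Under
this convention "overlap" means ≥ 1 shared base, so book-ended intervals
([a,b) and [b,c)) never merge, and all base-count thresholds are exact
integer counts.

The condensation pipeline applies four rules in a fixed order: exact
deduplication; removal of genes whose exonic bases lie wholly within the
exonic bases of a single other gene; subtraction of other-gene bases from
every exon with retention of maximal fragments ≥ 10 bp; collapse of
same-gene exons sharing ≥ 1 bp into metaexons. Decisions worth noting:

- **"Fully overlapping" genes** are judged on exonic bases (not gene
  spans) against one other gene (not the union of all others). Two genes
  with identical exonic footprints mutually contain each other; the
  lexicographically later gene id is removed, a deterministic tie-break.
- **The 10 bp retention rule applies per fragment** after subtraction
  (an exon with an internal conflict can split into several retained
  fragments), and only to exons actually truncated: an exon untouched by
  any cross-gene overlap is kept whatever its length.
- **Strand is ignored** for overlap and containment. The read chemistry
  the pipeline targets is unstranded, so a base shared by opposite-strand
  genes is just as unassignable as one shared on the same strand.
- Genes spanning two chromosomes are rejected at parse; every downstream
  rule assumes single-chromosome genes.

A deliberately literal per-base reference implementation
(`orthomex.naive`) re-derives gene ownership with boolean masks; the
sweep/tree implementation must agree with it exactly on adversarial
random annotations. Collapsing same-gene fragments cannot change base
ownership, so the ownership mask is the collapse-invariant fingerprint
used for that comparison.

## Orthology filtering

Hits are PSL records; `max_indel` is the largest *single* gap event
between consecutive blocks on either side — "indels larger than 25 bp"
is read per event, not as total gapped bases, because multiple small
introns/gaps are a different failure mode than one large structural
difference. Sequence identity is matches / (matches + mismatches): gap
columns are excluded from the denominator so identity measures base-level
divergence of aligned sequence rather than alignment completeness.

Filter order: indel filter → ambiguity removal → best-hit selection →
reciprocal check → collision removal. Two consequences of that order are
load-bearing: ambiguity is judged on the full (indel-filtered) candidate
list, so a query with two plausible homes is removed even though argmax
would have picked one; and collision removal drops *all* members of a
colliding group, since no evidence distinguishes the claimants.

Open parameters, with defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `max_indel` | 25 bp | largest tolerated single gap event (boundary kept) |
| `ambiguity_identity` | 0.90 | identity strictly above which a second distinct location makes a query ambiguous; "distinct" = non-overlapping target intervals |
| `reciprocal_overlap` | 0.5 | minimum overlap of a reverse/back best hit with the original locus, as a fraction of the shorter interval — the standard reciprocal-best-hit quantification of "returns the original location" |

Best-identity ties break deterministically by target (chrom, start, end)
and are logged. The ambiguity rule is applied in both the forward and
reverse directions: a sequence that maps ambiguously on the way back is
equally untrustworthy.

## Normalization

- log₂ CPM uses a prior count of 0.25 (and 2× the prior in the library
  denominator), keeping zeros finite while remaining a log-proportion.
- The expression filter keeps genes whose *group mean* log₂ CPM strictly
  exceeds 2 in at least one cell/tissue group, and is applied before
  normalization factors are computed.
- TMM follows the published algorithm exactly: reference = sample whose
  upper-quartile proportion is nearest the mean; M and A on the
  proportion scale with zero-in-either-sample genes excluded; double
  trimming (30% on M, 5% on A, both tails); inverse-asymptotic-variance
  weights; factors rescaled to geometric mean 1. A test cross-checks the
  factors against the R reference implementation (edgeR) to 1e-6.
  Exact invariance to scaling one library holds only for the log-ratios,
  not the precision weights, so the scale-invariance property is tested
  at 3% tolerance.
- Cyclic loess runs pairwise by default (span 0.7, 3 iterations, half the
  fitted M-vs-A trend moved from each sample of a pair), with a faster
  row-mean reference mode. Below 50 genes the smoother is
  underdetermined and the function refuses to run.
- log₂ RPKM subtracts log₂(L_g/1000) with L_g the species-appropriate
  orthologous gene length, making values comparable across genomes.

## Differential expression

The model chain is the weighted-least-squares approximation to a per-gene
mixed model:

1. **Precision weights**: per-gene OLS on log₂ CPM; lowess (span 0.5) of
   √(residual sd) against mean log₂ count; each observation's weight is
   trend⁻⁴ at its fitted log-count, clipped to a 10⁶ range around the
   median. Library sizes are TMM-effective throughout — without this,
   planted (or real) composition shifts between species masquerade as a
   coherent species effect in every null gene and FDR control degrades.
2. **Individual as a block**: a single consensus within-individual
   correlation, estimated from OLS residual cross-products pooled over
   genes by Fisher-z averaging, then **bias-inverted**: for a fixed
   design both the expected within-block cross-product and the expected
   residual sum of squares are linear in ρ under compound symmetry, so
   the pooled ratio maps back to ρ in closed form. Without the inversion
   the OLS projection attenuates ρ ≈ 0.5 to ≈ 0.23 in a 16-sample
   two-replicate design; with it, recovery is within ±0.06. A true
   per-gene mixed model is out of scope; the pooled-ρ GLS is the
   tractable and testable surrogate.
3. **GLS contrast fit** per gene under V = D C(ρ) D with D = diag(1/√w);
   with ρ = 0 and unit weights this reduces to OLS to numerical
   precision (tested at 1e-10).
4. **Moderation**: method-of-moments fit of the scaled-F prior on log
   variances (trigamma inversion by Newton iteration); posterior
   variances shrink toward s₀² with d₀ extra degrees of freedom. All
   variances equal triggers the d₀ = ∞ pooled branch with a normal
   reference distribution.
5. **BH step-up FDR**, NaN-aware, cross-checked against both a literal
   step-up oracle and statsmodels.

On a 10,000-gene null simulation (7 + 7 samples) the moderated test's
type-I error at nominal 0.05 sits near 0.049.

## Sharing, recapitulation, purity

The two-tier rule: FDR < 0.05 in one context is the primary discovery
threshold; nominal p < 0.05 in the other context is the secondary,
power-compensating threshold. A gene FDR-significant in both contexts is
shared. The recapitulation fraction divides the relaxed-threshold overlap
by the size of the reference (heart) FDR set. Enrichment gene lists use a
strict |log₂FC| > 1.5 floor; "above threshold only" means passing the
expression filter in exactly one context. GO enrichment itself is not
computed — the lists and a manifest (background, term-size window 3–3000
exclusive) are exported for an external tool.

Purity scenarios enumerate all cardiomyocyte sample subsets with ≥ 3
samples per species, each annotated with its mean purity. The full
enumeration grows combinatorially (≈ 9.8k subsets at 7 + 7 samples), so
an optional `max_scenarios` applies quota thinning across equal-width
mean-purity bins — the scan's purpose is comparing purity strata, so
every stratum keeps representatives; the full-sample scenario is always
retained. Each scenario reruns the complete interspecies cardiomyocyte
DE (species + RIN model) on its subset against the fixed heart reference.

## Synthetic data

`simulate_genome_pair` keeps one descendant equal to the ancestor and
mutates the other at per-base probability = divergence (default 0.012,
the approximate human–chimpanzee autosomal distance), so realized
inter-descendant exon identity is ≈ 1 − divergence. Confounders are
planted explicitly: paralogous copies written as extra alignment hits at
a configurable identity (default 0.95, above the ambiguity floor),
forward hits split by a > 25 bp target gap, and reverse hits shifted away
from home. `simulate_psl` fabricates the three PSL files directly from
the truth table; no aligner runs.

`simulate_counts` builds log₂ expression as
baseline + maturity·cell-type effect + species effect (per planted
category) + individual intercept + RIN slope + noise, then mixes
cardiomyocyte samples as purity·CM + (1 − purity)·contaminant on the
linear scale before negative-binomial sampling. Key choices:

- **Default design** is a typical two-species cardiomyocyte-vs-heart
  comparison: 7 + 7 T3-treated day-27 cardiomyocyte individuals, 11 + 21
  hearts, ~2,000 genes (a desk-scale gene count; the modeled per-gene
  structure does not depend on it). Cultured samples sharing an index
  share an individual; hearts are independent donors.
- **Effect categories** (shared / heart-specific / CM-specific / null)
  are planted at *exact* counts, randomly placed — the composition is a
  design constant of the fixture, not a sampled quantity.
- **Noise defaults**: NB dispersion 0.05 and residual log₂ sd 0.30
  (within-individual correlation 0.30 of that residual), typical of
  bulk RNA-seq across unrelated individuals.
- **Maturity** places groups on the iPSC→heart expression axis (iPSC 0,
  day-15 0.35, day-27 0.5/0.6, heart 1), reproducing the observed
  ordering of correlations with heart tissue.
- **Contaminant**: a single species-shared profile correlated 0.4 with
  the cardiomyocyte baseline (sd 1.5). Because it carries no species
  effect, lowering purity shrinks the detectable interspecies signal —
  the mechanism the purity scan measures. The real contaminant mixture
  is unknown; one fibroblast-like profile is the simplest model with
  that property.
- Two named study-condition configs freeze the conditions of the
  headline recovery analyses. `planted_overlap_config`: 60% of
  heart-effect genes also carry the CM effect (0.12/0.08/0.05 of all
  genes), fully pure CM samples and tighter noise (dispersion 0.02,
  residual sd 0.20) so relaxed-threshold detection is near-complete and
  the recapitulation fraction measures the set-overlap rule itself
  rather than residual power; purity dilution is deliberately excluded
  here because it is the subject of the separate scan.
  `purity_scan_config`: per-species purities 0.30–0.95 so sample subsets
  realize mean purities from ≈ 0.4 to ≈ 0.9.

All randomness flows from one integer seed through a single
`numpy.random.default_rng` stream per generator call; fixture writes are
byte-identical across runs.

## What the fixtures do not show

The generators emulate the *structure* of the data, not its full
messiness: alignment hits are fabricated from truth rather than produced
by an aligner, so alignment-level artifacts (soft-clipping, repeat
mosaicism, chained local hits) are absent; the contaminant is a single
profile rather than a mixture of cell types; library composition shifts
arise only from planted effects; and gene counts are desk-scale
(1,500–10,000) rather than genome-scale. Passing tests therefore
establish correctness of the rules and estimators under the stated
model, and calibration/recovery at realistic noise levels — not
performance on any particular real dataset. Headline counts from real
data (database size, DE counts, PC variance fractions) require the real
genomes and sequencing data and are not reproduced here.

## Degenerate inputs and numerical edges

Zero library sizes, empty groups, singleton correlation groups, missing
gene lengths, rank-deficient designs and sub-50-gene loess/voom inputs
raise informative errors. A gene whose GLS covariance fails Cholesky is
flagged NaN and excluded from moderation. TMM returns factor 1 with a
warning when trimming removes every gene. Scenario DE failures mark only
that scenario failed. BH propagates NaN p-values and excludes them from
the test count.
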