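"""Condense a raw exon annotation into gene-owned, non-redundant metaexons.

The condensation pipeline runs four rules in order:

1. **Deduplication** — exon records identical in (chrom, start, end, strand,
   gene) keep one representative; these arise from haplotype/patch scaffolds
   and multiple source annotations.
2. **Fully-overlapping-gene removal** — a gene all of whose exonic bases lie
   within the exonic bases of some other single gene is dropped entirely.
3. **Cross-gene overlap resolution** — for each exon, bases shared with exons
   of any *other* gene are subtracted; each remaining maximal sub-interval of
   at least ``MIN_RETAINED_BP`` (10) bases becomes a retained exon (an exon
   with an internal overlap may split into several smaller exons); shorter
   remnants are discarded. After this step no base is annotated to two genes.
4. **Same-gene collapse** — exons of one gene sharing at least 1 base are
   collapsed into a single metaexon spanning their union. Book-ended exons
   (zero shared bases) stay separate.

The resulting metaexons are transcript-structure-free counting units: read
counting against them avoids double-counting bases claimed by two genes, at
the cost of discarding ambiguous sequence.

Overlap and containment deliberately ignore strand: with unstranded
(non-strand-specific) libraries a read cannot be assigned between two
opposite-strand overlapping genes, so such bases conflict all the same.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

from intervaltree import IntervalTree

from .intervals import (
    GenomicInterval,
    merge_intervals,
    merge_touching,
    spans_contained,
    subtract_intervals,
)

logger = logging.getLogger(__name__)

#: minimum length of an exon fragment retained after cross-gene subtraction
MIN_RETAINED_BP = 10


@dataclass(frozen=True)
class ExonRecord:
    """One exon of one gene, in 0-based half-open coordinates."""

    interval: GenomicInterval
    gene_id: str
    exon_id: str
    source_tag: str = "primary"


@dataclass(frozen=True)
class MetaExon:
    """The interval union of a connected component of same-gene exons."""

    interval: GenomicInterval
    gene_id: str
    metaexon_id: str
    constituent_exon_ids: tuple[str, ...] = field(default_factory=tuple)

    @property
    def name(self) -> str:
        return f"{self.gene_id}:{self.metaexon_id}"


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


def parse_annotation(path: str | Path, dialect: str = "gtf") -> list[ExonRecord]:
    """Read exon features from a GTF or GFF3 file.

    Coordinates are converted from the 1-based inclusive convention of
    GTF/GFF3 to 0-based half-open. Non-exon features are ignored. Exon
    features without a gene identifier are skipped (counted and logged);
    a gene whose exons span two chromosomes is rejected outright because
    every downstream rule assumes single-chromosome genes.
    """
    import gffutils

    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"dialect must be 'gtf' or 'gff3', got {dialect!r}")
    records: list[ExonRecord] = []
    skipped_no_gene = 0
    gene_chrom: dict[str, str] = {}
    auto_ids: dict[str, int] = defaultdict(int)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") < 7:
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: expected >= 8 tab-separated fields"
                )
            try:
                feat = gffutils.feature.feature_from_line(line, dialect=None)
            except Exception as exc:  # noqa: BLE001 - rewrap with position
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: {exc}"
                ) from exc
            if feat.featuretype != "exon":
                continue
            gene_id = _gene_id_of(feat, dialect)
            if gene_id is None:
                skipped_no_gene += 1
                continue
            if gene_id in gene_chrom and gene_chrom[gene_id] != feat.seqid:
                raise AnnotationError(
                    f"{path}: line {lineno}: gene {gene_id} spans chromosomes "
                    f"{gene_chrom[gene_id]} and {feat.seqid}"
                )
            gene_chrom[gene_id] = feat.seqid
            exon_id = _first_attr(feat, "exon_id", "ID", "Name")
            if exon_id is None:
                auto_ids[gene_id] += 1
                exon_id = f"{gene_id}.exon{auto_ids[gene_id]}"
            source_tag = _first_attr(feat, "tag") or "primary"
            if feat.start is None or feat.end is None or feat.start > feat.end:
                raise AnnotationError(
                    f"{path}: malformed line {lineno}: bad coordinates"
                )
            records.append(
                ExonRecord(
                    interval=GenomicInterval(
                        chrom=feat.seqid,
                        start=feat.start - 1,  # 1-based inclusive -> 0-based half-open
                        end=feat.end,
                        strand=feat.strand if feat.strand in ("+", "-") else "+",
                    ),
                    gene_id=gene_id,
                    exon_id=exon_id,
                    source_tag=source_tag,
                )
            )
    if skipped_no_gene:
        logger.warning(
            "%s: skipped %d exon feature(s) without a gene identifier",
            path,
            skipped_no_gene,
        )
    return records


def _gene_id_of(feat, dialect: str) -> str | None:
    keys = ("gene_id",) if dialect == "gtf" else ("gene_id", "gene", "Parent")
    return _first_attr(feat, *keys)


def _first_attr(feat, *keys: str) -> str | None:
    for key in keys:
        vals = feat.attributes.get(key)
        if vals:
            return vals[0]
    return None


def deduplicate_exons(exons: Iterable[ExonRecord]) -> list[ExonRecord]:
    """Drop duplicate exon records and genes fully contained in another gene.

    A gene is removed when its exonic base set is a subset of the exonic base
    set of some *single* other gene. Two genes with identical exonic
    footprints mutually contain each other; the one with the
    lexicographically later gene_id is removed (deterministic tie-break).
    """
    seen: set[tuple[str, int, int, str, str]] = set()
    unique: list[ExonRecord] = []
    for rec in exons:
        key = (
            rec.interval.chrom,
            rec.interval.start,
            rec.interval.end,
            rec.interval.strand,
            rec.gene_id,
        )
        if key in seen:
            continue
        seen.add(key)
        unique.append(rec)

    # merged exonic footprint per gene, per chromosome
    gene_spans: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    by_gene: dict[str, list[ExonRecord]] = defaultdict(list)
    for rec in unique:
        by_gene[rec.gene_id].append(rec)
    for gid, recs in by_gene.items():
        chrom = recs[0].interval.chrom
        gene_spans[gid] = (
            chrom,
            merge_touching((r.interval.start, r.interval.end) for r in recs),
        )

    removed: set[str] = set()
    genes = sorted(gene_spans)
    for g in genes:
        g_chrom, g_sp = gene_spans[g]
        for h in genes:
            if h == g:
                continue
            h_chrom, h_sp = gene_spans[h]
            if h_chrom != g_chrom:
                continue
            if not spans_contained(g_sp, h_sp):
                continue
            identical = spans_contained(h_sp, g_sp)
            if identical and g < h:
                continue  # mutual containment: keep the earlier id
            removed.add(g)
            break
    if removed:
        logger.info("removed %d fully-overlapping gene(s): %s",
                    len(removed), ", ".join(sorted(removed)))
    return [r for r in unique if r.gene_id not in removed]


def resolve_cross_gene_overlaps(exons: Iterable[ExonRecord]) -> list[ExonRecord]:
    """Subtract other-gene exonic bases from every exon; keep >=10 bp remnants.

    Each maximal surviving sub-interval of an exon becomes its own record
    (suffix ``.p<k>`` on the exon_id when an exon splits); sub-intervals
    shorter than ``MIN_RETAINED_BP`` and exons fully covered by other-gene
    overlap are dropped. Afterwards no base belongs to two genes.
    """
    exons = list(exons)
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for rec in exons:
        trees[rec.interval.chrom].addi(rec.interval.start, rec.interval.end, rec.gene_id)

    out: list[ExonRecord] = []
    for rec in exons:
        iv = rec.interval
        holes = [
            (max(h.begin, iv.start), min(h.end, iv.end))
            for h in trees[iv.chrom].overlap(iv.start, iv.end)
            if h.data != rec.gene_id
        ]
        if not holes:
            out.append(rec)
            continue
        pieces = [
            (s, e)
            for s, e in subtract_intervals((iv.start, iv.end), holes)
            if e - s >= MIN_RETAINED_BP
        ]
        if len(pieces) == 1:
            s, e = pieces[0]
            out.append(replace(rec, interval=replace(iv, start=s, end=e)))
        else:
            for k, (s, e) in enumerate(pieces, start=1):
                out.append(
                    replace(
                        rec,
                        interval=replace(iv, start=s, end=e),
                        exon_id=f"{rec.exon_id}.p{k}",
                    )
                )
    return out


def collapse_metaexons(exons: Iterable[ExonRecord]) -> list[MetaExon]:
    """Collapse same-gene exons sharing >= 1 base into metaexons.

    Output is sorted by (chrom, start); metaexon ids are assigned per gene
    in coordinate order (``me1``, ``me2``, ...).
    """
    by_gene: dict[str, list[ExonRecord]] = defaultdict(list)
    for rec in exons:
        by_gene[rec.gene_id].append(rec)

    metaexons: list[MetaExon] = []
    for gid, recs in by_gene.items():
        recs = sorted(recs, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end))
        # connected components under ">= 1 shared base" on one chromosome
        components: list[list[ExonRecord]] = []
        cur: list[ExonRecord] = []
        cur_end = -1
        cur_chrom = None
        for rec in recs:
            if cur and rec.interval.chrom == cur_chrom and rec.interval.start < cur_end:
                cur.append(rec)
                cur_end = max(cur_end, rec.interval.end)
            else:
                if cur:
                    components.append(cur)
                cur = [rec]
                cur_chrom = rec.interval.chrom
                cur_end = rec.interval.end
        if cur:
            components.append(cur)
        for k, comp in enumerate(components, start=1):
            start = min(r.interval.start for r in comp)
            end = max(r.interval.end for r in comp)
            metaexons.append(
                MetaExon(
                    interval=GenomicInterval(
                        chrom=comp[0].interval.chrom,
                        start=start,
                        end=end,
                        strand=comp[0].interval.strand,
                    ),
                    gene_id=gid,
                    metaexon_id=f"me{k}",
                    constituent_exon_ids=tuple(r.exon_id for r in comp),
                )
            )
    metaexons.sort(key=lambda m: (m.interval.chrom, m.interval.start, m.interval.end, m.gene_id))
    return metaexons


def condense(exons: Iterable[ExonRecord]) -> list[MetaExon]:
    """Run the full pipeline: dedupe -> contained-gene removal -> cross-gene
    resolution -> same-gene collapse."""
    return collapse_metaexons(resolve_cross_gene_overlaps(deduplicate_exons(exons)))


def write_bed(metaexons: Iterable[MetaExon], path: str | Path) -> None:
    """BED6: chrom, start, end, gene_id:metaexon_id, score 0, strand."""
    with open(path, "w") as fh:
        for m in metaexons:
            fh.write(
                f"{m.interval.chrom}\t{m.interval.start}\t{m.interval.end}"
                f"\t{m.name}\t0\t{m.interval.strand}\n"
            )


def write_tsv(metaexons: Iterable[MetaExon], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tmetaexon_id\tchrom\tstart\tend\tstrand\tn_constituents\n")
        for m in metaexons:
            fh.write(
                f"{m.gene_id}\t{m.metaexon_id}\t{m.interval.chrom}\t{m.interval.start}"
                f"\t{m.interval.end}\t{m.interval.strand}\t{len(m.constituent_exon_ids)}\n"
            )


def read_metaexon_tsv(path: str | Path) -> list[MetaExon]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [
        MetaExon(
            interval=GenomicInterval(
                chrom=str(r.chrom), start=int(r.start), end=int(r.end), strand=str(r.strand)
            ),
            gene_id=str(r.gene_id),
            metaexon_id=str(r.metaexon_id),
        )
        for r in df.itertuples()
    ]
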