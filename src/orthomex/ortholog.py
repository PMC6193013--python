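"""Filter cross-species alignment hits into a 1:1 orthologous exon database.

Metaexon sequences from one genome (the "source", human in the motivating
study) are aligned against a second genome (the "target", chimpanzee);
the hits are filtered to a confident 1:1 set by five rules applied in order:

1. drop hits containing any single insertion/deletion event larger than
   25 bp (``filter_indels``);
2. drop a query outright when it has multiple possible mappings — two or
   more hits to distinct (non-overlapping) target locations, each with
   sequence identity above 0.90 (``remove_ambiguous``);
3. keep the highest-identity hit per query (``select_best_identity``);
4. require the reciprocal round trip — the target sequence's best hit back
   in the source genome must overlap the original metaexon, and its best
   hit back in the target genome must overlap the original target locus,
   each by at least half of the shorter interval (``reciprocal_check``);
5. drop all members of any group of surviving pairs whose target intervals
   overlap — different source exons claiming one target location
   (``remove_collisions``).

Sequence identity is matches / (matches + mismatches); gap columns do not
enter the denominator. The per-gene "orthologous length" recorded in the
final database is the summed length of the gene's surviving metaexon
intervals, per species — the length denominator for RPKM downstream.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

MAX_INDEL_BP = 25
AMBIGUITY_IDENTITY = 0.90
RECIPROCAL_OVERLAP_FRAC = 0.5


class PSLError(ValueError):
    """Raised for structurally invalid PSL lines."""


@dataclass(frozen=True)
class AlignmentHit:
    """One alignment record (one PSL line).

    ``query_interval`` is in query-sequence-local coordinates (the PSL
    qStart/qEnd); ``target_interval`` is genomic. ``max_indel`` is the
    largest *single* gap event between consecutive aligned blocks, on
    either side of the alignment — not the total gapped bases.
    """

    query_id: str
    query_interval: GenomicInterval
    target_interval: GenomicInterval
    strand: str
    matches: int
    mismatches: int
    q_gap_bases: int
    t_gap_bases: int
    max_indel: int

    @property
    def identity(self) -> float:
        return self.matches / (self.matches + self.mismatches)


@dataclass(frozen=True)
class OrthologyPair:
    """One surviving metaexon with its location in both genomes."""

    gene_id: str
    metaexon_id: str
    source_interval: GenomicInterval
    target_interval: GenomicInterval
    identity_fwd: float
    identity_rev: float


@dataclass
class OrthoExonDB:
    """The 1:1 orthologous exon database plus per-species gene lengths."""

    pairs: list[OrthologyPair] = field(default_factory=list)
    gene_lengths: dict[str, dict[str, int]] = field(default_factory=dict)
    # keys of gene_lengths[gene_id]: "source", "target"


def parse_psl(path: str | Path) -> list[AlignmentHit]:
    """Parse a 21-column PSL file (with or without the 5-line header).

    Coordinates stay 0-based half-open (PSL's native convention).
    ``max_indel`` is computed from blockSizes/qStarts/tStarts as the largest
    gap between consecutive blocks on the query or target side.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            first = line.split("\t", 1)[0]
            if not first or not first[0].isdigit():
                continue  # header / separator lines
            fields = line.split("\t")
            if len(fields) < 21:
                raise PSLError(f"{path}: line {lineno}: expected 21 fields, got {len(fields)}")
            try:
                hits.append(_hit_from_fields(fields))
            except PSLError as exc:
                raise PSLError(f"{path}: line {lineno}: {exc}") from None
            except (ValueError, IndexError) as exc:
                raise PSLError(f"{path}: line {lineno}: {exc}") from None
    return hits


def _hit_from_fields(f: list[str]) -> AlignmentHit:
    matches, mismatches, rep_matches = int(f[0]), int(f[1]), int(f[2])
    q_gap_bases, t_gap_bases = int(f[5]), int(f[7])
    strand = f[8]
    q_name, q_start, q_end = f[9], int(f[11]), int(f[12])
    t_name, t_start, t_end = f[13], int(f[15]), int(f[16])
    block_count = int(f[17])
    block_sizes = _int_list(f[18])
    q_starts = _int_list(f[19])
    t_starts = _int_list(f[20])
    if not (len(block_sizes) == len(q_starts) == len(t_starts) == block_count):
        raise PSLError(
            f"block count {block_count} does not match block lists "
            f"({len(block_sizes)}/{len(q_starts)}/{len(t_starts)})"
        )
    max_indel = 0
    for i in range(block_count - 1):
        q_gap = q_starts[i + 1] - (q_starts[i] + block_sizes[i])
        t_gap = t_starts[i + 1] - (t_starts[i] + block_sizes[i])
        max_indel = max(max_indel, q_gap, t_gap)
    return AlignmentHit(
        query_id=q_name,
        query_interval=GenomicInterval(q_name, q_start, q_end),
        target_interval=GenomicInterval(
            t_name, t_start, t_end, strand="-" if strand.startswith("-") else "+"
        ),
        strand=strand,
        matches=matches + rep_matches,
        mismatches=mismatches,
        q_gap_bases=q_gap_bases,
        t_gap_bases=t_gap_bases,
        max_indel=max_indel,
    )


def _int_list(s: str) -> list[int]:
    return [int(x) for x in s.rstrip(",").split(",") if x != ""]


def filter_indels(
    hits: Iterable[AlignmentHit], max_allowed: int = MAX_INDEL_BP
) -> list[AlignmentHit]:
    """Remove hits containing any single gap event larger than ``max_allowed``
    bases; a gap of exactly ``max_allowed`` is retained."""
    return [h for h in hits if h.max_indel <= max_allowed]


def select_best_identity(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """Highest-identity hit per query.

    Ties are broken deterministically by (target chrom, target start, target
    end) and logged: a tie means the alignment cannot distinguish two loci
    at the recorded precision.
    """
    by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    best: dict[str, AlignmentHit] = {}
    for qid, cand in by_query.items():
        cand.sort(
            key=lambda h: (
                -h.identity,
                h.target_interval.chrom,
                h.target_interval.start,
                h.target_interval.end,
            )
        )
        if len(cand) > 1 and cand[0].identity == cand[1].identity:
            logger.info("identity tie for query %s; kept %s:%d",
                        qid, cand[0].target_interval.chrom, cand[0].target_interval.start)
        best[qid] = cand[0]
    return best


def remove_ambiguous(
    hits: Iterable[AlignmentHit], identity_floor: float = AMBIGUITY_IDENTITY
) -> set[str]:
    """Queries that survive the multi-mapping rule.

    A query is discarded entirely when it has hits to two or more distinct
    target locations each with identity strictly above ``identity_floor``.
    Hits whose target intervals overlap count as one location.
    """
    by_query: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    surviving: set[str] = set()
    for qid, cand in by_query.items():
        high = [h for h in cand if h.identity > identity_floor]
        if _n_distinct_locations(high) >= 2:
            logger.info("query %s removed: %d high-identity mappings", qid, len(high))
            continue
        surviving.add(qid)
    return surviving


def _n_distinct_locations(hits: list[AlignmentHit]) -> int:
    ivs = sorted(
        (h.target_interval.chrom, h.target_interval.start, h.target_interval.end)
        for h in hits
    )
    n = 0
    cur_chrom, cur_end = None, -1
    for chrom, start, end in ivs:
        if chrom != cur_chrom or start >= cur_end:
            n += 1
            cur_chrom, cur_end = chrom, end
        else:
            cur_end = max(cur_end, end)
    return n


def _overlap_ok(a: GenomicInterval, b: GenomicInterval, min_frac: float) -> bool:
    shorter = min(a.length, b.length)
    return a.overlap_length(b) >= min_frac * shorter


def reciprocal_check(
    forward_best: Mapping[str, AlignmentHit],
    reverse_hits: Iterable[AlignmentHit],
    reverse_back_hits: Iterable[AlignmentHit],
    query_locations: Mapping[str, GenomicInterval],
    min_overlap_frac: float = RECIPROCAL_OVERLAP_FRAC,
    max_indel: int = MAX_INDEL_BP,
) -> dict[str, AlignmentHit]:
    """Keep queries whose target sequence maps back to its original loci.

    ``reverse_hits`` align the target-genome sequence of each forward best
    hit against the source genome; ``reverse_back_hits`` align it back
    against the target genome. Both are subjected to the same indel filter
    and best-identity selection as the forward direction. A query survives
    iff its best reverse hit overlaps the original source metaexon
    (``query_locations``) and its best back-hit overlaps the forward target
    locus, each by at least ``min_overlap_frac`` of the shorter interval.
    A missing reverse or back hit counts as a reciprocal failure.
    """
    rev_best = select_best_identity(filter_indels(reverse_hits, max_indel))
    back_best = select_best_identity(filter_indels(reverse_back_hits, max_indel))
    out: dict[str, AlignmentHit] = {}
    for qid, fwd in forward_best.items():
        origin = query_locations.get(qid)
        rev = rev_best.get(qid)
        back = back_best.get(qid)
        if origin is None or rev is None or back is None:
            logger.info("query %s removed: missing reverse/back hit", qid)
            continue
        if not _overlap_ok(rev.target_interval, origin, min_overlap_frac):
            logger.info("query %s removed: reverse hit off-target", qid)
            continue
        if not _overlap_ok(back.target_interval, fwd.target_interval, min_overlap_frac):
            logger.info("query %s removed: back hit off-target", qid)
            continue
        out[qid] = fwd
    return out


def remove_collisions(pairs: Iterable[OrthologyPair]) -> list[OrthologyPair]:
    """Drop every member of any group of pairs with overlapping target intervals.

    Two different source exons mapping to one target location cannot both be
    1:1 orthologs; neither can be trusted, so the whole group is removed.
    """
    pairs = list(pairs)
    order = sorted(
        range(len(pairs)),
        key=lambda i: (
            pairs[i].target_interval.chrom,
            pairs[i].target_interval.start,
            pairs[i].target_interval.end,
        ),
    )
    colliding: set[int] = set()
    cluster = []
    cluster_end = -1
    cluster_chrom = None
    for i in order:
        iv = pairs[i].target_interval
        if cluster and iv.chrom == cluster_chrom and iv.start < cluster_end:
            cluster.append(i)
            cluster_end = max(cluster_end, iv.end)
        else:
            if len(cluster) > 1:
                colliding.update(cluster)
            cluster = [i]
            cluster_chrom = iv.chrom
            cluster_end = iv.end
    if len(cluster) > 1:
        colliding.update(cluster)
    if colliding:
        logger.info("removed %d pair(s) in target-location collisions", len(colliding))
    return [p for i, p in enumerate(pairs) if i not in colliding]


def build_database(pairs: Iterable[OrthologyPair]) -> OrthoExonDB:
    """Assemble the final database with per-species orthologous gene lengths."""
    db = OrthoExonDB(pairs=sorted(
        pairs,
        key=lambda p: (p.source_interval.chrom, p.source_interval.start, p.metaexon_id),
    ))
    for p in db.pairs:
        lens = db.gene_lengths.setdefault(p.gene_id, {"source": 0, "target": 0})
        lens["source"] += p.source_interval.length
        lens["target"] += p.target_interval.length
    return db


def orthologize(
    metaexons: Mapping[str, tuple[str, GenomicInterval]],
    forward_hits: Iterable[AlignmentHit],
    reverse_hits: Iterable[AlignmentHit],
    back_hits: Iterable[AlignmentHit],
    max_indel: int = MAX_INDEL_BP,
    ambiguity_identity: float = AMBIGUITY_IDENTITY,
    reciprocal_overlap: float = RECIPROCAL_OVERLAP_FRAC,
) -> OrthoExonDB:
    """Full filtering pipeline from raw hits to the orthologous exon database.

    ``metaexons`` maps each query (metaexon) id to (gene_id, source genomic
    interval). Ambiguity is judged on the indel-filtered hit list *before*
    best-hit selection in both the forward and reverse directions: a query
    with several plausible homes is removed even though one of them would
    have won the argmax.
    """
    fwd = filter_indels(forward_hits, max_indel)
    rev = filter_indels(reverse_hits, max_indel)
    unambiguous_fwd = remove_ambiguous(fwd, ambiguity_identity)
    unambiguous_rev = remove_ambiguous(rev, ambiguity_identity)
    rev_qids = {h.query_id for h in rev}
    fwd = [h for h in fwd if h.query_id in unambiguous_fwd and h.query_id in metaexons]
    # a query ambiguous on the way back is just as untrustworthy
    fwd = [h for h in fwd if h.query_id in unambiguous_rev or h.query_id not in rev_qids]
    best = select_best_identity(fwd)
    locations = {qid: iv for qid, (gid, iv) in metaexons.items()}
    reciprocal = reciprocal_check(
        best, rev, back_hits, locations,
        min_overlap_frac=reciprocal_overlap, max_indel=max_indel,
    )
    rev_best = select_best_identity(filter_indels(reverse_hits, max_indel))
    pairs = []
    for qid, hit in reciprocal.items():
        gene_id, source_iv = metaexons[qid]
        rb = rev_best.get(qid)
        pairs.append(
            OrthologyPair(
                gene_id=gene_id,
                metaexon_id=qid,
                source_interval=source_iv,
                target_interval=hit.target_interval,
                identity_fwd=hit.identity,
                identity_rev=rb.identity if rb is not None else float("nan"),
            )
        )
    return build_database(remove_collisions(pairs))


def write_database(db: OrthoExonDB, prefix: str | Path) -> None:
    """Write the pair table, per-species BEDs and the gene-length table."""
    prefix = str(prefix)
    with open(prefix + ".pairs.tsv", "w") as fh:
        fh.write(
            "gene_id\tmetaexon_id\tsource_chrom\tsource_start\tsource_end\tsource_strand"
            "\ttarget_chrom\ttarget_start\ttarget_end\ttarget_strand"
            "\tidentity_fwd\tidentity_rev\n"
        )
        for p in db.pairs:
            s, t = p.source_interval, p.target_interval
            fh.write(
                f"{p.gene_id}\t{p.metaexon_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.strand}"
                f"\t{t.chrom}\t{t.start}\t{t.end}\t{t.strand}"
                f"\t{p.identity_fwd:.6f}\t{p.identity_rev:.6f}\n"
            )
    for side in ("source", "target"):
        with open(f"{prefix}.{side}.bed", "w") as fh:
            for p in db.pairs:
                iv = p.source_interval if side == "source" else p.target_interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.gene_id}:{p.metaexon_id}\t0\t{iv.strand}\n")
    with open(prefix + ".gene_lengths.tsv", "w") as fh:
        fh.write("gene_id\tsource_length\ttarget_length\n")
        for gid in sorted(db.gene_lengths):
            lens = db.gene_lengths[gid]
            fh.write(f"{gid}\t{lens['source']}\t{lens['target']}\n")
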