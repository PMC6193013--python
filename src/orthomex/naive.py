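"""Per-base reference implementations used to validate the fast interval code.

Everything here works on explicit boolean base masks over a small genome and
is deliberately written in the most literal way possible: it serves as an
independent oracle for the condensation pipeline and must stay structurally
unrelated to the sweep/tree algorithms in :mod:`orthomex.annotation`.
Only suitable for genomes of a few tens of kilobases.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .annotation import ExonRecord, MIN_RETAINED_BP


def _gene_masks(
    exons: list[ExonRecord], genome_len: int
) -> dict[tuple[str, str], np.ndarray]:
    """Boolean exonic-base mask per (chrom, gene)."""
    masks: dict[tuple[str, str], np.ndarray] = {}
    for rec in exons:
        key = (rec.interval.chrom, rec.gene_id)
        if key not in masks:
            masks[key] = np.zeros(genome_len, dtype=bool)
        masks[key][rec.interval.start : rec.interval.end] = True
    return masks


def naive_dedup(exons: list[ExonRecord], genome_len: int) -> list[ExonRecord]:
    seen = set()
    unique = []
    for rec in exons:
        key = (rec.interval.chrom, rec.interval.start, rec.interval.end,
               rec.interval.strand, rec.gene_id)
        if key not in seen:
            seen.add(key)
            unique.append(rec)
    masks = _gene_masks(unique, genome_len)
    genes_by_chrom: dict[str, list[str]] = defaultdict(list)
    for chrom, gid in masks:
        genes_by_chrom[chrom].append(gid)
    removed = set()
    for chrom, gids in genes_by_chrom.items():
        for g in gids:
            for h in gids:
                if h == g:
                    continue
                mg, mh = masks[(chrom, g)], masks[(chrom, h)]
                if not (mg & ~mh).any():  # g's bases all inside h's
                    if not (mh & ~mg).any() and g < h:
                        continue  # identical footprints: keep earlier id
                    removed.add(g)
                    break
    return [r for r in unique if r.gene_id not in removed]


def naive_resolve(exons: list[ExonRecord], genome_len: int) -> list[ExonRecord]:
    """Per-base cross-gene subtraction with the 10 bp run-length rule."""
    masks = _gene_masks(exons, genome_len)
    out = []
    for rec in exons:
        chrom = rec.interval.chrom
        other = np.zeros(genome_len, dtype=bool)
        for (c, gid), m in masks.items():
            if c == chrom and gid != rec.gene_id:
                other |= m
        keep = np.zeros(genome_len, dtype=bool)
        keep[rec.interval.start : rec.interval.end] = True
        if not (keep & other).any():
            out.append(rec)  # untouched exon: the length rule does not apply
            continue
        keep &= ~other
        # maximal runs of kept bases
        idx = np.flatnonzero(keep)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([idx[0]], idx[breaks + 1]))
        ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
        pieces = [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= MIN_RETAINED_BP]
        for k, (s, e) in enumerate(pieces, start=1):
            from dataclasses import replace

            exon_id = rec.exon_id if len(pieces) == 1 else f"{rec.exon_id}.p{k}"
            out.append(
                replace(rec, interval=replace(rec.interval, start=s, end=e), exon_id=exon_id)
            )
    return out


def ownership_mask(
    exons: list[ExonRecord], genome_len: int, chroms: list[str]
) -> dict[str, np.ndarray]:
    """Per-chromosome array of gene ownership per base ('' = unowned).

    Collapsing same-gene exons into metaexons does not change base ownership,
    so this mask is the collapse-invariant fingerprint of the pipeline.
    """
    out = {c: np.full(genome_len, "", dtype=object) for c in chroms}
    for rec in exons:
        arr = out[rec.interval.chrom]
        span = arr[rec.interval.start : rec.interval.end]
        claimed = (span != "") & (span != rec.gene_id)
        if claimed.any():
            raise AssertionError(
                f"base owned by two genes: {rec.gene_id} vs {span[claimed][0]}"
            )
        arr[rec.interval.start : rec.interval.end] = rec.gene_id
    return out


def naive_condense_mask(
    exons: list[ExonRecord], genome_len: int
) -> dict[str, np.ndarray]:
    """Gene-ownership mask after the dedupe -> resolve sequence, per base."""
    chroms = sorted({r.interval.chrom for r in exons})
    resolved = naive_resolve(naive_dedup(exons, genome_len), genome_len)
    return ownership_mask(resolved, genome_len, chroms)


def naive_bh(pvals: np.ndarray) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up: adj_i = min over j>=i of m*p_(j)/j."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = min(1.0, running)
    return adj
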