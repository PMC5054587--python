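"""Small-RNA tag filtering, genome placement, and genic annotation.

Tags (distinct sequences with per-sample read counts) are kept when 18-25 nt
long and seen at least five times in some sample, placed on both genome
strands allowing up to two substitutions plus at most one 1-2 nt microindel,
and classified against gene models extended 500 bp each side.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import encode, revcomp

FEATURE_CLASSES = ("gene_body", "utr5", "utr3", "upstream", "downstream", "intergenic")


@dataclass
class SmallRnaTag:
    """A distinct small-RNA sequence with per-sample read counts."""

    sequence: str
    counts: dict[str, int]

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def max_count(self) -> int:
        return max(self.counts.values(), default=0)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SrnaAlignment:
    """One genomic placement of a tag.

    ``start``/``span`` are on the forward strand of ``contig_id``; for a
    minus-strand placement the tag's reverse complement matches the forward
    genome.  ``indel_len`` > 0 means the placement contains one microindel
    (span differs from the tag length by that many bases).
    """

    tag: SmallRnaTag
    contig_id: str
    start: int
    span: int
    strand: str
    mismatches: int
    indel_len: int

    @property
    def end(self) -> int:
        return self.start + self.span

    @property
    def five_prime_pos(self) -> int:
        """Genomic coordinate of the tag's 5'-most base."""
        return self.start if self.strand == "+" else self.end - 1


def filter_tags(tags: Iterable[SmallRnaTag], config) -> list[SmallRnaTag]:
    """Keep tags with length in [sr_len_min, sr_len_max] and adequate support.

    Support means the maximum per-sample count reaches ``min_tag_count``
    (strictly exceeds it when ``tag_count_strict`` is set, matching the
    alternative "more than five times" reading).
    """
    strict = getattr(config, "tag_count_strict", False)
    out = []
    for tag in tags:
        if not (config.sr_len_min <= tag.length <= config.sr_len_max):
            continue
        m = tag.max_count
        if (m > config.min_tag_count) if strict else (m >= config.min_tag_count):
            out.append(tag)
    return out


# ---------------------------------------------------------------------------
# alignment


def _scan(t: np.ndarray, g: np.ndarray, max_mm: int, max_indel: int) -> dict:
    """All placements of encoded tag ``t`` on encoded forward genome ``g``.

    Returns {(start, span): (mismatches, indel_len)} for every placement
    with <= max_mm substitutions and one optional gap of 1..max_indel nt on
    either side (terminal gaps excluded).  For each (start, span) the
    minimal (mismatch, indel) combination is kept.
    """
    L, n = len(t), len(g)
    results: dict[tuple[int, int], tuple[int, int]] = {}
    if L <= n:
        mm = (sliding_window_view(g, L) != t).sum(axis=1)
        for s in np.flatnonzero(mm <= max_mm):
            results[(int(s), L)] = (int(mm[s]), 0)
    for gap in range(1, max_indel + 1):
        # gap in the tag relative to the genome: genome span L + gap
        span = L + gap
        if span <= n:
            W = sliding_window_view(g, span)
            precum = np.cumsum(W[:, :L] != t, axis=1, dtype=np.int16)
            suf = W[:, gap:] != t
            sufcum = np.cumsum(suf[:, ::-1], axis=1, dtype=np.int16)[:, ::-1]
            tot = precum[:, 0 : L - 1] + sufcum[:, 1:L]
            best = tot.min(axis=1)
            for s in np.flatnonzero(best <= max_mm):
                key = (int(s), span)
                cand = (int(best[s]), gap)
                if key not in results or cand < results[key]:
                    results[key] = cand
        # gap in the genome relative to the tag: genome span L - gap
        span = L - gap
        if 2 <= span <= n:
            W = sliding_window_view(g, span)
            precum = np.cumsum(W != t[:span], axis=1, dtype=np.int16)
            suf = W != t[gap:]
            sufcum = np.cumsum(suf[:, ::-1], axis=1, dtype=np.int16)[:, ::-1]
            tot = precum[:, 0 : span - 1] + sufcum[:, 1:span]
            best = tot.min(axis=1)
            for s in np.flatnonzero(best <= max_mm):
                key = (int(s), span)
                cand = (int(best[s]), gap)
                if key not in results or cand < results[key]:
                    results[key] = cand
    return results


def align_tags(
    tags: Iterable[SmallRnaTag], contigs, config
) -> list[SrnaAlignment]:
    """Place each tag on both strands of every contig.

    All qualifying placements are reported (the study allowed multi-locus
    alignment); an N in the genome never matches any tag base.
    """
    genome = {c.id: encode(c.sequence) for c in contigs}
    out: list[SrnaAlignment] = []
    for tag in tags:
        fwd = encode(tag.sequence)
        rev = encode(revcomp(tag.sequence))
        for cid, g in genome.items():
            for strand, arr in (("+", fwd), ("-", rev)):
                for (start, span), (mm, indel) in sorted(
                    _scan(arr, g, config.sr_max_mm, config.sr_indel_max).items()
                ):
                    out.append(
                        SrnaAlignment(tag, cid, start, span, strand, mm, indel)
                    )
    return out


def align_perfect(tags: Iterable[SmallRnaTag], contigs) -> list[SrnaAlignment]:
    """Fast exact-match placement (0 mismatches, no indel) on both strands."""
    out: list[SrnaAlignment] = []
    for tag in tags:
        for cid, seq in ((c.id, c.sequence) for c in contigs):
            for strand, query in (("+", tag.sequence), ("-", revcomp(tag.sequence))):
                start = seq.find(query)
                while start != -1:
                    out.append(SrnaAlignment(tag, cid, start, len(query), strand, 0, 0))
                    start = seq.find(query, start + 1)
    return out


# ---------------------------------------------------------------------------
# genic annotation


def _class_within(pos: int, gene) -> str:
    b0, b1 = gene.body
    if b0 <= pos < b1:
        return "gene_body"
    for s, e in gene.utr5_intervals:
        if s <= pos < e:
            return "utr5"
    for s, e in gene.utr3_intervals:
        if s <= pos < e:
            return "utr3"
    s0, s1 = gene.span
    if s0 <= pos < s1:
        # a gap inside the span not covered by CDS/UTR rows; treat as body
        return "gene_body"
    if pos < s0:
        return "upstream" if gene.strand == "+" else "downstream"
    return "downstream" if gene.strand == "+" else "upstream"


def annotate_alignments(
    alignments: Sequence[SrnaAlignment],
    genes,
    contig_lengths: Mapping[str, int],
    config,
    unique_gene: bool = False,
) -> pd.DataFrame:
    """Assign each placement (by its 5'-most base) to genes and feature classes.

    A placement inside a gene's extended region is classified with precedence
    gene body > UTR > flank; a placement overlapping several genes' regions
    is counted for each (``ambiguous``) unless ``unique_gene`` drops it.
    Placements outside every extended region are intergenic.  Counts are
    read-weighted per sample.  Returns a tidy frame with columns
    gene_id, feature_class, sample, count, ambiguous.
    """
    flank = config.flank
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    gene_by_id = {g.id: g for g in genes}
    for g in genes:
        s, e = g.span
        clen = contig_lengths[g.contig_id]
        trees[g.contig_id].addi(max(0, s - flank), min(clen, e + flank), g.id)

    rows: dict[tuple[str | None, str, str, bool], int] = defaultdict(int)
    for aln in alignments:
        pos = aln.five_prime_pos
        hits = trees[aln.contig_id][pos] if aln.contig_id in trees else set()
        if not hits:
            for sample, n in aln.tag.counts.items():
                if n:
                    rows[(None, "intergenic", sample, False)] += n
            continue
        ambiguous = len(hits) > 1
        if ambiguous and unique_gene:
            continue
        for hit in hits:
            gene = gene_by_id[hit.data]
            cls = _class_within(pos, gene)
            for sample, n in aln.tag.counts.items():
                if n:
                    rows[(gene.id, cls, sample, ambiguous)] += n
    df = pd.DataFrame(
        [
            {"gene_id": g, "feature_class": c, "sample": s, "count": n, "ambiguous": a}
            for (g, c, s, a), n in rows.items()
        ],
        columns=["gene_id", "feature_class", "sample", "count", "ambiguous"],
    )
    return df.sort_values(
        ["gene_id", "feature_class", "sample"], ignore_index=True, na_position="last"
    )


def gene_counts(annotation: pd.DataFrame, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene x sample read counts over the extended region (all classes)."""
    genic = annotation[annotation["gene_id"].notna()]
    table = (
        genic.pivot_table(
            index="gene_id", columns="sample", values="count", aggfunc="sum", fill_value=0
        )
        .astype(np.int64)
    )
    if samples is not None:
        table = table.reindex(columns=list(samples), fill_value=0)
    table.columns.name = None
    return table


def length_distribution(
    tags: Iterable[SmallRnaTag],
    samples: Sequence[str],
    length_range: tuple[int, int] = (18, 25),
) -> pd.DataFrame:
    """Per-sample read-weighted counts per tag length (bins sum to totals)."""
    lo, hi = length_range
    idx = range(lo, hi + 1)
    hist = pd.DataFrame(0, index=idx, columns=list(samples), dtype=np.int64)
    for tag in tags:
        if lo <= tag.length <= hi:
            for s, n in tag.counts.items():
                if s in hist.columns:
                    hist.loc[tag.length, s] += n
    hist.index.name = "length"
    return hist
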