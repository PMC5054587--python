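"""Known-miRNA annotation and MIRNA-locus prediction from tag pairs.

A candidate MIRNA locus is a pair of distinct tags perfectly aligned to the
same contig and strand within 400 bp of each other, between which the
genomic sequence could fold into a hairpin: the two arms must be largely
complementary (Watson-Crick plus G:U wobble), and a maximum-base-pairing
fold of the putative precursor (Nussinov recursion, minimum loop 3 nt) must
pair the arms predominantly with each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

from ._seq import normalize_rna
from .smallrna_profiler import SmallRnaTag, SrnaAlignment

# DNA-alphabet base pairs counted as paired in a duplex: Watson-Crick + G:U wobble
_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class KnownMirnaHit:
    tag: SmallRnaTag
    mirna_ids: tuple[str, ...]


@dataclass(frozen=True)
class TagPair:
    """Two distinct perfectly aligned tags on one contig/strand, left arm first."""

    left: SrnaAlignment
    right: SrnaAlignment

    @property
    def pair_distance(self) -> int:
        return abs(self.left.five_prime_pos - self.right.five_prime_pos)


@dataclass
class MirnaCandidate:
    contig_id: str
    strand: str
    mir_span: tuple[int, int]
    star_span: tuple[int, int]
    precursor_span: tuple[int, int]
    pair_distance: int
    duplex_paired_fraction: float
    arm_pair_fraction: float
    accepted: bool
    reason: str = ""


def load_mature_mirnas(path) -> dict[str, str]:
    """Read a mature-miRNA FASTA; sequences are U->T normalized."""
    return {rec.id: normalize_rna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def annotate_known(
    tags: Iterable[SmallRnaTag], mature_set: Mapping[str, str]
) -> list[KnownMirnaHit]:
    """Exact-sequence matches of tags against known mature miRNAs.

    One tag may match several reference entries; all matching ids are kept.
    """
    by_seq: dict[str, list[str]] = {}
    for mid, seq in mature_set.items():
        by_seq.setdefault(normalize_rna(seq), []).append(mid)
    hits = []
    for tag in tags:
        ids = by_seq.get(tag.sequence)
        if ids:
            hits.append(KnownMirnaHit(tag=tag, mirna_ids=tuple(sorted(ids))))
    return hits


def find_pairs(alignments: Sequence[SrnaAlignment], config) -> list[TagPair]:
    """All unordered pairs of perfect placements of distinct tags.

    Placements must share contig and strand, sit within ``pair_window`` bp
    of each other (5'-start to 5'-start, inclusive), and not overlap.
    """
    perfect = [a for a in alignments if a.mismatches == 0 and a.indel_len == 0]
    by_key: dict[tuple[str, str], list[SrnaAlignment]] = {}
    for a in perfect:
        by_key.setdefault((a.contig_id, a.strand), []).append(a)
    pairs = []
    for group in by_key.values():
        group.sort(key=lambda a: (a.start, a.span, a.tag.sequence))
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if b.start - a.five_prime_pos > config.pair_window + max(a.span, b.span):
                    break
                if a.tag.sequence == b.tag.sequence:
                    continue
                if abs(a.five_prime_pos - b.five_prime_pos) > config.pair_window:
                    continue
                if a.end > b.start and b.end > a.start:  # overlapping spans
                    continue
                left, right = (a, b) if a.start <= b.start else (b, a)
                pairs.append(TagPair(left=left, right=right))
    return pairs


# ---------------------------------------------------------------------------
# hairpin evaluation


def _duplex_fraction(arm1: str, arm2: str, max_offset: int = 2) -> float:
    """Best complementarity of arm1 against the reversed partner arm.

    The reversed arm emulates the antiparallel duplex geometry; a +-2 nt
    offset scan absorbs register shifts from imprecise arm ends.
    """
    rev2 = arm2[::-1]
    best = 0
    for off in range(-max_offset, max_offset + 1):
        paired = 0
        for i, base in enumerate(arm1):
            j = i + off
            if 0 <= j < len(rev2) and (base, rev2[j]) in _PAIRS:
                paired += 1
        best = max(best, paired)
    return best / len(arm1) if arm1 else 0.0


def _fill_py(can: np.ndarray, min_loop: int) -> np.ndarray:
    """Diagonal-wise DP fill with the bifurcation vectorized over the diagonal."""
    n = can.shape[0]
    dp = np.zeros((n, n), dtype=np.int16)
    for l in range(min_loop + 1, n):
        m_i = n - l
        i_idx = np.arange(m_i)
        j_idx = i_idx + l
        # pairing (i, j): dp[i+1][j-1] + 1
        best = np.where(can[i_idx, j_idx], dp[i_idx + 1, j_idx - 1] + 1, 0).astype(np.int16)
        # bifurcation dp[i][i+m-1] + dp[i+m][j] (m = 1..l); m=1 and m=l cover
        # leaving i or j unpaired since dp of a single base is 0
        for m in range(1, l + 1):
            cand = dp[i_idx, i_idx + m - 1] + dp[i_idx + m, j_idx]
            np.maximum(best, cand, out=best)
        dp[i_idx, j_idx] = best
    return dp


def _fill_jit_src(can, min_loop):  # pragma: no cover - jitted below when numba exists
    n = can.shape[0]
    dp = np.zeros((n, n), dtype=np.int16)
    for l in range(min_loop + 1, n):
        for i in range(n - l):
            j = i + l
            best = dp[i + 1, j - 1] + 1 if can[i, j] else 0
            for m in range(1, l + 1):
                cand = dp[i, i + m - 1] + dp[i + m, j]
                if cand > best:
                    best = cand
            dp[i, j] = best
    return dp


try:  # numba gives a ~10x faster fill; the numpy fill is the reference path
    from numba import njit

    _nussinov_fill = njit(cache=False)(_fill_jit_src)
except ImportError:  # pragma: no cover
    _nussinov_fill = _fill_py


def nussinov(seq: str, min_loop: int = 3) -> tuple[int, list[tuple[int, int]]]:
    """Maximum-base-pairing fold (Watson-Crick + G:U, nested, loop >= min_loop).

    Returns the optimal pair count and one deterministic optimal structure
    as a list of (i, j) index pairs.
    """
    n = len(seq)
    if n == 0:
        return 0, []
    from ._seq import encode

    codes = encode(seq)
    pairmat = np.zeros((4, 4), dtype=bool)
    for x, y in _PAIRS:
        pairmat["ACGT".index(x), "ACGT".index(y)] = True
    safe = np.minimum(codes, 3)
    can = pairmat[safe[:, None], safe[None, :]]
    can &= (codes < 4)[:, None] & (codes < 4)[None, :]
    i_grid, j_grid = np.ogrid[0:n, 0:n]
    can &= (j_grid - i_grid) > min_loop
    dp = _nussinov_fill(can, min_loop)

    pairs: list[tuple[int, int]] = []

    def trace(i: int, j: int) -> None:
        while i < j:
            if dp[i, j] == 0:
                return
            if can[i, j] and dp[i, j] == dp[i + 1, j - 1] + 1:
                pairs.append((i, j))
                i, j = i + 1, j - 1
                continue
            for m in range(1, j - i + 1):
                if dp[i, j] == dp[i, i + m - 1] + dp[i + m, j]:
                    trace(i, i + m - 1)
                    i = i + m
                    break
            else:  # pragma: no cover - recurrence guarantees a split exists
                return

    trace(0, n - 1)
    pairs.sort()
    return int(dp[0, n - 1]), pairs


def evaluate_hairpin(pair: TagPair, contig_seqs: Mapping[str, str], config) -> MirnaCandidate:
    """Score a tag pair as a putative miRNA/miRNA* duplex on a hairpin.

    Acceptance requires (1) an inter-arm loop of at least ``min_loop`` nt,
    (2) duplex complementarity of the left arm against the reversed right
    arm >= ``duplex_min_paired`` (G:U counted, 2-nt offset scan), and (3) a
    Nussinov maximum-pairing fold of the precursor in which cross-arm pairs
    cover >= ``duplex_min_paired`` of the shorter arm.  The left arm is
    reported as the miR arm by convention; the pair itself does not reveal
    which strand is the mature product.
    """
    a, b = pair.left, pair.right
    seq = contig_seqs[a.contig_id]
    mir_span, star_span = (a.start, a.end), (b.start, b.end)
    precursor = (a.start, b.end)
    base = dict(
        contig_id=a.contig_id,
        strand=a.strand,
        mir_span=mir_span,
        star_span=star_span,
        precursor_span=precursor,
        pair_distance=pair.pair_distance,
    )
    if a.end > b.start:
        return MirnaCandidate(
            **base, duplex_paired_fraction=0.0, arm_pair_fraction=0.0,
            accepted=False, reason="overlapping arm spans",
        )
    arm1, arm2 = seq[a.start : a.end], seq[b.start : b.end]
    duplex = _duplex_fraction(arm1, arm2)
    loop = b.start - a.end
    if loop < config.min_loop:
        return MirnaCandidate(
            **base, duplex_paired_fraction=duplex, arm_pair_fraction=0.0,
            accepted=False, reason=f"inter-arm loop {loop} < {config.min_loop}",
        )
    if duplex < config.duplex_min_paired:
        return MirnaCandidate(
            **base, duplex_paired_fraction=duplex, arm_pair_fraction=0.0,
            accepted=False, reason="duplex complementarity below threshold",
        )
    # secondary check: fold the precursor and demand cross-arm pairing
    prec_seq = seq[a.start : b.end]
    _, fold_pairs = nussinov(prec_seq, config.min_loop)
    len1, len2 = a.span, b.span
    off2 = b.start - a.start
    cross = sum(1 for i, j in fold_pairs if i < len1 and j >= off2)
    arm_frac = cross / min(len1, len2)
    accepted = arm_frac >= config.duplex_min_paired
    return MirnaCandidate(
        **base, duplex_paired_fraction=duplex, arm_pair_fraction=arm_frac,
        accepted=accepted, reason="" if accepted else "precursor fold does not pair the arms",
    )


def predict_mirna_loci(
    tags: Iterable[SmallRnaTag], contigs, config
) -> list[MirnaCandidate]:
    """End-to-end MIRNA prediction: perfect placement, pairing, hairpin check."""
    from .smallrna_profiler import align_perfect

    alignments = align_perfect(tags, contigs)
    contig_seqs = {c.id: c.sequence for c in contigs}
    return [evaluate_hairpin(p, contig_seqs, config) for p in find_pairs(alignments, config)]
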