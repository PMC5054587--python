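"""Assembly sequence-redundancy profiling via near-duplicate k-mers.

A k-mer is redundant when another k-mer at a sufficiently separated
coordinate lies within a small Hamming distance (default: 100-mers within
2 substitutions).  Exact computation uses pigeonhole partitioning: a pair
within distance d must share at least one of d+1 equal-length segments
exactly, so candidate partners are gathered from per-segment hash buckets
and verified by a direct Hamming count.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from ._seq import encode, revcomp


@dataclass
class RedundancyReport:
    k: int
    max_hamming: int
    n_kmers_sampled: int
    n_redundant: int
    n_skipped_n: int
    fraction_redundant: float
    both_strands: bool
    min_separation: int


def _collect_kmers(contigs, k: int, sample_step: int):
    """(contig index, start, encoded kmer) for all sampled N-free k-mers."""
    kmers = []
    n_skipped = 0
    for ci, contig in enumerate(contigs):
        arr = encode(contig.sequence)
        for start in range(0, len(arr) - k + 1, sample_step):
            window = arr[start : start + k]
            if (window == 255).any():
                n_skipped += 1
                continue
            kmers.append((ci, start, window))
    return kmers, n_skipped


def _segment_bounds(k: int, n_seg: int) -> list[tuple[int, int]]:
    edges = np.linspace(0, k, n_seg + 1).astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(n_seg)]


def kmer_redundancy(
    contigs,
    k: int = 100,
    max_hamming: int = 2,
    sample_step: int = 1,
    both_strands: bool = False,
    min_separation: int | None = None,
) -> RedundancyReport:
    """Fraction of sampled k-mers with a near-duplicate partner elsewhere.

    Partners on the same contig must start at least ``min_separation``
    (default ``k``, i.e. non-overlapping) bases away, suppressing the
    trivial matches between overlapping windows of a single locus; partners
    on other contigs always qualify.  ``both_strands`` additionally matches
    against reverse-complemented k-mers.  K-mers containing N are skipped
    and reported.
    """
    if sample_step < 1:
        raise ValueError("sample_step must be >= 1")
    if min_separation is None:
        min_separation = k
    for c in contigs:
        if len(c.sequence) < k:
            raise ValueError(f"contig {c.id} shorter than k={k}")

    kmers, n_skipped = _collect_kmers(contigs, k, sample_step)
    n = len(kmers)
    if n == 0:
        return RedundancyReport(k, max_hamming, 0, 0, n_skipped, 0.0, both_strands, min_separation)

    mat = np.stack([km for _, _, km in kmers])
    coords = [(ci, start) for ci, start, _ in kmers]
    variants = [(0, mat)]
    if both_strands:
        # reverse complement: complement of codes 0..3 is 3 - code
        variants.append((1, (3 - mat[:, ::-1]).astype(np.uint8)))

    n_seg = max_hamming + 1
    bounds = _segment_bounds(k, n_seg)

    def separated(i: int, j: int) -> bool:
        (ci, si), (cj, sj) = coords[i], coords[j]
        return ci != cj or abs(si - sj) >= min_separation

    redundant = np.zeros(n, dtype=bool)
    for si_, (lo, hi) in enumerate(bounds):
        buckets: dict[bytes, list[tuple[int, int]]] = defaultdict(list)
        for orient, vm in variants:
            segs = vm[:, lo:hi]
            for idx in range(n):
                buckets[segs[idx].tobytes()].append((orient, idx))
        for members in buckets.values():
            if len(members) < 2:
                continue
            for x in range(len(members)):
                ox, ix = members[x]
                if ox != 0:
                    continue  # only forward k-mers are the query side
                if redundant[ix]:
                    continue
                for oy, iy in members:
                    if iy == ix:
                        continue  # same coordinate is never a partner
                    if not separated(ix, iy):
                        continue
                    target = mat[iy] if oy == 0 else (3 - mat[iy][::-1]).astype(np.uint8)
                    if int((mat[ix] != target).sum()) <= max_hamming:
                        redundant[ix] = True
                        break
    n_red = int(redundant.sum())
    return RedundancyReport(
        k=k,
        max_hamming=max_hamming,
        n_kmers_sampled=n,
        n_redundant=n_red,
        n_skipped_n=n_skipped,
        fraction_redundant=n_red / n,
        both_strands=both_strands,
        min_separation=min_separation,
    )


def kmer_redundancy_bruteforce(
    contigs,
    k: int = 100,
    max_hamming: int = 2,
    sample_step: int = 1,
    both_strands: bool = False,
    min_separation: int | None = None,
) -> RedundancyReport:
    """All-pairs Hamming scan; independent reference for small inputs."""
    if min_separation is None:
        min_separation = k
    kmers, n_skipped = _collect_kmers(contigs, k, sample_step)
    n = len(kmers)
    redundant = np.zeros(n, dtype=bool)
    for i in range(n):
        ci, si, wi = kmers[i]
        for j in range(n):
            if i == j:
                continue  # same coordinate is never a partner
            cj, sj, wj = kmers[j]
            if ci == cj and abs(si - sj) < min_separation:
                continue
            if int((wi != wj).sum()) <= max_hamming:
                redundant[i] = True
                break
            if both_strands:
                rc = (3 - wj[::-1]).astype(np.uint8)
                if int((wi != rc).sum()) <= max_hamming:
                    redundant[i] = True
                    break
    n_red = int(redundant.sum())
    return RedundancyReport(
        k, max_hamming, n, n_red, n_skipped, (n_red / n) if n else 0.0, both_strands, min_separation
    )
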