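"""Cross-list integration of differential results.

Directional overlap of two differential gene lists (shared up/up, down/down
and the two opposing categories), complementary small-RNA vs transcript
fold-change pairing (a gene whose sRNA coverage rises while its transcript
falls, or vice versa), membership counting across many lists, and the
shared-fraction percentage summary.  All fold changes follow the package
sign convention log2(reference/comparison).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd


@dataclass
class DirectionalOverlap:
    """Sign-partitioned overlap of two differential lists A and B."""

    up_in_both: set[str]
    down_in_both: set[str]
    up_a_down_b: set[str]
    down_a_up_b: set[str]
    exclusive_a: set[str]
    exclusive_b: set[str]
    unclassifiable: set[str] = field(default_factory=set)

    @property
    def categories(self) -> dict[str, set[str]]:
        return {
            "up_in_both": self.up_in_both,
            "down_in_both": self.down_in_both,
            "up_a_down_b": self.up_a_down_b,
            "down_a_up_b": self.down_a_up_b,
        }


@dataclass(frozen=True)
class ComplementaryTarget:
    gene_id: str
    srna_log2fc: float
    mrna_log2fc: float


def overlap_directional(
    de_a: Mapping[str, float], de_b: Mapping[str, float]
) -> DirectionalOverlap:
    """Partition two differential lists (gene -> log2fc) by fold-change sign.

    The four directional categories partition the intersection of the two
    lists; genes differential in only one list are reported as exclusive.
    Zero fold changes cannot be assigned a direction and are set aside.
    """
    inter = set(de_a) & set(de_b)
    res = DirectionalOverlap(set(), set(), set(), set(), set(de_a) - inter, set(de_b) - inter)
    for g in inter:
        fa, fb = de_a[g], de_b[g]
        if fa == 0 or fb == 0:
            res.unclassifiable.add(g)
        elif fa > 0 and fb > 0:
            res.up_in_both.add(g)
        elif fa < 0 and fb < 0:
            res.down_in_both.add(g)
        elif fa > 0:
            res.up_a_down_b.add(g)
        else:
            res.down_a_up_b.add(g)
    return res


def complementary_targets(
    mrna_de: Mapping[str, float], srna_de: Mapping[str, float]
) -> list[ComplementaryTarget]:
    """Genes differential in both layers with opposite fold-change signs.

    The canonical silencing pattern is sRNA accumulation up in the mutant
    while the transcript goes down (or the reverse); on the shared
    log2(reference/comparison) convention that is simply opposite signs.
    """
    out = []
    for g in sorted(set(mrna_de) & set(srna_de)):
        fm, fs = mrna_de[g], srna_de[g]
        if fm * fs < 0:
            out.append(ComplementaryTarget(gene_id=g, srna_log2fc=fs, mrna_log2fc=fm))
    return out


def cross_reference(
    target_lists: Mapping[str, Iterable[str]], min_lists: int = 2
) -> pd.DataFrame:
    """Count list membership per gene; keep genes in at least ``min_lists``."""
    if len(target_lists) < 2:
        raise ValueError("cross-referencing needs at least two lists")
    counts: Counter = Counter()
    members: dict[str, list[str]] = {}
    for name, genes in target_lists.items():
        for g in set(genes):
            counts[g] += 1
            members.setdefault(g, []).append(name)
    rows = [
        {"gene_id": g, "n_lists": n, "lists": ",".join(sorted(members[g]))}
        for g, n in counts.items()
        if n >= min_lists
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "n_lists", "lists"])
    return df.sort_values(["n_lists", "gene_id"], ascending=[False, True], ignore_index=True)


def shared_fraction(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """Percentage of A also found in B, rounded half-up to one decimal."""
    a, b = set(set_a), set(set_b)
    if not a:
        raise ValueError("set A is empty")
    pct = Decimal(100 * len(a & b)) / Decimal(len(a))
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
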