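"""GO-term enrichment with one-to-many orthology count multiplication.

Gene models are annotated through putative orthologs; because several gene
models can match a single ortholog, each gene's contribution to a GO term
is multiplied by the number of gene models in the background universe that
share its ortholog.  Enrichment of a foreground list against the expressed
background is the hypergeometric upper tail on these multiplied counts,
with terms treated as flat labels (no hierarchy propagation).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """gene model -> ortholog (many-to-one) and ortholog -> GO terms."""

    gene_to_ortholog: dict[str, str]
    ortholog_to_terms: dict[str, frozenset[str]]

    def multiplicity(self, universe: Iterable[str]) -> dict[str, int]:
        """m(ortholog): number of universe gene models matching it."""
        counts = Counter(
            self.gene_to_ortholog[g] for g in universe if g in self.gene_to_ortholog
        )
        return dict(counts)

    def terms_of_gene(self, gene: str) -> frozenset[str]:
        orth = self.gene_to_ortholog.get(gene)
        return self.ortholog_to_terms.get(orth, frozenset()) if orth else frozenset()


def load_annotation_map(path: str | Path) -> AnnotationMap:
    """Read a TSV with columns gene, ortholog, go_terms (comma-separated)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"gene", "ortholog", "go_terms"}
    if not need.issubset(df.columns):
        raise ValueError(f"annotation map must have columns {sorted(need)}")
    g2o: dict[str, str] = {}
    o2t: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        g2o[row.gene] = row.ortholog
        terms = o2t.setdefault(row.ortholog, set())
        if isinstance(row.go_terms, str) and row.go_terms:
            terms.update(t for t in row.go_terms.split(",") if t)
    return AnnotationMap(g2o, {o: frozenset(t) for o, t in o2t.items()})


def expand_counts(
    gene_list: Iterable[str],
    amap: AnnotationMap,
    multiplicity: Mapping[str, int] | None = None,
    weighted: bool = True,
) -> tuple[Counter, int]:
    """Multiplicity-weighted term counts for a gene list.

    Each annotated gene contributes m(ortholog) units to every GO term of
    its ortholog and m(ortholog) to the total; unannotated genes contribute
    nothing (logged).  With ``weighted=False`` every contribution is 1.
    """
    genes = list(gene_list)
    if multiplicity is None:
        multiplicity = Counter(
            amap.gene_to_ortholog[g] for g in genes if g in amap.gene_to_ortholog
        )
    term_counts: Counter = Counter()
    total = 0
    for gene in genes:
        orth = amap.gene_to_ortholog.get(gene)
        if orth is None or orth not in amap.ortholog_to_terms:
            log.debug("gene %s has no GO annotation; contributes 0", gene)
            continue
        m = multiplicity.get(orth, 1) if weighted else 1
        total += m
        for term in amap.ortholog_to_terms[orth]:
            term_counts[term] += m
    return term_counts, total


def enrich(
    fg_genes: Sequence[str],
    bg_genes: Sequence[str],
    amap: AnnotationMap,
    config,
    weighted: bool = True,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of foreground terms vs background.

    The foreground must be a subset of the background universe; ortholog
    multiplicities are computed on the background so foreground and
    background counts share one weighting.  A term is enriched when its
    p-value is at most ``go_alpha`` (inclusive).
    """
    fg_set, bg_set = set(fg_genes), set(bg_genes)
    if not fg_set <= bg_set:
        raise ValueError("foreground gene list is not a subset of the background universe")
    mult = amap.multiplicity(bg_set)
    fg_counts, fg_total = expand_counts(sorted(fg_set), amap, mult, weighted)
    bg_counts, bg_total = expand_counts(sorted(bg_set), amap, mult, weighted)
    rows = []
    for term in sorted(bg_counts):
        k, kk = fg_counts.get(term, 0), bg_counts[term]
        if k > kk:
            raise ValueError(f"term {term}: fg count {k} exceeds bg count {kk}")
        p = float(stats.hypergeom.sf(k - 1, bg_total, kk, fg_total)) if k > 0 else 1.0
        rows.append(
            {
                "term": term,
                "fg_count": k,
                "bg_count": kk,
                "fg_total": fg_total,
                "bg_total": bg_total,
                "p": min(1.0, p),
                "enriched": p <= config.go_alpha,
            }
        )
    df = pd.DataFrame(
        rows, columns=["term", "fg_count", "bg_count", "fg_total", "bg_total", "p", "enriched"]
    )
    return df.sort_values(["p", "term"], ignore_index=True)
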