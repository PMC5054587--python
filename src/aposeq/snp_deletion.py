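"""Genotype calling from allele-count pileups and deletion-scenario classification.

A tetraploid parent carries heterozygous (AB) gene copies; deletion mutants
derived from it lose either one homeologous copy (scenario 1: parent AB,
every mutant AA at the retained allele) or all copies of a hemizygous gene
(scenario 2: parent covered and homozygous with no second allele anywhere,
mutants with no reads at all).  Sites are genotyped per sample from raw
allele counts and then matched against these two patterns.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

# genotype labels
AA = "AA"
AB = "AB"
A_HEMI = "A-"   # homozygous with no second allele seen in any sample (parent only)
NO_READS = "--"
NA = "NA"

SCENARIO_HET_LOSS = 1   # parent AB, mutants AA
SCENARIO_HEMI_LOSS = 2  # parent A-, mutants --


@dataclass
class PileupSite:
    """Per-sample allele counts at one genomic position (0-based)."""

    contig_id: str
    pos: int
    counts: dict[str, dict[str, int]]

    def depth(self, sample: str) -> int:
        return sum(self.counts.get(sample, {}).values())


@dataclass(frozen=True)
class SampleCall:
    genotype: str
    major: str | None
    minor: str | None
    maf: float
    depth: int


@dataclass
class SnpCall:
    """Per-sample genotype classes at one pileup site."""

    site: PileupSite
    calls: dict[str, SampleCall]

    @property
    def is_snp(self) -> bool:
        """A site is a SNP locus only if some sample is heterozygous."""
        return any(c.genotype == AB for c in self.calls.values())


@dataclass
class DeletionCandidate:
    """A gene (or contig) supported by sites matching one deletion scenario."""

    unit_id: str
    scenario: int
    sites: list[SnpCall]

    @property
    def n_support(self) -> int:
        return len(self.sites)


def _call_sample(counts: Mapping[str, int], config) -> SampleCall:
    depth = sum(counts.values())
    if depth == 0:
        return SampleCall(NO_READS, None, None, 0.0, 0)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    major = ranked[0][0]
    minor = ranked[1][0] if len(ranked) > 1 else None
    minor_count = ranked[1][1] if len(ranked) > 1 else 0
    maf = minor_count / depth
    if depth < config.min_depth:
        return SampleCall(NA, major, minor, maf, depth)
    if maf >= config.maf_min:
        return SampleCall(AB, major, minor, maf, depth)
    if maf <= config.hom_err_max:
        return SampleCall(AA, major, minor if minor_count else None, maf, depth)
    return SampleCall(NA, major, minor, maf, depth)


def call_genotypes(
    pileups: Iterable[PileupSite],
    config,
    parent_id: str | None = None,
    samples: Sequence[str] | None = None,
) -> list[SnpCall]:
    """Genotype each sample at each site from raw allele counts.

    Rules per sample: depth 0 -> ``--``; 0 < depth < ``min_depth`` -> NA;
    minor-allele frequency >= ``maf_min`` -> AB; MAF <= ``hom_err_max`` -> AA;
    anything between -> NA.  When ``parent_id`` is given, a parent AA call is
    upgraded to ``A-`` (hemizygous-compatible) if no sample shows genuine
    evidence of a second allele at the site (an AB call, or an AA call on a
    different major allele).
    """
    out = []
    for site in pileups:
        if samples is not None:
            missing = set(samples) - set(site.counts)
            for s in missing:
                site.counts.setdefault(s, {})
        calls = {s: _call_sample(c, config) for s, c in site.counts.items()}
        if parent_id is not None and parent_id in calls:
            pc = calls[parent_id]
            if pc.genotype == AA:
                second_seen = any(
                    (c.genotype == AB)
                    or (c.genotype == AA and c.major is not None and c.major != pc.major)
                    for s, c in calls.items()
                    if s != parent_id
                )
                if not second_seen:
                    calls[parent_id] = SampleCall(A_HEMI, pc.major, None, pc.maf, pc.depth)
        out.append(SnpCall(site=site, calls=calls))
    return out


def classify_scenarios(
    calls: Iterable[SnpCall],
    parent_id: str,
    mutant_ids: Sequence[str],
    config,
    unit_of_site: Callable[[str, int], str | None] | None = None,
) -> list[DeletionCandidate]:
    """Match genotyped sites against the two deletion scenarios.

    Scenario 1: parent AB, every mutant AA with its allele among the
    parent's two alleles.  Scenario 2: parent ``A-`` at adequate depth and
    every mutant with at most ``max_stray_reads`` reads.  Sites where any
    mutant is NA are excluded.  ``unit_of_site`` maps (contig, pos) to a
    grouping unit (typically a gene id); sites mapping to None are dropped,
    and when grouping by gene, scenario-2 support additionally requires zero
    mutant reads across *all* of the gene's covered sites.
    """
    if not mutant_ids:
        raise ValueError("at least one mutant id required")
    per_unit: dict[tuple[str, int], list[SnpCall]] = defaultdict(list)
    unit_sites: dict[str, list[SnpCall]] = defaultdict(list)

    calls = list(calls)
    for call in calls:
        unit = (
            unit_of_site(call.site.contig_id, call.site.pos)
            if unit_of_site is not None
            else call.site.contig_id
        )
        if unit is None:
            continue
        unit_sites[unit].append(call)
        parent = call.calls.get(parent_id)
        if parent is None:
            raise ValueError(f"parent sample {parent_id} absent at {call.site.contig_id}:{call.site.pos}")
        mutants = [call.calls.get(m, SampleCall(NO_READS, None, None, 0.0, 0)) for m in mutant_ids]
        if any(m.genotype == NA for m in mutants):
            continue
        if parent.genotype == AB:
            alleles = {parent.major, parent.minor}
            if all(m.genotype == AA and m.major in alleles for m in mutants):
                per_unit[(unit, SCENARIO_HET_LOSS)].append(call)
        elif parent.genotype == A_HEMI and parent.depth >= config.min_depth:
            stray = getattr(config, "max_stray_reads", 0)
            if all(call.site.depth(m) <= stray for m in mutant_ids):
                per_unit[(unit, SCENARIO_HEMI_LOSS)].append(call)

    stray = getattr(config, "max_stray_reads", 0)
    out = []
    for (unit, scenario), sites in sorted(per_unit.items()):
        if scenario == SCENARIO_HEMI_LOSS and unit_of_site is not None:
            # require literal absence of mutant reads over the whole unit
            total_stray = {
                m: sum(c.site.depth(m) for c in unit_sites[unit]) for m in mutant_ids
            }
            if any(v > stray * len(unit_sites[unit]) for v in total_stray.values()):
                continue
        out.append(DeletionCandidate(unit_id=unit, scenario=scenario, sites=sites))
    return out


def summarize_candidates(
    candidates: Iterable[DeletionCandidate], min_support: int = 1
) -> pd.DataFrame:
    """One row per unit with per-scenario site counts, ranked by total support.

    Rows with fewer than ``min_support`` supporting sites are dropped; ties
    in support break lexicographically on the unit id.
    """
    agg: dict[str, dict[int, int]] = defaultdict(lambda: {1: 0, 2: 0})
    for cand in candidates:
        agg[cand.unit_id][cand.scenario] += cand.n_support
    rows = [
        {
            "unit_id": unit,
            "n_scenario1": sc[1],
            "n_scenario2": sc[2],
            "n_support": sc[1] + sc[2],
        }
        for unit, sc in agg.items()
    ]
    df = pd.DataFrame(rows, columns=["unit_id", "n_scenario1", "n_scenario2", "n_support"])
    df = df[df["n_support"] >= min_support]
    return df.sort_values(
        ["n_support", "unit_id"], ascending=[False, True], ignore_index=True
    )


def gene_lookup(genes, contig_lengths: Mapping[str, int], flank: int = 0):
    """Build a (contig, pos) -> gene_id mapping function from gene models."""
    by_contig: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
    for g in genes:
        s, e = g.span
        by_contig[g.contig_id].append(
            (max(0, s - flank), min(contig_lengths[g.contig_id], e + flank), g.id)
        )
    for ivs in by_contig.values():
        ivs.sort()

    def lookup(contig: str, pos: int) -> str | None:
        for s, e, gid in by_contig.get(contig, ()):
            if s <= pos < e:
                return gid
            if s > pos:
                break
        return None

    return lookup
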