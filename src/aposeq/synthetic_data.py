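"""Synthetic genomes, genotypes, counts, small-RNA populations and Ct tables.

Every generator is a pure function of its parameters and seed and records
its implanted features in a :class:`TruthTable`, so each downstream stage
can be scored against known ground truth.  The defaults emulate the study
design being modelled: a heterozygous tetraploid parent with two deletion
mutants (one losing single homeologous copies, one losing hemizygous genes
outright), negative-binomial mRNA counts with two replicates per group,
small-RNA populations mixing 21/22/24-nt classes with hairpin miRNA loci
and 24-nt siRNA clusters over gene bodies, and delta-Ct tables with two
biological and two technical replicates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import decode, random_seq, revcomp
from .core_io import Contig, CountMatrix, GeneModel
from .snp_deletion import PileupSite
from .smallrna_profiler import SmallRnaTag

HET_LOSS = "heterozygous-loss"   # scenario 1: parent AB -> mutants AA
HEMI_LOSS = "hemizygous-loss"    # scenario 2: parent A- -> mutants --

_BASES = "ACGT"


@dataclass(frozen=True)
class HetSite:
    """An implanted homeolog SNP: the assembly carries ``ref``; the second
    (collapsed) homeolog copy carries ``alt``."""

    contig_id: str
    pos: int
    ref: str
    alt: str
    gene_id: str


@dataclass(frozen=True)
class MirnaLocus:
    contig_id: str
    strand: str
    precursor: tuple[int, int]
    mir: tuple[int, int]
    star: tuple[int, int]


@dataclass
class TruthTable:
    """Ground truth of every implanted feature of a synthetic dataset."""

    het_sites: list[HetSite] = field(default_factory=list)
    het_genes: set[str] = field(default_factory=set)
    deleted_genes: dict[str, dict[str, str]] = field(default_factory=dict)
    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)
    mirna_loci: list[MirnaLocus] = field(default_factory=list)
    sirna_targets: dict[str, float] = field(default_factory=dict)
    qpcr_truth: dict[str, float] = field(default_factory=dict)

    def deletions_common_to(self, mutant_ids: Iterable[str]) -> dict[str, str]:
        """Genes deleted in every listed mutant, with their scenario label."""
        mutant_ids = list(mutant_ids)
        if not mutant_ids:
            return {}
        common = set(self.deleted_genes.get(mutant_ids[0], {}))
        for m in mutant_ids[1:]:
            common &= set(self.deleted_genes.get(m, {}))
        return {g: self.deleted_genes[mutant_ids[0]][g] for g in sorted(common)}

    def to_json(self, path) -> None:
        payload = {
            "het_sites": [asdict(h) for h in self.het_sites],
            "het_genes": sorted(self.het_genes),
            "deleted_genes": self.deleted_genes,
            "de_genes": self.de_genes,
            "mirna_loci": [asdict(m) for m in self.mirna_loci],
            "sirna_targets": self.sirna_targets,
            "qpcr_truth": self.qpcr_truth,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            het_sites=[HetSite(**h) for h in raw["het_sites"]],
            het_genes=set(raw["het_genes"]),
            deleted_genes=raw["deleted_genes"],
            de_genes=raw["de_genes"],
            mirna_loci=[
                MirnaLocus(
                    m["contig_id"], m["strand"],
                    tuple(m["precursor"]), tuple(m["mir"]), tuple(m["star"]),
                )
                for m in raw["mirna_loci"]
            ],
            sirna_targets=raw["sirna_targets"],
            qpcr_truth=raw["qpcr_truth"],
        )


# ---------------------------------------------------------------------------
# genome


def simulate_genome(
    n_contigs: int = 2,
    contig_length: int = 200_000,
    n_genes: int = 200,
    gene_len_range: tuple[int, int] = (900, 3000),
    het_fraction: float = 0.3,
    n_het_snps: int = 3,
    n_mirna_loci: int = 6,
    n_scenario1: int = 20,
    n_scenario2: int = 10,
    n_sirna_targets: int = 10,
    sirna_log2fc: float = 2.0,
    mutant_ids: Sequence[str] = ("m115", "m134"),
    seed: int = 0,
) -> tuple[list[Contig], list[GeneModel], TruthTable]:
    """Simulate contigs with structured gene models and implanted features.

    A ``het_fraction`` of genes exist as collapsed homeolog pairs differing
    at ``n_het_snps`` sites (the assembly carries one copy; the alternate
    alleles live in the truth table).  ``n_scenario1`` heterozygous genes
    and ``n_scenario2`` homozygous genes are marked deleted in every mutant.
    miRNA hairpin loci (two perfectly complementary 21-nt arms around a
    short loop) are implanted in intergenic space, and ``n_sirna_targets``
    genes are marked as 24-nt siRNA cluster targets with the given true
    small-RNA fold change (log2 parent/mutant).
    """
    if min(n_contigs, contig_length, n_genes) <= 0 or gene_len_range[0] <= 0:
        raise ValueError("genome parameters must be positive")
    rng = np.random.default_rng(seed)
    per_contig = int(np.ceil(n_genes / n_contigs))
    slot = contig_length // per_contig
    margin = 700  # keeps extended (±500 bp) regions of neighbours disjoint
    if gene_len_range[1] + 2 * margin > slot:
        raise ValueError(
            f"gene length up to {gene_len_range[1]} does not fit a {slot}-bp slot; "
            "increase contig_length or reduce n_genes"
        )

    contigs: list[Contig] = []
    genes: list[GeneModel] = []
    truth = TruthTable()
    gi = 0
    for ci in range(n_contigs):
        seq = list(random_seq(rng, contig_length))
        cid = f"ctg{ci + 1}"
        n_here = min(per_contig, n_genes - gi)
        gaps: list[tuple[int, int]] = []
        prev_end = 0
        for k in range(n_here):
            gid = f"g{gi + 1:04d}"
            gi += 1
            glen = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
            start = k * slot + margin
            strand = "+" if rng.random() < 0.5 else "-"
            cursor = start
            utr5_len = int(rng.integers(80, 250))
            utr3_len = int(rng.integers(80, 250))
            core = glen - utr5_len - utr3_len
            n_exons = int(rng.integers(1, 5))
            intron_lens = (
                [int(rng.integers(80, 200)) for _ in range(n_exons - 1)] if n_exons > 1 else []
            )
            cds_total = core - sum(intron_lens)
            if cds_total < n_exons * 30:
                n_exons, intron_lens, cds_total = 1, [], core
            cuts = np.sort(rng.integers(1, cds_total, size=n_exons - 1)) if n_exons > 1 else []
            exon_lens = np.diff([0, *cuts, cds_total]).astype(int)
            exon_lens = np.maximum(exon_lens, 10)
            first_iv = (cursor, cursor + utr5_len)
            cursor += utr5_len
            cds = []
            for e, el in enumerate(exon_lens):
                cds.append((cursor, cursor + int(el)))
                cursor += int(el)
                if e < len(intron_lens):
                    cursor += intron_lens[e]
            last_iv = (cursor, cursor + utr3_len)
            cursor += utr3_len
            utr5_ivs, utr3_ivs = ((first_iv,), (last_iv,)) if strand == "+" else ((last_iv,), (first_iv,))
            genes.append(
                GeneModel(
                    id=gid, contig_id=cid, strand=strand,
                    cds_intervals=tuple(cds),
                    utr5_intervals=utr5_ivs, utr3_intervals=utr3_ivs,
                )
            )
            gaps.append((prev_end, start - 500))
            prev_end = cursor + 500
        gaps.append((prev_end, contig_length))

        # implant miRNA hairpins into intergenic gaps of this contig
        share = int(np.ceil(n_mirna_loci / n_contigs))
        usable = [g for g in gaps if g[1] - g[0] > 200]
        for j in range(share):
            if len(truth.mirna_loci) >= n_mirna_loci or not usable:
                break
            lo, hi = usable[j % len(usable)]
            loop = int(rng.integers(12, 40))
            total = 21 + loop + 21
            offset = lo + 30 + j // len(usable) * (total + 60)
            if offset + total > hi - 30:
                continue
            mir_seq = random_seq(rng, 21)
            star_seq = revcomp(mir_seq)
            seq[offset : offset + 21] = list(mir_seq)
            seq[offset + 21 + loop : offset + total] = list(star_seq)
            truth.mirna_loci.append(
                MirnaLocus(
                    contig_id=cid, strand="+",
                    precursor=(offset, offset + total),
                    mir=(offset, offset + 21),
                    star=(offset + 21 + loop, offset + total),
                )
            )
        contigs.append(Contig(cid, "".join(seq)))

    # heterozygous (homeolog-pair) genes and their implanted SNPs
    gene_ids = [g.id for g in genes]
    n_het = int(round(het_fraction * n_genes))
    het_idx = rng.choice(len(genes), size=n_het, replace=False)
    contig_seq = {c.id: c.sequence for c in contigs}
    for idx in sorted(het_idx):
        g = genes[idx]
        truth.het_genes.add(g.id)
        b0, b1 = g.body
        positions = sorted(
            int(p) for p in rng.choice(np.arange(b0, b1), size=n_het_snps, replace=False)
        )
        for pos in positions:
            ref = contig_seq[g.contig_id][pos]
            alt = _BASES[(_BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            truth.het_sites.append(HetSite(g.contig_id, pos, ref, alt, g.id))

    # deletions shared by every mutant
    het_list = sorted(truth.het_genes)
    hom_list = [g for g in gene_ids if g not in truth.het_genes]
    if n_scenario1 > len(het_list) or n_scenario2 > len(hom_list):
        raise ValueError("not enough genes for the requested deletion counts")
    s1 = [str(g) for g in rng.choice(het_list, size=n_scenario1, replace=False)] if n_scenario1 else []
    s2 = [str(g) for g in rng.choice(hom_list, size=n_scenario2, replace=False)] if n_scenario2 else []
    for m in mutant_ids:
        truth.deleted_genes[m] = {**{g: HET_LOSS for g in s1}, **{g: HEMI_LOSS for g in s2}}

    # siRNA cluster targets among non-deleted genes
    candidates = [g for g in gene_ids if g not in s1 and g not in s2]
    pick = rng.choice(candidates, size=min(n_sirna_targets, len(candidates)), replace=False)
    truth.sirna_targets = {str(g): float(sirna_log2fc) for g in sorted(pick)}
    return contigs, genes, truth


# ---------------------------------------------------------------------------
# pileups


def simulate_mutant_pileups(
    contigs: Sequence[Contig],
    genes: Sequence[GeneModel],
    truth: TruthTable,
    parent_id: str = "R35",
    mutant_ids: Sequence[str] = ("m115", "m134"),
    depth_mean: float = 30.0,
    error_rate: float = 0.0,
    n_hom_sites: int = 3,
    seed: int = 0,
) -> list[PileupSite]:
    """Per-sample allele counts emulating the parent/mutant genotype patterns.

    Heterozygous sites emit both alleles at ~50:50 in the parent; a
    scenario-1 mutant retains only the assembly allele, a scenario-2 mutant
    emits no reads over the gene.  Depth is Poisson per site and sample;
    ``error_rate`` replaces each read base with a uniform wrong base.
    """
    if depth_mean <= 0 or not (0 <= error_rate < 1):
        raise ValueError("depth_mean must be positive and error_rate in [0,1)")
    rng = np.random.default_rng(seed)
    contig_seq = {c.id: c.sequence for c in contigs}
    het_by_gene: dict[str, list[HetSite]] = {}
    for h in truth.het_sites:
        het_by_gene.setdefault(h.gene_id, []).append(h)

    samples = [parent_id, *mutant_ids]
    sites: list[PileupSite] = []
    for gene in genes:
        if gene.id in het_by_gene:
            site_specs = [(h.pos, h.ref, h.alt) for h in het_by_gene[gene.id]]
        else:
            b0, b1 = gene.body
            positions = np.linspace(b0, b1 - 1, n_hom_sites).astype(int)
            site_specs = [(int(p), contig_seq[gene.contig_id][p], None) for p in positions]
        for pos, ref, alt in site_specs:
            counts: dict[str, dict[str, int]] = {}
            for sample in samples:
                scenario = truth.deleted_genes.get(sample, {}).get(gene.id)
                if scenario == HEMI_LOSS:
                    counts[sample] = {}
                    continue
                depth = int(rng.poisson(depth_mean))
                per: dict[str, int] = {}
                if depth:
                    # allele identity: heterozygous unless this mutant lost a copy
                    if alt is not None and scenario != HET_LOSS:
                        alt_mask = rng.random(depth) < 0.5
                    else:
                        alt_mask = np.zeros(depth, dtype=bool)
                    bases = np.where(alt_mask, alt, ref)
                    if error_rate > 0:
                        err = rng.random(depth) < error_rate
                        for i in np.flatnonzero(err):
                            b = bases[i]
                            others = [x for x in _BASES if x != b]
                            bases[i] = others[int(rng.integers(0, 3))]
                    for b in bases:
                        per[str(b)] = per.get(str(b), 0) + 1
                counts[sample] = per
            sites.append(PileupSite(contig_id=gene.contig_id, pos=pos, counts=counts))
    return sites


# ---------------------------------------------------------------------------
# mRNA counts


def simulate_counts(
    genes: Sequence[GeneModel],
    design: Mapping[str, Sequence[str]],
    mu_range: tuple[float, float] = (20.0, 2000.0),
    dispersion: float = 0.1,
    de_spec: Mapping[str, float] | None = None,
    lib_factor_range: tuple[float, float] = (0.8, 1.25),
    seed: int = 0,
) -> tuple[CountMatrix, dict[str, float]]:
    """Negative-binomial counts for a two-group design with implanted changes.

    ``design`` maps group -> sample names; the first group is the reference.
    ``de_spec`` maps gene -> true log2 fold change (reference/comparison);
    the effect is split symmetrically between the groups.  Variance follows
    mu + dispersion * mu^2; per-sample library-size multipliers are drawn
    uniformly from ``lib_factor_range``.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    groups = list(design)
    if len(groups) != 2:
        raise ValueError("design must contain exactly two groups")
    de_spec = dict(de_spec or {})
    rng = np.random.default_rng(seed)
    gene_ids = [g.id if hasattr(g, "id") else str(g) for g in genes]
    unknown = set(de_spec) - set(gene_ids)
    if unknown:
        raise ValueError(f"de_spec genes not in gene set: {sorted(unknown)}")
    mu = np.exp(rng.uniform(np.log(mu_range[0]), np.log(mu_range[1]), size=len(gene_ids)))
    lfc = np.array([de_spec.get(g, 0.0) for g in gene_ids])
    mean_by_group = {
        groups[0]: mu * 2.0 ** (lfc / 2),
        groups[1]: mu * 2.0 ** (-lfc / 2),
    }
    samples = [s for g in groups for s in design[g]]
    counts = np.zeros((len(gene_ids), len(samples)), dtype=np.int64)
    col = 0
    for g in groups:
        for _ in design[g]:
            lib = rng.uniform(*lib_factor_range)
            m = mean_by_group[g] * lib
            if dispersion == 0:
                counts[:, col] = rng.poisson(m)
            else:
                r = 1.0 / dispersion
                p = r / (r + m)
                counts[:, col] = rng.negative_binomial(r, p)
            col += 1
    truth = {g: float(de_spec.get(g, 0.0)) for g in gene_ids}
    return CountMatrix(gene_ids, samples, counts), truth


# ---------------------------------------------------------------------------
# small RNA


def simulate_smallrna(
    contigs: Sequence[Contig],
    genes: Sequence[GeneModel],
    truth: TruthTable,
    length_mix: Mapping[str, Mapping[int, float]],
    genotype_of_sample: Mapping[str, str] | None = None,
    parent_genotype: str = "R35",
    n_reads: int = 50_000,
    n_background: int = 2000,
    mir_reads: float = 300.0,
    star_reads: float = 60.0,
    sirna_reads: float = 150.0,
    sirna_tiles_per_gene: int = 8,
    seed: int = 0,
) -> list[SmallRnaTag]:
    """Small-RNA tag populations with implanted miRNA and siRNA signal.

    Each sample's background reads are multinomial over the 18-25 nt bins
    of its ``length_mix`` and spread within each bin over genome-derived
    background tags.  Implanted signal is additive on top: each hairpin arm
    receives ~``mir_reads``/``star_reads`` Poisson reads, and each 24-nt
    tile over a siRNA target gene receives ~``sirna_reads`` Poisson reads
    scaled per genotype by the implanted fold change (parent at full
    intensity, other genotypes at 2^-log2fc).  All tags align perfectly
    somewhere by construction.
    """
    rng = np.random.default_rng(seed)
    lengths = list(range(18, 26))
    for sample, mix in length_mix.items():
        total = sum(mix.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"length mix for {sample} sums to {total}, not 1")
    contig_seq = {c.id: c.sequence for c in contigs}
    gene_by_id = {g.id: g for g in genes}

    # shared catalogue: sequence -> (kind, gene_id or None)
    catalogue: dict[str, tuple[str, str | None]] = {}

    def add(seq: str, kind: str, gid: str | None) -> None:
        if "N" not in seq and seq not in catalogue:
            catalogue[seq] = (kind, gid)

    for locus in truth.mirna_loci:
        s = contig_seq[locus.contig_id]
        add(s[locus.mir[0] : locus.mir[1]], "mir", None)
        add(s[locus.star[0] : locus.star[1]], "star", None)
    for gid in truth.sirna_targets:
        g = gene_by_id[gid]
        b0, b1 = g.body
        for p in np.linspace(b0, max(b0, b1 - 24), sirna_tiles_per_gene).astype(int):
            add(contig_seq[g.contig_id][p : p + 24], "sirna", gid)
    per_len = int(np.ceil(n_background / len(lengths)))
    for ln in lengths:
        made = 0
        while made < per_len:
            cid = list(contig_seq)[int(rng.integers(0, len(contig_seq)))]
            s = contig_seq[cid]
            p = int(rng.integers(0, len(s) - ln))
            sub = s[p : p + ln]
            if rng.random() < 0.5:
                sub = revcomp(sub)
            if sub not in catalogue:
                add(sub, "background", None)
            made += 1

    by_len: dict[int, list[str]] = {ln: [] for ln in lengths}
    for seq in catalogue:
        if len(seq) in by_len:
            by_len[len(seq)].append(seq)

    bg_by_len = {ln: [s for s in by_len[ln] if catalogue[s][0] == "background"] for ln in lengths}
    tag_counts: dict[str, dict[str, int]] = {seq: {} for seq in catalogue}
    for sample, mix in length_mix.items():
        genotype = (genotype_of_sample or {}).get(sample, parent_genotype)
        probs = np.array([mix.get(ln, 0.0) for ln in lengths])
        reads_per_len = rng.multinomial(n_reads, probs / probs.sum())
        for ln, n_here in zip(lengths, reads_per_len):
            pool = bg_by_len[ln]
            if not pool or n_here == 0:
                continue
            draw = rng.multinomial(n_here, np.full(len(pool), 1.0 / len(pool)))
            for seq, n_tag in zip(pool, draw):
                if n_tag:
                    tag_counts[seq][sample] = tag_counts[seq].get(sample, 0) + int(n_tag)
        for seq, (kind, gid) in catalogue.items():
            if kind == "background":
                continue
            if kind == "mir":
                lam = mir_reads
            elif kind == "star":
                lam = star_reads
            else:  # sirna tile
                lfc = truth.sirna_targets.get(gid, 0.0)
                lam = sirna_reads * (1.0 if genotype == parent_genotype else 2.0 ** (-lfc))
            n_tag = int(rng.poisson(lam))
            if n_tag:
                tag_counts[seq][sample] = tag_counts[seq].get(sample, 0) + n_tag

    samples = list(length_mix)
    return [
        SmallRnaTag(sequence=seq, counts={s: cnt.get(s, 0) for s in samples})
        for seq, cnt in tag_counts.items()
        if any(cnt.values())
    ]


# ---------------------------------------------------------------------------
# qPCR Ct tables


def simulate_ct(
    qpcr_truth: Mapping[str, float],
    ref_gene: str = "HpUBC21",
    test_group: str = "R35",
    control_group: str = "m115",
    ct_noise_sd: float = 0.2,
    n_bio: int = 2,
    n_tech: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table for the delta-delta-Ct pipeline with known fold changes.

    ``qpcr_truth`` maps gene -> true expression fold of the test group over
    the control group (the reference gene is unaffected by construction).
    Ct = per-gene baseline - log2(expression) + Gaussian noise per
    technical measurement.
    """
    if n_bio < 2:
        raise ValueError("n_bio must be >= 2 (t-test undefined otherwise)")
    if any(f <= 0 for f in qpcr_truth.values()):
        raise ValueError("true fold changes must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    baselines = {g: float(rng.uniform(21, 28)) for g in [*qpcr_truth, ref_gene]}
    for group in (test_group, control_group):
        for gene in [*qpcr_truth, ref_gene]:
            if gene == ref_gene:
                expr = 1.0
            else:
                expr = float(qpcr_truth[gene]) if group == test_group else 1.0
            for b in range(1, n_bio + 1):
                for t in range(1, n_tech + 1):
                    noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "sample": group,
                            "gene": gene,
                            "bio_rep": b,
                            "tech_rep": t,
                            "ct": baselines[gene] - np.log2(expr) + noise,
                        }
                    )
    return pd.DataFrame(rows)
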