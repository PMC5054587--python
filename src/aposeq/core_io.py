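"""Domain types and readers/writers for the pipeline's standard formats.

Coordinate convention: everything in memory is 0-based half-open.  GFF3 and
SAM are converted at the boundary (1-based inclusive on disk) and restored
on export.  Pileup TSVs store internal 0-based positions.
"""

from __future__ import annotations

import dataclasses
import tomllib
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import VALID_BASES, normalize_rna
from .snp_deletion import PileupSite
from .smallrna_profiler import SmallRnaTag


class ParseError(ValueError):
    """Raised when an input file violates its format."""


class ValidationError(ValueError):
    """Raised when parsed content violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Contig:
    """A genome contig: an id and its DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("contig id must be non-empty")
        if len(self.sequence) < 1:
            raise ValidationError(f"contig {self.id}: empty sequence")
        bad = set(self.sequence.upper()) - VALID_BASES
        if bad:
            raise ValidationError(f"contig {self.id}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


def _check_intervals(ivs: Sequence[tuple[int, int]], label: str) -> None:
    prev_end = None
    for s, e in ivs:
        if not (0 <= s < e):
            raise ValidationError(f"{label}: bad interval [{s},{e})")
        if prev_end is not None and s < prev_end:
            raise ValidationError(f"{label}: intervals overlap or are unsorted")
        prev_end = e


@dataclass(frozen=True)
class GeneModel:
    """A predicted gene model.

    ``cds_intervals`` are the coding blocks; introns are the gaps between
    them.  The gene body (CDS plus introns) runs from the first CDS start to
    the last CDS end.  UTRs are stored explicitly.  All intervals are
    0-based half-open on the forward strand of ``contig_id``.
    """

    id: str
    contig_id: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    utr5_intervals: tuple[tuple[int, int], ...] = ()
    utr3_intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.id}: strand must be + or -")
        if not self.cds_intervals:
            raise ValidationError(f"gene {self.id}: no CDS intervals")
        for ivs, label in (
            (self.cds_intervals, f"gene {self.id} CDS"),
            (self.utr5_intervals, f"gene {self.id} 5'UTR"),
            (self.utr3_intervals, f"gene {self.id} 3'UTR"),
        ):
            _check_intervals(ivs, label)

    @property
    def intron_intervals(self) -> tuple[tuple[int, int], ...]:
        cds = self.cds_intervals
        return tuple((cds[i][1], cds[i + 1][0]) for i in range(len(cds) - 1))

    @property
    def body(self) -> tuple[int, int]:
        """CDS-plus-introns span (gene body)."""
        return (self.cds_intervals[0][0], self.cds_intervals[-1][1])

    @property
    def span(self) -> tuple[int, int]:
        ivs = list(self.cds_intervals) + list(self.utr5_intervals) + list(self.utr3_intervals)
        return (min(s for s, _ in ivs), max(e for _, e in ivs))


@dataclass(frozen=True)
class ExtendedRegion:
    """A gene span widened by ``flank`` bp each side, clipped to the contig."""

    gene_id: str
    start: int
    end: int
    flank: int = 500

    @classmethod
    def from_gene(cls, gene: GeneModel, contig_length: int, flank: int = 500) -> "ExtendedRegion":
        s, e = gene.span
        return cls(gene.id, max(0, s - flank), min(contig_length, e + flank), flank)

    def __contains__(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    genotype: str
    stage: str
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValidationError(f"sample {self.sample_id}: replicate must be >= 1")


@dataclass
class CountMatrix:
    """Features x samples matrix of non-negative integer read counts."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValidationError("count matrix dimensions inconsistent with id lists")
        if (self.counts < 0).any():
            raise ValidationError("count matrix has negative entries")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())


@dataclass
class AnalysisConfig:
    """Every tunable threshold of the pipeline, with its default.

    Defaults mirror the published study design where a value is printed
    (MAF >= 0.25, tag lengths 18-25 nt, >= 5 reads in a sample, 500 bp
    flanks, <= 2 mismatches plus a 1-2 nt microindel, 400 bp pair window,
    two-fold / adjusted p <= 0.01 differential rule, enrichment p <= 1e-5,
    qPCR 1.5-fold / p < 0.05) and conventional practice elsewhere.
    """

    maf_min: float = 0.25
    min_depth: int = 8
    hom_err_max: float = 0.05
    max_stray_reads: int = 0
    sr_len_min: int = 18
    sr_len_max: int = 25
    min_tag_count: int = 5
    tag_count_strict: bool = False  # True -> "more than five times" (> min_tag_count)
    flank: int = 500
    sr_max_mm: int = 2
    sr_indel_max: int = 2
    pair_window: int = 400
    duplex_min_paired: float = 0.6
    min_loop: int = 3
    fc_min: float = 2.0
    de_alpha: float = 0.01
    srna_pseudocount: float = 1.0
    go_alpha: float = 1e-5
    qpcr_fc_min: float = 1.5
    qpcr_alpha: float = 0.05
    mrna_mm_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maf_min", "hom_err_max", "duplex_min_paired", "mrna_mm_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        for name in (
            "min_depth", "sr_len_min", "sr_len_max", "min_tag_count", "flank",
            "pair_window", "fc_min", "de_alpha", "go_alpha", "qpcr_fc_min", "qpcr_alpha",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")

    @classmethod
    def from_toml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[Contig]:
    return [Contig(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(contigs: Iterable[Contig], path: str | Path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.id, description="") for c in contigs]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 gene models

_UTR5_TYPES = {"five_prime_UTR", "5'UTR", "five_prime_utr"}
_UTR3_TYPES = {"three_prime_UTR", "3'UTR", "three_prime_utr"}


def _gff_attrs(col: str) -> dict[str, str]:
    out = {}
    for item in col.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k] = v
    return out


def load_gene_models(
    path: str | Path, contig_lengths: Mapping[str, int] | None = None
) -> list[GeneModel]:
    """Parse gene models from GFF3 (one :class:`GeneModel` per mRNA row).

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    CDS and UTR rows attach to their mRNA via the ``Parent`` attribute.
    """
    mrnas: dict[str, dict] = {}
    order: list[str] = []
    children: dict[str, dict[str, list[tuple[int, int]]]] = defaultdict(
        lambda: {"cds": [], "utr5": [], "utr3": []}
    )
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = cols
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start1 < 1 or end1 < start1:
                raise ParseError(f"{path}: line {lineno}: bad coordinate range {start1}-{end1}")
            iv = (start1 - 1, end1)  # GFF3 1-based inclusive -> 0-based half-open
            attrs = _gff_attrs(attrs_s)
            if ftype == "mRNA":
                mid = attrs.get("ID")
                if not mid:
                    raise ParseError(f"{path}: line {lineno}: mRNA without ID")
                mrnas[mid] = {"contig": seqid, "strand": strand}
                order.append(mid)
            elif ftype == "CDS":
                children[attrs.get("Parent", "")]["cds"].append(iv)
            elif ftype in _UTR5_TYPES:
                children[attrs.get("Parent", "")]["utr5"].append(iv)
            elif ftype in _UTR3_TYPES:
                children[attrs.get("Parent", "")]["utr3"].append(iv)
            # gene and other feature rows carry no interval information we need

    genes = []
    for mid in order:
        info = mrnas[mid]
        kid = children.get(mid, {"cds": [], "utr5": [], "utr3": []})
        gene = GeneModel(
            id=mid,
            contig_id=info["contig"],
            strand=info["strand"],
            cds_intervals=tuple(sorted(kid["cds"])),
            utr5_intervals=tuple(sorted(kid["utr5"])),
            utr3_intervals=tuple(sorted(kid["utr3"])),
        )
        if contig_lengths is not None:
            clen = contig_lengths.get(gene.contig_id)
            if clen is None:
                raise ValidationError(f"gene {mid}: unknown contig {gene.contig_id}")
            if gene.span[1] > clen:
                raise ValidationError(f"gene {mid}: extends past contig end ({gene.span[1]} > {clen})")
        genes.append(gene)
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path, source: str = "aposeq") -> None:
    """Write gene models as GFF3, restoring 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.contig_id}\t{source}\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={g.id}\n"
            )
            for a, b in g.cds_intervals:
                fh.write(f"{g.contig_id}\t{source}\tCDS\t{a + 1}\t{b}\t.\t{g.strand}\t0\tParent={g.id}\n")
            for a, b in g.utr5_intervals:
                fh.write(
                    f"{g.contig_id}\t{source}\tfive_prime_UTR\t{a + 1}\t{b}\t.\t{g.strand}\t.\tParent={g.id}\n"
                )
            for a, b in g.utr3_intervals:
                fh.write(
                    f"{g.contig_id}\t{source}\tthree_prime_UTR\t{a + 1}\t{b}\t.\t{g.strand}\t.\tParent={g.id}\n"
                )


# ---------------------------------------------------------------------------
# pileups

_BASES = ("A", "C", "G", "T")


def load_pileup(path: str | Path, known_samples: Sequence[str] | None = None) -> list[PileupSite]:
    """Read per-site allele counts from TSV (contig, pos, sample, A, C, G, T).

    Positions in the TSV are internal 0-based coordinates.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "pos", "sample", "A", "C", "G", "T"],
        comment="#",
    )
    if known_samples is not None:
        unknown = set(df["sample"].astype(str)) - set(known_samples)
        if unknown:
            raise ValidationError(
                f"unknown sample id(s) {sorted(unknown)}; known samples: {list(known_samples)}"
            )
    sites: dict[tuple[str, int], PileupSite] = {}
    for row in df.itertuples(index=False):
        key = (str(row.contig), int(row.pos))
        site = sites.get(key)
        if site is None:
            site = PileupSite(contig_id=key[0], pos=key[1], counts={})
            sites[key] = site
        counts = {b: int(getattr(row, b)) for b in _BASES if int(getattr(row, b)) > 0}
        site.counts[str(row.sample)] = counts
    return sorted(sites.values(), key=lambda s: (s.contig_id, s.pos))


def write_pileup(sites: Iterable[PileupSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for site in sites:
            for sample in sorted(site.counts):
                counts = site.counts[sample]
                vals = "\t".join(str(counts.get(b, 0)) for b in _BASES)
                fh.write(f"{site.contig_id}\t{site.pos}\t{sample}\t{vals}\n")


def load_pileup_sam(
    path: str | Path,
    sample_of_readgroup: Mapping[str, str] | None = None,
    default_sample: str | None = None,
    known_samples: Sequence[str] | None = None,
) -> list[PileupSite]:
    """Derive per-site allele counts from a (text) SAM file.

    Each aligned base of each read increments the count of its query base at
    the reference position (SAM POS converted to 0-based).  The sample is
    taken from the read's RG tag via ``sample_of_readgroup``, falling back to
    ``default_sample``.
    """
    import pysam

    sites: dict[tuple[str, int], PileupSite] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam:
            if read.is_unmapped or read.query_sequence is None:
                continue
            if read.has_tag("RG") and sample_of_readgroup is not None:
                sample = sample_of_readgroup.get(read.get_tag("RG"))
                if sample is None:
                    raise ValidationError(
                        f"unknown read group {read.get_tag('RG')}; "
                        f"known: {sorted(sample_of_readgroup)}"
                    )
            else:
                sample = default_sample
            if sample is None:
                raise ValidationError("SAM read without resolvable sample id")
            if known_samples is not None and sample not in known_samples:
                raise ValidationError(
                    f"unknown sample id {sample}; known samples: {list(known_samples)}"
                )
            contig = read.reference_name
            seq = read.query_sequence.upper()
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                base = seq[qpos]
                if base not in _BASES:
                    continue
                key = (contig, rpos)
                site = sites.get(key)
                if site is None:
                    site = PileupSite(contig_id=contig, pos=rpos, counts={})
                    sites[key] = site
                per = site.counts.setdefault(sample, {})
                per[base] = per.get(base, 0) + 1
    return sorted(sites.values(), key=lambda s: (s.contig_id, s.pos))


# ---------------------------------------------------------------------------
# small-RNA tags


def load_tags(sample_files: Mapping[str, str | Path]) -> list[SmallRnaTag]:
    """Read small-RNA tags from per-sample FASTA files.

    Headers carry read counts as ``id_count=N``.  Identical sequences across
    samples are merged into one tag with a per-sample count mapping; U is
    normalized to T.
    """
    merged: dict[str, dict[str, int]] = {}
    for sample, path in sample_files.items():
        for rec in SeqIO.parse(str(path), "fasta"):
            header = rec.id
            if "_count=" not in header:
                raise ParseError(f"{path}: header {header!r} lacks '_count=N'")
            count_s = header.rsplit("_count=", 1)[1]
            try:
                count = int(count_s)
            except ValueError as exc:
                raise ParseError(f"{path}: bad count in header {header!r}") from exc
            if count < 0:
                raise ParseError(f"{path}: negative count in header {header!r}")
            seq = normalize_rna(str(rec.seq))
            bad = set(seq) - {"A", "C", "G", "T"}
            if bad:
                raise ParseError(f"{path}: non-nucleotide character(s) {sorted(bad)} in {header!r}")
            per = merged.setdefault(seq, {})
            per[sample] = per.get(sample, 0) + count
    samples = list(sample_files)
    return [
        SmallRnaTag(sequence=seq, counts={s: per.get(s, 0) for s in samples})
        for seq, per in merged.items()
    ]


def write_tags(tags: Iterable[SmallRnaTag], sample_id: str, path: str | Path) -> None:
    """Write one sample's tag counts back to FASTA (tags with zero count skipped)."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags):
            n = tag.counts.get(sample_id, 0)
            if n > 0:
                fh.write(f">t{i}_count={n}\n{tag.sequence}\n")


# ---------------------------------------------------------------------------
# count matrices


def read_counts_tsv(path: str | Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix.from_frame(df.astype(np.int64))


def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="feature_id")
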