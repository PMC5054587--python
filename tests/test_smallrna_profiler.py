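"""Tag filtering, genome placement and genic annotation against brute-force oracles."""

import numpy as np
import pytest

from aposeq._seq import encode, random_seq, revcomp
from aposeq.core_io import AnalysisConfig, Contig, GeneModel
from aposeq.smallrna_profiler import (
    SmallRnaTag,
    SrnaAlignment,
    _class_within,
    _scan,
    align_perfect,
    align_tags,
    annotate_alignments,
    filter_tags,
    gene_counts,
    length_distribution,
)


def tag(seq, **counts):
    return SmallRnaTag(sequence=seq, counts=counts or {"s1": 10})


class TestFilter:
    def test_length_boundaries(self, cfg):
        kept = filter_tags([tag("A" * 17), tag("C" * 18, s1=5, s2=0), tag("G" * 25), tag("T" * 26)], cfg)
        assert [t.length for t in kept] == [18, 25]

    def test_count_rule_max_over_samples(self, cfg):
        dropped = tag("ACGT" * 5, a=4, b=4, c=4)
        kept = tag("TGCA" * 5, a=4, b=5, c=0)
        assert filter_tags([dropped, kept], cfg) == [kept]

    def test_strict_mode_requires_more_than_threshold(self, cfg):
        import dataclasses

        strict = dataclasses.replace(cfg, tag_count_strict=True)
        t5, t6 = tag("ACGT" * 5, s1=5), tag("TGCA" * 5, s1=6)
        assert filter_tags([t5, t6], strict) == [t6]

    def test_idempotent_and_matches_bruteforce(self, cfg, rng):
        tags = [
            tag(random_seq(rng, int(rng.integers(10, 31))), s1=int(rng.integers(0, 12)),
                s2=int(rng.integers(0, 12)))
            for _ in range(1000)
        ]
        kept = filter_tags(tags, cfg)
        assert filter_tags(kept, cfg) == kept
        brute = [
            t for t in tags
            if 18 <= len(t.sequence) <= 25 and max(t.counts.values()) >= 5
        ]
        assert kept == brute


def brute_scan(tagseq, genome, max_mm, max_indel):
    """Exhaustive O(genome x tag^2) placement scan (N never matches)."""
    res = {}
    L, n = len(tagseq), len(genome)

    def neq(a, b):
        return a != b or a == "N" or b == "N"

    for span in range(L - max_indel, L + max_indel + 1):
        gap = abs(span - L)
        for s in range(0, n - span + 1):
            sub = genome[s : s + span]
            best = None
            if span == L:
                best = sum(neq(a, b) for a, b in zip(tagseq, sub))
            elif span > L:  # gap inside the tag (genome longer)
                for j in range(1, L):
                    mm = sum(neq(tagseq[i], sub[i]) for i in range(j))
                    mm += sum(neq(tagseq[i], sub[i + gap]) for i in range(j, L))
                    best = mm if best is None else min(best, mm)
            else:  # gap inside the genome (tag longer)
                for j in range(1, span):
                    mm = sum(neq(tagseq[i], sub[i]) for i in range(j))
                    mm += sum(neq(tagseq[i + gap], sub[i]) for i in range(j, span))
                    best = mm if best is None else min(best, mm)
            if best is not None and best <= max_mm:
                res[(s, span)] = (best, gap)
    return res


class TestAlign:
    def test_exact_substring_single_placement(self, cfg, rng):
        g = random_seq(rng, 2000)
        t = tag(g[500:521])
        alns = align_tags([t], [Contig("c1", g)], cfg)
        exact = [a for a in alns if a.mismatches == 0 and a.indel_len == 0]
        assert len(exact) == 1
        a = exact[0]
        assert (a.start, a.span, a.strand) == (500, 21, "+")

    def test_three_scattered_substitutions_rejected(self, cfg):
        # three substitutions spread across the tag exceed the two-mismatch
        # budget and cannot be absorbed by a single microindel
        g = random_seq(np.random.default_rng(99), 300)
        t = list(g[100:121])
        for i, b in ((3, "A"), (10, "C"), (17, "G")):
            t[i] = b if t[i] != b else ("T" if b != "T" else "A")
        assert align_tags([tag("".join(t))], [Contig("c1", g)], cfg) == []

    def test_scan_matches_bruteforce_oracle(self, cfg, rng):
        g = random_seq(rng, 2000)
        g = g[:700] + "NN" + g[702:]
        contig = Contig("c1", g)
        for _ in range(25):
            L = int(rng.integers(18, 26))
            p = int(rng.integers(0, len(g) - L))
            t = list(g[p : p + L])
            for _ in range(int(rng.integers(0, 4))):
                t[int(rng.integers(0, len(t)))] = "ACGT"[int(rng.integers(0, 4))]
            if rng.random() < 0.5:
                i = int(rng.integers(1, len(t) - 1))
                glen = int(rng.integers(1, 3))
                if rng.random() < 0.5:
                    t = t[:i] + ["ACGT"[int(rng.integers(0, 4))]] * glen + t[i:]
                else:
                    t = t[:i] + t[i + glen :]
            seq = "".join(t)
            got = _scan(encode(seq), encode(g), cfg.sr_max_mm, cfg.sr_indel_max)
            assert got == brute_scan(seq, g, cfg.sr_max_mm, cfg.sr_indel_max)

    def test_reverse_strand_placement_found(self, cfg, rng):
        g = random_seq(rng, 1000)
        t = tag(revcomp(g[300:321]))
        alns = [a for a in align_tags([t], [Contig("c1", g)], cfg)
                if a.mismatches == 0 and a.indel_len == 0]
        assert any(a.strand == "-" and a.start == 300 for a in alns)

    def test_alignment_reconstructs_to_recorded_edits(self, cfg, rng):
        g = random_seq(rng, 1500)
        tags = []
        for _ in range(10):
            L = int(rng.integers(18, 26))
            p = int(rng.integers(0, len(g) - L))
            s = list(g[p : p + L])
            s[int(rng.integers(0, L))] = "ACGT"[int(rng.integers(0, 4))]
            tags.append(tag("".join(s)))
        for a in align_tags(tags, [Contig("c1", g)], cfg):
            sub = g[a.start : a.end]
            query = a.tag.sequence if a.strand == "+" else revcomp(a.tag.sequence)
            if a.indel_len == 0:
                assert sum(x != y for x, y in zip(query, sub)) == a.mismatches
            else:
                assert abs(len(sub) - len(query)) == a.indel_len
                best = min(
                    brute_scan(query, sub, 25, a.indel_len).get((0, len(sub)), (99,))[0]
                    for _ in (0,)
                )
                assert best == a.mismatches


def make_gene(gid, contig, strand, start):
    """A simple gene: 5'UTR 100, CDS 200, intron 100, CDS 200, 3'UTR 100."""
    utr_a = (start, start + 100)
    cds = ((start + 100, start + 300), (start + 400, start + 600))
    utr_b = (start + 600, start + 700)
    u5, u3 = (utr_a, utr_b) if strand == "+" else (utr_b, utr_a)
    return GeneModel(gid, contig, strand, cds_intervals=cds,
                     utr5_intervals=(u5,), utr3_intervals=(u3,))


class TestAnnotate:
    def test_feature_class_assignment(self, cfg):
        gene = make_gene("g1", "c1", "+", 2000)
        assert _class_within(2150, gene) == "gene_body"   # CDS
        assert _class_within(2350, gene) == "gene_body"   # intron
        assert _class_within(2050, gene) == "utr5"
        assert _class_within(2650, gene) == "utr3"
        assert _class_within(1700, gene) == "upstream"    # 300 bp 5' of span
        assert _class_within(2800, gene) == "downstream"

    def test_strand_flips_flank_classes(self, cfg):
        gene = make_gene("g1", "c1", "-", 2000)
        assert _class_within(1700, gene) == "downstream"
        assert _class_within(2800, gene) == "upstream"

    def test_annotation_matches_nested_loop_oracle(self, cfg, rng):
        contig_len = 30_000
        genes = [
            make_gene(f"g{i}", "c1", "+" if i % 2 else "-", 1000 + i * 2500)
            for i in range(10)
        ]
        g = random_seq(rng, contig_len)
        alns = []
        tags = []
        for i in range(120):
            p = int(rng.integers(0, contig_len - 21))
            t = tag(g[p : p + 21] if rng.random() < 0.5 else random_seq(rng, 21),
                    s1=int(rng.integers(1, 20)))
            strand = "+" if rng.random() < 0.5 else "-"
            tags.append(t)
            alns.append(SrnaAlignment(t, "c1", p, 21, strand, 0, 0))
        table = annotate_alignments(alns, genes, {"c1": contig_len}, cfg)

        # oracle: nested loop over placements x genes
        from collections import defaultdict

        want = defaultdict(int)
        for a in alns:
            pos = a.start if a.strand == "+" else a.start + a.span - 1
            hits = []
            for gene in genes:
                s, e = gene.span
                if max(0, s - 500) <= pos < min(contig_len, e + 500):
                    hits.append(gene)
            if not hits:
                for smp, n in a.tag.counts.items():
                    want[(None, "intergenic", smp)] += n
            for gene in hits:
                cls = _class_within(pos, gene)
                for smp, n in a.tag.counts.items():
                    want[(gene.id, cls, smp)] += n
        got = {
            (r.gene_id if isinstance(r.gene_id, str) else None, r.feature_class, r.sample): r.count
            for r in table.itertuples()
        }
        assert got == dict(want)

    def test_counts_invariant_to_tag_order(self, cfg, rng):
        genes = [make_gene("g1", "c1", "+", 1000)]
        ts = [tag(random_seq(rng, 21), s1=i + 1) for i in range(10)]
        alns = [SrnaAlignment(t, "c1", 900 + 30 * i, 21, "+", 0, 0) for i, t in enumerate(ts)]
        t1 = annotate_alignments(alns, genes, {"c1": 5000}, cfg)
        t2 = annotate_alignments(alns[::-1], genes, {"c1": 5000}, cfg)
        assert t1.equals(t2)

    def test_ambiguous_placement_counted_for_both_genes(self, cfg):
        g1 = make_gene("g1", "c1", "+", 1000)
        g2 = make_gene("g2", "c1", "+", 1900)  # extended regions overlap
        t = tag("ACGT" * 6, s1=7)
        a = SrnaAlignment(t, "c1", 1750, 24, "+", 0, 0)
        table = annotate_alignments([a], [g1, g2], {"c1": 5000}, cfg)
        assert set(table["gene_id"]) == {"g1", "g2"}
        assert table["ambiguous"].all()
        dropped = annotate_alignments([a], [g1, g2], {"c1": 5000}, cfg, unique_gene=True)
        assert len(dropped) == 0


class TestLengthDistribution:
    def test_empty_input_all_zero(self):
        hist = length_distribution([], ["s1"])
        assert (hist.to_numpy() == 0).all()

    def test_bins_sum_to_total_reads(self, rng):
        tags = [tag(random_seq(rng, int(rng.integers(18, 26))),
                    s1=int(rng.integers(0, 9)), s2=int(rng.integers(0, 9)))
                for _ in range(200)]
        hist = length_distribution(tags, ["s1", "s2"])
        for s in ("s1", "s2"):
            assert hist[s].sum() == sum(t.counts[s] for t in tags)
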