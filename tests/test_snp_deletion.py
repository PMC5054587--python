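"""Genotype calling rules and deletion-scenario classification."""

import numpy as np
import pytest

from aposeq import snp_deletion as snp
from aposeq import synthetic_data as sd
from aposeq.core_io import AnalysisConfig
from aposeq.snp_deletion import PileupSite


def site(contig="c1", pos=100, **per_sample):
    return PileupSite(contig_id=contig, pos=pos, counts=dict(per_sample))


class TestCallGenotypes:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ({"A": 9, "G": 3}, "AB"),    # maf 0.25: "at least 0.25" is inclusive
            ({"A": 10, "G": 2}, "AA"),   # maf 0.1667 < 0.25, but > hom_err -> see below
            ({"A": 19, "G": 1}, "AA"),   # maf 0.05 <= hom_err_max
            ({"A": 18, "G": 2}, "NA"),   # maf 0.10 in the ambiguous band
            ({}, "--"),
            ({"A": 3}, "NA"),            # depth below min_depth
            ({"A": 30}, "AA"),
        ],
    )
    def test_per_sample_rules(self, cfg, counts, expected):
        if counts == {"A": 10, "G": 2}:
            # maf 1/6 lies between hom_err_max and maf_min -> ambiguous
            expected = "NA"
        calls = snp.call_genotypes([site(s1=counts)], cfg)
        assert calls[0].calls["s1"].genotype == expected

    def test_parent_hemizygous_upgrade(self, cfg):
        # parent homozygous, no second allele anywhere -> A-
        calls = snp.call_genotypes(
            [site(R35={"A": 15}, m115={}, m134={})], cfg, parent_id="R35"
        )
        assert calls[0].calls["R35"].genotype == snp.A_HEMI

    def test_parent_stays_AA_when_second_allele_elsewhere(self, cfg):
        calls = snp.call_genotypes(
            [site(R35={"A": 15}, m115={"A": 6, "G": 6}, m134={})], cfg, parent_id="R35"
        )
        assert calls[0].calls["R35"].genotype == "AA"

    def test_site_is_snp_only_if_some_sample_heterozygous(self, cfg):
        het = snp.call_genotypes([site(s1={"A": 9, "G": 3})], cfg)[0]
        hom = snp.call_genotypes([site(s1={"A": 12})], cfg)[0]
        assert het.is_snp and not hom.is_snp


class TestClassifyScenarios:
    def run(self, cfg, *sites):
        calls = snp.call_genotypes(list(sites), cfg, parent_id="R35")
        return snp.classify_scenarios(calls, "R35", ["m115", "m134"], cfg)

    def test_scenario1_parent_AB_mutants_AA(self, cfg):
        cands = self.run(cfg, site(R35={"A": 8, "G": 8}, m115={"A": 16}, m134={"A": 14}))
        assert [(c.scenario, c.n_support) for c in cands] == [(1, 1)]

    def test_scenario2_parent_hemizygous_mutants_no_reads(self, cfg):
        cands = self.run(cfg, site(R35={"A": 15}, m115={}, m134={}))
        assert [(c.scenario, c.n_support) for c in cands] == [(2, 1)]

    def test_one_heterozygous_mutant_blocks_candidate(self, cfg):
        cands = self.run(cfg, site(R35={"A": 8, "G": 8}, m115={"A": 16}, m134={"A": 7, "G": 7}))
        assert cands == []

    def test_mutant_allele_must_come_from_parent(self, cfg):
        cands = self.run(cfg, site(R35={"A": 8, "G": 8}, m115={"T": 16}, m134={"A": 14}))
        assert cands == []

    def test_scenarios_mutually_exclusive_per_site(self, cfg):
        # the parent patterns AB and A- cannot hold simultaneously
        for s in [
            site(R35={"A": 8, "G": 8}, m115={"A": 16}, m134={"A": 14}),
            site(R35={"A": 15}, m115={}, m134={}),
        ]:
            cands = self.run(cfg, s)
            assert len({c.scenario for c in cands}) <= 1

    def test_stray_mutant_reads_block_scenario2_by_default(self, cfg):
        cands = self.run(cfg, site(R35={"A": 15}, m115={"A": 1}, m134={}))
        assert cands == []


class TestSummarize:
    def test_mixed_scenarios_sum_support(self, cfg):
        calls = snp.call_genotypes(
            [
                site(pos=10, R35={"A": 8, "G": 8}, m115={"A": 16}, m134={"A": 14}),
                site(pos=20, R35={"C": 7, "T": 9}, m115={"C": 16}, m134={"C": 14}),
                site(pos=900, R35={"A": 15}, m115={}, m134={}),
            ],
            cfg,
            parent_id="R35",
        )
        cands = snp.classify_scenarios(calls, "R35", ["m115", "m134"], cfg)
        df = snp.summarize_candidates(cands)
        row = df.iloc[0]
        assert (row.n_scenario1, row.n_scenario2, row.n_support) == (2, 1, 3)

    def test_min_support_drops_weak_units(self, cfg):
        calls = snp.call_genotypes(
            [site(contig="cA", R35={"A": 8, "G": 8}, m115={"A": 16}, m134={"A": 14})],
            cfg,
            parent_id="R35",
        )
        cands = snp.classify_scenarios(calls, "R35", ["m115", "m134"], cfg)
        assert len(snp.summarize_candidates(cands, min_support=2)) == 0

    def test_matches_naive_rescan_on_random_instance(self, cfg, rng):
        # build 50 random sites and recompute the summary by brute force
        sites = []
        for i in range(50):
            def draw():
                kind = rng.integers(0, 4)
                if kind == 0:
                    return {}
                if kind == 1:
                    d = int(rng.integers(8, 30))
                    return {"A": d}
                if kind == 2:
                    d = int(rng.integers(8, 30))
                    return {"A": d - d // 2, "G": d // 2}
                return {"A": int(rng.integers(1, 7))}

            sites.append(
                site(contig=f"c{int(rng.integers(1, 6))}", pos=int(i), R35=draw(),
                     m115=draw(), m134=draw())
            )
        calls = snp.call_genotypes(sites, cfg, parent_id="R35")
        cands = snp.classify_scenarios(calls, "R35", ["m115", "m134"], cfg)
        got = {
            (r.unit_id, r.n_scenario1, r.n_scenario2)
            for r in snp.summarize_candidates(cands).itertuples()
        }

        # independent naive rescan of the stated rules
        def genotype(c, parent_alleles_elsewhere=None):
            d = sum(c.values())
            if d == 0:
                return "--", None, None
            items = sorted(c.items(), key=lambda kv: (-kv[1], kv[0]))
            major = items[0][0]
            minor_n = items[1][1] if len(items) > 1 else 0
            if d < cfg.min_depth:
                return "NA", major, None
            if minor_n / d >= cfg.maf_min:
                return "AB", major, items[1][0]
            if minor_n / d <= cfg.hom_err_max:
                return "AA", major, None
            return "NA", major, None

        expect = {}
        for s in sites:
            gP, majP, minP = genotype(s.counts["R35"])
            muts = [genotype(s.counts[m]) for m in ("m115", "m134")]
            if any(g == "NA" for g, _, _ in muts):
                continue
            if gP == "AB" and all(g == "AA" and mj in (majP, minP) for g, mj, _ in muts):
                k = expect.setdefault(s.contig_id, [0, 0])
                k[0] += 1
            elif gP == "AA" and all(sum(s.counts[m].values()) == 0 for m in ("m115", "m134")):
                second = any(
                    genotype(s.counts[m])[0] == "AB"
                    or (genotype(s.counts[m])[0] == "AA" and genotype(s.counts[m])[1] != majP)
                    for m in ("m115", "m134")
                )
                if not second:
                    k = expect.setdefault(s.contig_id, [0, 0])
                    k[1] += 1
        want = {(u, a, b) for u, (a, b) in expect.items() if a + b >= 1}
        assert got == want


class TestRecovery:
    def test_noise_free_recovery_is_exact(self, cfg, small_world):
        contigs, genes, truth = small_world
        pile = sd.simulate_mutant_pileups(
            contigs, genes, truth, depth_mean=30, error_rate=0.0, seed=21
        )
        calls = snp.call_genotypes(pile, cfg, parent_id="R35")
        clen = {c.id: len(c) for c in contigs}
        lookup = snp.gene_lookup(genes, clen)
        cands = snp.classify_scenarios(calls, "R35", ["m115", "m134"], cfg, lookup)
        found = {(c.unit_id, c.scenario) for c in cands}
        want = {
            (g, 1 if lbl == sd.HET_LOSS else 2)
            for g, lbl in truth.deletions_common_to(["m115", "m134"]).items()
        }
        assert found == want

    def test_scenario2_gene_emits_no_mutant_reads(self, cfg, small_world):
        contigs, genes, truth = small_world
        pile = sd.simulate_mutant_pileups(contigs, genes, truth, seed=3)
        s2_genes = {
            g for g, lbl in truth.deleted_genes["m115"].items() if lbl == sd.HEMI_LOSS
        }
        clen = {c.id: len(c) for c in contigs}
        lookup = snp.gene_lookup(genes, clen)
        for p in pile:
            if lookup(p.contig_id, p.pos) in s2_genes:
                assert p.depth("m115") == 0 and p.depth("m134") == 0

    def test_error_free_scenario1_mutant_has_zero_minor_count(self, cfg, small_world):
        contigs, genes, truth = small_world
        pile = sd.simulate_mutant_pileups(contigs, genes, truth, error_rate=0.0, seed=4)
        s1_genes = {
            g for g, lbl in truth.deleted_genes["m115"].items() if lbl == sd.HET_LOSS
        }
        clen = {c.id: len(c) for c in contigs}
        lookup = snp.gene_lookup(genes, clen)
        for p in pile:
            if lookup(p.contig_id, p.pos) in s1_genes:
                assert len(p.counts["m115"]) <= 1  # single retained allele only
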