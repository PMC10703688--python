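"""Allelic mass balance: sums, infinite sites, AHR loose-end pairs."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from gbalance.allelic import (balance_allelic, find_ahr_loose_pairs,
                              split_minor_allele)
from gbalance.graph import build_graph
from gbalance.profiles import SnpCounts
from gbalance.simulate import SimConfig, simulate
from gbalance.solver import FitConfig, fit_pipeline


def diploid_graph(length=4_000_000, cn=2, breakpoints=None):
    g = build_graph({"chr1": length}, {"chr1": breakpoints or []}, [])
    for s in g.segments:
        s.cn = cn
    for e in g.edges:
        e.cn = 0 if e.kind == "loose" else cn
    return g


def snp_table(pos, c1, c2, alpha=0.95, tau=2.0):
    return SnpCounts(pd.DataFrame({"chrom": "chr1", "pos": pos,
                                   "count_hap1": c1, "count_hap2": c2}),
                     alpha=alpha, tau=tau)


def crossover_snps(rng, length=4_000_000, xover=2_000_000, depth=40):
    pos = np.sort(rng.choice(length, length // 1500, replace=False))
    right = pos >= xover
    c1 = np.where(right, rng.poisson(2 * depth - 2, len(pos)),
                  rng.poisson(depth, len(pos)))
    c2 = np.where(right, rng.poisson(2, len(pos)),
                  rng.poisson(depth, len(pos)))
    return snp_table(pos, c1, c2)


def assert_allelic_invariants(ag):
    """Allelic sums equal totals; infinite sites never violated."""
    g = ag.parent
    for i, s in enumerate(g.segments):
        assert ag.cn_a[i] + ag.cn_b[i] == s.cn
        assert ag.cn_a[i] >= 0 and ag.cn_b[i] >= 0
    for eid, imgs in ag.images.items():
        e = g.edges[eid]
        if e.kind == "variant":
            assert sum(imgs.values()) == e.cn
            assert sum(1 for v in imgs.values() if v > 0) <= 1
        else:
            assert sum(imgs.values()) <= e.cn
            # at most one incoming / outgoing image per allelic vertex
            for h in ("A", "B"):
                assert sum(1 for (h1, h2), v in imgs.items()
                           if h2 == h and v > 0) <= 1
                assert sum(1 for (h1, h2), v in imgs.items()
                           if h1 == h and v > 0) <= 1


class TestBalanceAllelic:
    def test_heterozygous_diploid_is_one_one(self, rng):
        g = diploid_graph(breakpoints=[2_000_000])
        pos = np.arange(1000, 4_000_000, 2000)
        snps = snp_table(pos, rng.poisson(40, len(pos)),
                         rng.poisson(40, len(pos)))
        ag = balance_allelic(g, snps)
        assert ag.cn_a == [1, 1] and ag.cn_b == [1, 1]
        assert ag.loose == []
        assert_allelic_invariants(ag)

    def test_single_haplotype_duplication(self, rng):
        # total 3 with one duplicated homolog: variant edge on that homolog
        from gbalance.graph import Breakend, Junction
        j = Junction(Breakend("chr1", 3_000_000, "+"),
                     Breakend("chr1", 1_000_000, "-"))
        g = build_graph({"chr1": 4_000_000},
                        {"chr1": [1_000_000, 3_000_000]}, [j])
        for s, cn in zip(g.segments, (2, 3, 2)):
            s.cn = cn
        for _, e in g.edges_of_kind("variant"):
            e.cn = 1
        for _, e in g.edges_of_kind("telomere"):
            e.cn = 2
        for _, e in g.edges_of_kind("reference"):
            e.cn = 2
        for _, e in g.edges_of_kind("loose"):
            e.cn = 0
        pos = np.arange(1000, 4_000_000, 2000)
        mid = (pos >= 1_000_000) & (pos < 3_000_000)
        snps = snp_table(pos, rng.poisson(np.where(mid, 78, 40)),
                         rng.poisson(40, len(pos)))
        ag = balance_allelic(g, snps)
        assert (ag.cn_a[1], ag.cn_b[1]) == (2, 1)
        (imgs,) = [im for eid, im in ag.images.items()
                   if g.edges[eid].kind == "variant"]
        assert imgs[("A", "A")] == 1  # junction lives on the gained homolog
        assert_allelic_invariants(ag)

    def test_ahr_crossover_yields_copy_neutral_pair(self, rng):
        g = diploid_graph()
        snps = crossover_snps(rng)
        g2 = split_minor_allele(g, snps)
        assert len(g2.segments) == 2
        ag = balance_allelic(g2, snps)
        assert sorted((ag.cn_a[i], ag.cn_b[i]) for i in range(2)) == \
            [(1, 1), (2, 0)]
        pairs = find_ahr_loose_pairs(ag)
        assert len(pairs) == 1
        l1, l2 = pairs[0]
        assert l1.hap != l2.hap
        assert abs(l1.breakend.pos - 2_000_000) < 50_000
        assert_allelic_invariants(ag)

    def test_unrearranged_genome_has_no_pairs(self, rng):
        g = diploid_graph(breakpoints=[2_000_000])
        pos = np.arange(1000, 4_000_000, 2000)
        snps = snp_table(pos, rng.poisson(40, len(pos)),
                         rng.poisson(40, len(pos)))
        ag = balance_allelic(g, snps)
        assert find_ahr_loose_pairs(ag) == []


class TestSplitMinorAllele:
    def test_uniform_minor_counts_not_split(self, rng):
        g = diploid_graph()
        pos = np.arange(1000, 4_000_000, 2000)
        snps = snp_table(pos, rng.poisson(40, len(pos)),
                         rng.poisson(40, len(pos)))
        assert len(split_minor_allele(g, snps).segments) == 1

    def test_small_segment_not_split(self, rng):
        g = diploid_graph(length=800_000)
        snps = crossover_snps(rng, length=800_000, xover=400_000)
        assert len(split_minor_allele(g, snps).segments) == 1

    def test_sparse_snps_not_split(self):
        g = diploid_graph()
        snps = snp_table([100, 200_000, 3_500_000], [40, 40, 80], [40, 40, 2])
        assert len(split_minor_allele(g, snps).segments) == 1

    def test_split_preserves_total_cn_and_balance(self, rng):
        from gbalance.graph import validate_balance
        g = diploid_graph()
        g2 = split_minor_allele(g, crossover_snps(rng))
        assert [s.cn for s in g2.segments] == [2, 2]
        assert validate_balance(g2) == []


class TestSimulatedInvariants:
    def test_allelic_fit_on_simulated_genomes(self):
        cfg = SimConfig(chrom_lengths={"chr1": 6_000_000}, n_junctions=5,
                        nahr_prevalence=0.0, n_homology_pairs=0, ploidy=2.0,
                        purity=0.9)
        for seed in (5, 6):
            truth, prof = simulate(cfg, seed)
            depth = prof.tumor_depth(truth.alpha, truth.tau_realized)
            fit = fit_pipeline(depth, prof.junction_calls)
            g2 = split_minor_allele(fit.graph, prof.snps)
            ag = balance_allelic(g2, prof.snps)
            assert_allelic_invariants(ag)

    def test_allelic_cn_recovery_up_to_homolog_swap(self):
        from gbalance.benchmark import rebin, score_cn
        cfg = SimConfig(chrom_lengths={"chr1": 6_000_000}, n_junctions=4,
                        nahr_prevalence=0.0, n_homology_pairs=0, ploidy=2.0,
                        purity=0.8)
        truth, prof = simulate(cfg, 9)
        depth = prof.tumor_depth(truth.alpha, truth.tau_realized)
        fit = fit_pipeline(depth, prof.junction_calls)
        g2 = split_minor_allele(fit.graph, prof.snps)
        ag = balance_allelic(g2, prof.snps)
        nb = 6_000_000 // 1000
        fa, fb = np.zeros(nb), np.zeros(nb)
        for i, s in enumerate(ag.parent.segments):
            sl = slice(s.start // 1000, s.end // 1000)
            fa[sl], fb[sl] = ag.cn_a[i], ag.cn_b[i]
        _, ta, tb = truth.cn_bins("chr1", 1000)
        rmse = score_cn(None, None,
                        {"chr1": (rebin(fa, 10), rebin(fb, 10))},
                        {"chr1": (rebin(ta, 10), rebin(tb, 10))})
        assert rmse < 0.3
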