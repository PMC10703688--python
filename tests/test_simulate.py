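"""Simulator: determinism, mass conservation, emission statistics."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from gbalance.simulate import (SimConfig, _end_bnd, _start_bnd, emit_profiles,
                               simulate, simulate_genome, simulate_karyotype)


CFG = SimConfig(chrom_lengths={"chr1": 5_000_000, "chr2": 5_000_000},
                n_junctions=20)


class TestDeterminism:
    def test_seed_fixes_output_stream(self):
        t1, p1 = simulate(CFG, 123)
        t2, p2 = simulate(CFG, 123)
        assert t1.walks == t2.walks
        assert [j.name for j in t1.junctions] == [j.name for j in t2.junctions]
        for c in p1.tumor_raw:
            assert np.array_equal(p1.tumor_raw[c], p2.tumor_raw[c])
        assert p1.snps.table.equals(p2.snps.table)

    def test_different_seeds_differ(self):
        t1, _ = simulate(CFG, 1)
        t2, _ = simulate(CFG, 2)
        assert t1.walks != t2.walks


class TestGenome:
    def test_snp_density_binomial_range(self, rng):
        cfg = SimConfig(chrom_lengths={"chr1": 15_000_000, "chr2": 15_000_000})
        g = simulate_genome(cfg, rng)
        n = sum(len(p) for p in g.snps.values())
        # 30 Mb at 1/1500: 20,000 +- ~4.3 s.d. of 140
        assert abs(n - 20_000) <= 600

    def test_homology_registry_populated(self, rng):
        g = simulate_genome(SimConfig(n_homology_pairs=8), rng)
        assert len(g.homology) == 8
        assert (g.homology.pos2 - g.homology.pos1 > 10_000).all()

    def test_planted_repeats_present_in_sequence(self, rng):
        cfg = SimConfig(chrom_lengths={"chr1": 2_000_000},
                        n_homology_pairs=2, homology_sep_range=(5e4, 5e5),
                        with_sequence=True)
        g = simulate_genome(cfg, rng)
        for r in g.homology.itertuples():
            s1 = g.sequences[r.chrom1][r.pos1:r.pos1 + 600]
            s2 = g.sequences[r.chrom2][r.pos2:r.pos2 + 600]
            ident = np.mean([a == b for a, b in zip(s1, s2)])
            assert ident >= 0.96


class TestKaryotype:
    def test_no_events_stays_diploid(self, rng):
        cfg = dataclasses.replace(CFG, n_junctions=0, nahr_prevalence=0.0,
                                  ploidy=2.0)
        g = simulate_genome(cfg, rng)
        t = simulate_karyotype(cfg, g, rng)
        assert t.junctions == []
        for c in cfg.chrom_lengths:
            _, a, b = t.atoms(c)
            assert (a == 1).all() and (b == 1).all()

    def test_mass_conservation(self, rng):
        for seed in (3, 4, 5):
            t, _ = simulate(CFG, seed)
            total = sum(e[2] - e[1] for w in t.walks for e in w)
            assert total / CFG.haploid_size == pytest.approx(t.tau_realized)
            assert abs(t.tau_realized - t.tau_target) <= 0.45

    def test_junction_breakends_in_walks(self):
        # structural soundness: every truth junction is an adjacency of
        # oriented segment ends in at least one walk
        t, _ = simulate(CFG, 77)
        adj = set()
        for w in t.walks:
            for e1, e2 in zip(w[:-1], w[1:]):
                adj.add(frozenset((b.chrom, b.pos, b.strand)
                                  for b in (_end_bnd(e1), _start_bnd(e2))))
        for j in t.junctions:
            key = frozenset((b.chrom, b.pos, b.strand) for b in j.breakends)
            assert key in adj

    def test_nahr_junctions_lie_on_registered_pairs(self):
        cfg = dataclasses.replace(CFG, n_junctions=40, nahr_prevalence=0.10,
                                  n_homology_pairs=10)
        t, _ = simulate(cfg, 5)
        nahr = [j for j in t.junctions if j.mechanism == "NAHR"]
        assert nahr
        hom = t.genome.homology
        mids = set(hom.pos1 + 300) | set(hom.pos2 + 300)
        for j in nahr:
            assert j.b1.pos in mids and j.b2.pos in mids

    def test_ahr_event_truth_structure(self, rng):
        cfg = SimConfig(chrom_lengths={"chr1": 8_000_000}, n_junctions=0,
                        nahr_prevalence=0.0, ploidy=2.0, n_ahr_events=1)
        g = simulate_genome(cfg, rng)
        t = simulate_karyotype(cfg, g, rng)
        (u,) = t.upd_events
        assert u.mechanism == "AHR_UPD"
        bounds, a, b = t.atoms("chr1")
        mid = (bounds[:-1] + bounds[1:]) / 2
        inside = (mid > u.start) & (mid < u.end)
        assert ((a[inside] + b[inside]) == 2).all()
        assert (np.minimum(a, b)[inside] == 0).all()
        assert (np.minimum(a, b)[~inside] == 1).all()
        assert t.junctions == []  # crossover leaves no junction

    def test_pupd_event_collars(self, rng):
        cfg = SimConfig(chrom_lengths={"chr1": 8_000_000}, n_junctions=2,
                        nahr_prevalence=0.0, ploidy=2.0, n_pupd_events=1,
                        events_avoid_occupied=True)
        g = simulate_genome(cfg, rng)
        t = simulate_karyotype(cfg, g, rng)
        (u,) = [u for u in t.upd_events if u.mechanism == "P_UPD"]
        bounds, a, b = t.atoms("chr1")
        mid = (bounds[:-1] + bounds[1:]) / 2
        inside = (mid > u.start) & (mid < u.end)
        assert ((a + b)[inside] == 2).all()
        # flanking collars carry total CN 1
        left = np.nonzero(bounds[1:] == u.start)[0]
        right = np.nonzero(bounds[:-1] == u.end)[0]
        assert (a + b)[left[0]] == 1 and (a + b)[right[0]] == 1


class TestEmission:
    def test_mean_depth_matches_coverage(self, rng):
        cfg = dataclasses.replace(CFG, n_junctions=0, ploidy=2.0, purity=1.0,
                                  bias_sigma=0.0)
        t, p = simulate(cfg, 11)
        mean = np.mean(np.concatenate(list(p.tumor_raw.values())))
        expect = 80.0 * 1000 / 150
        assert abs(mean - expect) / expect < 0.01

    def test_zero_tumor_signal_matches_normal(self):
        # alpha -> 0 limit: tumor profile statistically identical to a
        # diploid normal at matched coverage
        cfg = dataclasses.replace(CFG, n_junctions=10, purity=1e-9,
                                  tumor_coverage=40.0, ploidy=2.0)
        t, p = simulate(cfg, 13)
        ks = stats.ks_2samp(p.tumor_raw["chr1"][:1000],
                            p.normal_raw["chr1"][:1000])
        assert ks.pvalue > 0.01

    def test_detection_rate_proportional_to_purity(self):
        cfg = dataclasses.replace(CFG, n_junctions=40, purity=0.6,
                                  detection_s=1.0)
        frac = []
        for seed in range(12):
            t, _ = simulate(cfg, 100 + seed)
            frac.append(t.detected.mean())
        n = sum(len(t.detected) for _ in [0])
        assert np.mean(frac) == pytest.approx(0.6, abs=3 * 0.5 / np.sqrt(480))

    def test_withhold_override(self):
        cfg = dataclasses.replace(CFG, n_junctions=40, withhold_frac=0.3)
        fracs = [simulate(cfg, s)[0].detected.mean() for s in range(8)]
        assert np.mean(fracs) == pytest.approx(0.7, abs=0.1)
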