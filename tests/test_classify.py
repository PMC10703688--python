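"""Mechanistic breakend classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbalance.classify import (classify_copy, classify_reciprocal,
                               classify_telomere_repeat, classify_upd,
                               nahr_pair)
from gbalance.graph import Breakend
from gbalance.solver import FitConfig, balance_total

from conftest import make_graph


class TestReciprocal:
    def test_opposite_pair_within_10kb(self):
        bs = [Breakend("chr1", 1_000_000, "+"), Breakend("chr1", 1_005_000, "-")]
        assert classify_reciprocal(bs) == [True, True]

    def test_lone_breakend(self):
        assert classify_reciprocal([Breakend("chr1", 1_000_000, "+")]) == [False]

    def test_boundary_exclusive(self):
        bs = [Breakend("chr1", 1_000_000, "+"), Breakend("chr1", 1_010_500, "-")]
        assert classify_reciprocal(bs) == [False, False]

    def test_same_orientation_not_reciprocal(self):
        bs = [Breakend("chr1", 1_000_000, "+"), Breakend("chr1", 1_002_000, "+")]
        assert classify_reciprocal(bs) == [False, False]

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.integers(0, 5_000_000),
                              st.sampled_from("+-")), min_size=2, max_size=8))
    def test_symmetry(self, items):
        bs = [Breakend("chr1", p, s) for p, s in items]
        flags = classify_reciprocal(bs)
        # b1 reciprocal-to b2 implies b2 reciprocal-to b1: rebuild pairwise
        for i, b in enumerate(bs):
            partner = [j for j, o in enumerate(bs) if j != i
                       and o.strand != b.strand and abs(o.pos - b.pos) <= 10_000]
            assert flags[i] == bool(partner)


class TestClassifyCopy:
    def fitted_step(self):
        vals = np.concatenate([np.full(3000, 3.0), np.full(3000, 2.0),
                               np.full(4000, 2.0)])
        g, _ = make_graph({"chr1": vals}, {"chr1": [3_000_000, 6_000_000]})
        return balance_total(g, FitConfig(lam=1)).graph

    def test_cn_step_is_copy_altered(self):
        g = self.fitted_step()
        assert classify_copy(Breakend("chr1", 3_000_000, "+"), g) == "copy_altered"

    def test_uniform_interface_is_copy_neutral(self):
        g = self.fitted_step()
        assert classify_copy(Breakend("chr1", 6_000_000, "+"), g) == "copy_neutral"

    def test_interior_of_merged_segment_is_neutral(self):
        g = self.fitted_step()
        assert classify_copy(Breakend("chr1", 8_000_000, "-"), g) == "copy_neutral"

    def test_chromosome_end_compared_to_ploidy(self):
        g = self.fitted_step()
        g.meta["ploidy"] = 2.0
        assert classify_copy(Breakend("chr1", 0, "-"), g) == "copy_altered"
        assert classify_copy(Breakend("chr1", 10_000_000, "+"), g) == \
            "copy_neutral"


class TestNahr:
    HOM = pd.DataFrame([("chr1", 1_000_000, "chr1", 1_500_000, "+", 0.98)],
                       columns=["chrom1", "pos1", "chrom2", "pos2",
                                "strand2", "identity"])

    def test_deletion_breakends_flanking_direct_repeats(self):
        b1 = Breakend("chr1", 1_000_300, "+")
        b2 = Breakend("chr1", 1_500_300, "-")
        assert nahr_pair(b1, b2, self.HOM)

    def test_no_homology_in_window(self):
        b1 = Breakend("chr1", 3_000_000, "+")
        b2 = Breakend("chr1", 3_500_000, "-")
        assert not nahr_pair(b1, b2, self.HOM)

    def test_wrong_strand_geometry_rejected(self):
        # direct repeats cannot mediate a same-orientation breakend pair
        b1 = Breakend("chr1", 1_000_300, "+")
        b2 = Breakend("chr1", 1_500_300, "+")
        assert not nahr_pair(b1, b2, self.HOM)

    def test_inverted_repeats_pair_same_orientation(self):
        hom = self.HOM.assign(strand2="-")
        b1 = Breakend("chr1", 1_000_300, "+")
        b2 = Breakend("chr1", 1_500_300, "+")
        assert nahr_pair(b1, b2, hom)

    def test_low_false_flag_rate_on_simulated_non_nahr(self):
        from gbalance.simulate import SimConfig, simulate
        cfg = SimConfig(chrom_lengths={"chr1": 5_000_000, "chr2": 5_000_000},
                        n_junctions=40, nahr_prevalence=0.0,
                        n_homology_pairs=10)
        flagged = total = 0
        for seed in (1, 2, 3):
            truth, _ = simulate(cfg, seed)
            hom = truth.genome.homology
            for j in truth.junctions:
                assert j.mechanism != "NAHR"
                total += 1
                flagged += bool(nahr_pair(j.b1, j.b2, hom))
        assert flagged / total < 0.02


class TestClassifyUpd:
    def segs(self, rows):
        return [("chr1", a, b, t, m) for a, b, t, m in rows]

    def test_adjacent_to_balanced_two_is_ahr(self):
        calls = classify_upd(self.segs([(0, 5, 2, 1), (5, 9, 2, 0)]))
        assert [c.mechanism for c in calls] == ["AHR_UPD"]

    def test_otherwise_p_upd(self):
        calls = classify_upd(self.segs([(0, 4, 3, 1), (4, 8, 2, 0),
                                        (8, 9, 1, 0)]))
        assert [c.mechanism for c in calls] == ["P_UPD"]

    def test_whole_chromosome_upd_is_p_upd(self):
        calls = classify_upd(self.segs([(0, 9, 2, 0)]))
        assert [c.mechanism for c in calls] == ["P_UPD"]

    def test_partition_is_exhaustive(self):
        segs = self.segs([(0, 2, 2, 0), (2, 4, 2, 1), (4, 6, 2, 0),
                          (6, 8, 1, 0), (8, 9, 2, 0)])
        calls = classify_upd(segs)
        assert len(calls) == 3  # every (2,0) segment got exactly one label
        assert {(c.start, c.mechanism) for c in calls} == \
            {(0, "AHR_UPD"), (4, "AHR_UPD"), (8, "P_UPD")}


class TestTelomereRepeat:
    def test_canonical_g_rich(self):
        assert classify_telomere_repeat("TTAGGG" * 3) == "GRTR_pos"

    def test_canonical_c_rich(self):
        assert classify_telomere_repeat("CCCTAA" * 3) == "CRTR_pos"

    def test_short_sequence_negative(self):
        assert classify_telomere_repeat("TTAGGGTTAGGG") == "negative"

    def test_random_sequence_negative(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        assert classify_telomere_repeat(seq) in ("negative",)

    def test_both_panels_inconsistent(self):
        seq = "TTAGGG" * 3 + "ACGT" + "CCCTAA" * 3
        with pytest.raises(ValueError, match="both"):
            classify_telomere_repeat(seq)

    def test_reverse_strand_flips_class(self):
        assert classify_telomere_repeat("TTAGGG" * 3, strand="-") == "CRTR_pos"

    @settings(derandomize=True, max_examples=12)
    @given(st.integers(0, 5), st.sampled_from(["TTAGGG", "CCCTAA"]))
    def test_cyclic_rotation_closure(self, k, unit):
        # every rotation frame of a tandem repeat array is matched
        arr = (unit * 4)[k:k + 18]
        want = "GRTR_pos" if unit == "TTAGGG" else "CRTR_pos"
        assert classify_telomere_repeat(arr) == want
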