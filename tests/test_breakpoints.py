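import pytest
from hypothesis import given, settings, strategies as hst

from hicbreaks.breakpoints import (BreakpointPair, Breakpoint, UNKNOWN,
                                   annotate_pair_origins,
                                   assign_breakpoint_origin,
                                   assign_pair_origin,
                                   block_order_from_table,
                                   classify_reciprocal, find_breakpoints,
                                   pair_breakpoints)
from hicbreaks.simulate import (Event, ScenarioConfig,
                                simulate_rearrangement_scenario)

from helpers import (BLOCK_LEN, GAP_LEN, broken_adjacencies_oracle,
                     make_order, pair_coord_set, truth_coord_set)


def orders_from_truth(gt):
    t = gt.block_tables["AB"]
    return (block_order_from_table(t, "a", gt.chrom_sizes["A"]),
            block_order_from_table(t, "b", gt.chrom_sizes["B"]))


class TestFindBreakpoints:
    def test_identical_orders_no_internal_breakpoints(self):
        seq = [("A", 1), ("B", 1), ("C", 1)]
        bps = find_breakpoints(make_order(seq), make_order(seq),
                               include_telomeres=False)
        assert bps == []

    def test_identical_orders_telomeres_only(self):
        seq = [("A", 1), ("B", 1)]
        bps = find_breakpoints(make_order(seq), make_order(seq))
        assert len(bps) == 2
        assert all(bp.is_telomere for bp in bps)
        assert {bp.start for bp in bps} == {0, 2 * (BLOCK_LEN + GAP_LEN) + GAP_LEN}

    def test_single_inversion_two_breakpoints_each_genome(self):
        a = make_order([("A", 1), ("B", 1), ("C", 1)])
        b = make_order([("A", 1), ("B", -1), ("C", 1)])
        bps_a = find_breakpoints(a, b, include_telomeres=False)
        bps_b = find_breakpoints(b, a, include_telomeres=False)
        assert [(bp.left_block, bp.right_block) for bp in bps_a] == \
            [("A", "B"), ("B", "C")]
        assert [(bp.left_block, bp.right_block) for bp in bps_b] == \
            [("A", "B"), ("B", "C")]
        # breakpoint regions are the gaps between consecutive blocks
        assert bps_a[0].start == GAP_LEN + BLOCK_LEN
        assert bps_a[0].end == bps_a[0].start + GAP_LEN

    def test_swapped_blocks_internal_plus_telomeres(self):
        a = make_order([("A", 1), ("B", 1)])
        b = make_order([("B", 1), ("A", 1)])
        bps = find_breakpoints(a, b)
        internal = [bp for bp in bps if not bp.is_telomere]
        assert [(bp.left_block, bp.right_block) for bp in internal] == \
            [("A", "B")]
        assert sum(bp.is_telomere for bp in bps) == 2

    def test_jointly_reversed_run_is_not_broken(self):
        a = make_order([("A", 1), ("B", 1), ("C", 1)])
        b = make_order([("C", -1), ("B", -1), ("A", -1)])
        assert find_breakpoints(a, b, include_telomeres=False) == []

    def test_missing_block_id_rejected_with_name(self):
        a = make_order([("A", 1), ("B", 1)])
        b = make_order([("A", 1), ("Z", 1)])
        with pytest.raises(ValueError, match="B.*Z|Z.*B"):
            find_breakpoints(a, b)

    def test_duplicated_block_id_rejected(self):
        from hicbreaks.breakpoints import BlockOrder, OrientedBlock
        blocks = [OrientedBlock("A", "chr1", 0, 10, 1),
                  OrientedBlock("A", "chr1", 20, 30, 1)]
        with pytest.raises(ValueError, match="A"):
            BlockOrder(blocks)

    @given(hst.permutations(list("ABCDE")),
           hst.lists(hst.sampled_from([1, -1]), min_size=5, max_size=5))
    @settings(max_examples=60, deadline=None)
    def test_matches_bigram_oracle(self, perm, strands):
        seq_a = [(c, 1) for c in "ABCDE"]
        seq_b = list(zip(perm, strands))
        a = make_order(seq_a)
        b = make_order(seq_b)
        bps = find_breakpoints(a, b, include_telomeres=False)
        got = {(bp.left_block, bp.right_block) for bp in bps}
        want = {(seq_a[k][0], seq_a[k + 1][0])
                for k in broken_adjacencies_oracle(seq_a, seq_b)}
        assert got == want


class TestPairing:
    def test_single_inversion_one_reciprocal_pair(self, fig7_truth):
        pairs = pair_breakpoints(*orders_from_truth(fig7_truth))
        non_tel = [p for p in pairs
                   if not (p.bp1.is_telomere or p.bp2.is_telomere)]
        assert len(non_tel) == 1
        (p,) = non_tel
        # both mouse breakpoints link the same two human breakpoints
        assert p.multiplicity == 2
        assert p.reciprocal

    def test_breakpoint_reuse_shared_member_nonreciprocal(self, fig8_truth):
        pairs = pair_breakpoints(*orders_from_truth(fig8_truth))
        non_tel = [p for p in pairs
                   if not (p.bp1.is_telomere or p.bp2.is_telomere)]
        shared = {}
        for p in non_tel:
            for bp in (p.bp1, p.bp2):
                shared[bp] = shared.get(bp, 0) + 1
        assert max(shared.values()) >= 2
        reused = [p for p in non_tel
                  if shared[p.bp1] > 1 or shared[p.bp2] > 1]
        assert len(reused) >= 2
        assert all(not p.reciprocal for p in reused)

    def test_zero_breakpoints_zero_pairs(self):
        seq = [("A", 1), ("B", 1), ("C", 1)]
        pairs = pair_breakpoints(make_order(seq), make_order(seq),
                                 include_telomeres=False)
        assert pairs == []

    def test_pair_count_bounded_by_partner_breakpoints(self, fig8_truth):
        order_a, order_b = orders_from_truth(fig8_truth)
        pairs = pair_breakpoints(order_a, order_b)
        bps_b = find_breakpoints(order_b, order_a, include_telomeres=False)
        assert len(pairs) <= len(bps_b)

    def test_members_ordered_for_determinism(self, fig8_truth):
        pairs = pair_breakpoints(*orders_from_truth(fig8_truth))
        for p in pairs:
            assert p.bp1.sort_key() <= p.bp2.sort_key()


class TestClassifyReciprocal:
    def _bp(self, name, start):
        return Breakpoint("A", "chr1", start, start + 10, name, name + "x")

    def test_single_isolated_pair_reciprocal(self):
        pair = BreakpointPair(self._bp("a", 0), self._bp("b", 100))
        (out,) = classify_reciprocal([pair])
        assert out.reciprocal

    def test_chain_all_nonreciprocal(self):
        x, y, z, w = (self._bp(n, k * 100)
                      for k, n in enumerate("xyzw"))
        pairs = [BreakpointPair(x, y), BreakpointPair(y, z),
                 BreakpointPair(z, w)]
        out = classify_reciprocal(pairs)
        assert [p.reciprocal for p in out] == [False, False, False]

    def test_mixed_isolated_and_shared(self):
        a, b, x, y, z = (self._bp(n, k * 100)
                         for k, n in enumerate("abxyz"))
        pairs = classify_reciprocal([
            BreakpointPair(a, b), BreakpointPair(x, y), BreakpointPair(y, z)])
        flags = {(p.bp1.left_block, p.bp2.left_block): p.reciprocal
                 for p in pairs}
        assert flags[("a", "b")] is True
        assert flags[("x", "y")] is False
        assert flags[("y", "z")] is False


class TestOrigin:
    def _bp(self, start=1000, end=2000):
        return Breakpoint("A", "chr1", start, end, "L", "R")

    def _partners(self, chrom="chrM1"):
        return (Breakpoint("B", chrom, 100, 200, "P", "Q"),
                Breakpoint("B", chrom, 500, 600, "Q", "R"))

    def test_truth_table(self):
        bp = self._bp()
        p = self._partners()
        hd_hit = {"chr1": [(1500, 1600)]}
        hd_miss = {"chr1": [(5000, 6000)]}
        md_both = {"chrM1": [(150, 160), (550, 560)]}
        md_one = {"chrM1": [(150, 160)]}
        md_none = {}
        assert assign_breakpoint_origin(bp, p, hd_hit, md_none) == "human"
        assert assign_breakpoint_origin(bp, p, hd_miss, md_both) == "mouse"
        assert assign_breakpoint_origin(bp, p, hd_hit, md_one) == UNKNOWN
        assert assign_breakpoint_origin(bp, p, hd_hit, md_both) == UNKNOWN
        assert assign_breakpoint_origin(bp, p, hd_miss, md_one) == UNKNOWN
        assert assign_breakpoint_origin(bp, p, hd_miss, md_none) == UNKNOWN

    def test_missing_partners_unknown(self):
        assert assign_breakpoint_origin(self._bp(), None, {}, {}) == UNKNOWN

    def test_pair_origin_rules(self):
        assert assign_pair_origin("human", "human") == "human"
        assert assign_pair_origin("mouse", "mouse") == "mouse"
        assert assign_pair_origin("human", "mouse") == UNKNOWN
        assert assign_pair_origin("mouse", UNKNOWN) == UNKNOWN
        assert assign_pair_origin(UNKNOWN, UNKNOWN) == UNKNOWN

    @pytest.mark.parametrize("lineage", ["A", "B"])
    def test_single_event_origin_recovered_with_outgroup(self, lineage):
        cfg = ScenarioConfig(n_blocks=4, seed=0)
        gt = simulate_rearrangement_scenario(
            cfg, events=[Event(lineage, "inversion", 1, 2)])
        order_a, order_b = orders_from_truth(gt)
        pairs = pair_breakpoints(order_a, order_b)
        t_ao, t_bo = gt.block_tables["AO"], gt.block_tables["BO"]
        hd = find_breakpoints(block_order_from_table(t_ao, "a"),
                              block_order_from_table(t_ao, "b"),
                              include_telomeres=False)
        md = find_breakpoints(block_order_from_table(t_bo, "a"),
                              block_order_from_table(t_bo, "b"),
                              include_telomeres=False)
        hd_map = {bp.chrom: [] for bp in hd}
        for bp in hd:
            hd_map[bp.chrom].append((bp.start, bp.end))
        md_map = {bp.chrom: [] for bp in md}
        for bp in md:
            md_map[bp.chrom].append((bp.start, bp.end))
        annotate_pair_origins(pairs, order_a, order_b, hd_map, md_map,
                              label_a="A", label_b="B")
        recip = [p for p in pairs if p.reciprocal
                 and not (p.bp1.is_telomere or p.bp2.is_telomere)]
        assert recip, "single interior inversion must give a reciprocal pair"
        assert all(p.origin == lineage for p in recip)


class TestTruthEquivalence:
    """Module output vs the signed-word ground truth of the simulator."""

    @given(hst.integers(3, 8), hst.integers(0, 10_000))
    @settings(max_examples=80, deadline=None)
    def test_random_scenarios_match_truth(self, n_blocks, seed):
        rng_cfg = ScenarioConfig(
            n_blocks=n_blocks, seed=seed,
            n_inversions_A=seed % 2 + (seed // 7) % 2,
            n_translocations_A=(seed // 3) % 2,
            n_inversions_B=(seed // 5) % 2,
            n_translocations_B=(seed // 11) % 2)
        gt = simulate_rearrangement_scenario(rng_cfg)
        pairs = pair_breakpoints(*orders_from_truth(gt))
        assert pair_coord_set(pairs) == truth_coord_set(gt.true_pairs)
        got_recip = {
            tuple(sorted([(p.bp1.chrom, p.bp1.start, p.bp1.end),
                          (p.bp2.chrom, p.bp2.start, p.bp2.end)])): p.reciprocal
            for p in pairs}
        want_recip = {
            tuple(sorted([tuple(p["bp1"]), tuple(p["bp2"])])): p["reciprocal"]
            for p in gt.true_pairs}
        assert got_recip == want_recip
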