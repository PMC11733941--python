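import itertools

import pytest

from dmdgp.encoding import encode
from dmdgp.solver import (InfeasibleEdgeError, Realizer, bp_reference,
                          decompose, dfs_engine, fbs_engine, flip,
                          pruning_edges, solve, solve_edge_dfs,
                          solve_edge_fbs)


class TestTreeEngines:
    """The height-four worked tree: 8 root-leaf paths of 4 nodes."""

    @staticmethod
    def leaf(index):  # 0-based left-to-right leaf -> 3-bit path
        return tuple((index >> (2 - s)) & 1 for s in range(3))

    def test_dfs_visits_all_but_rightmost_path(self):
        """Solution at the 7th of 8 leaves: 14 of 15 nodes expanded."""
        target = self.leaf(6)
        _, nodes = dfs_engine(3, lambda p: p == target)
        assert nodes == 14

    def test_dfs_left_spine_costs_path_length(self):
        target = self.leaf(0)
        _, nodes = dfs_engine(3, lambda p: p == target)
        assert nodes == 4

    def test_fbs_charges_rank_times_path_length(self):
        """Solution ranked third: three full paths of four nodes = 12."""
        target = self.leaf(6)
        order = [self.leaf(5), self.leaf(1), target] + \
            [self.leaf(k) for k in (0, 2, 3, 4, 7)]
        _, nodes = fbs_engine(order, lambda p: p == target, path_length=4)
        assert nodes == 12

    def test_fbs_first_rank_costs_one_path(self):
        target = self.leaf(3)
        _, nodes = fbs_engine([target], lambda p: p == target, 4)
        assert nodes == 4


class TestDecompose:
    def test_default_policy_n3_is_one_component(self, planted):
        _, inst = planted(3, seed=0)
        comps = decompose(pruning_edges(inst))
        assert len(comps) == 1
        assert len(comps[0].edges) == 5
        # windows 5-8, 5-11, 6-7, 11-14, 12-13 chain into support 5..14
        assert comps[0].bit_support == frozenset(range(5, 15))

    def test_disjoint_windows_stay_independent(self, planted):
        _, inst = planted(3, seed=0, policy=("C-CA",))
        comps = decompose(pruning_edges(inst))
        assert [len(c.edges) for c in comps] == [1, 1]
        assert all(c.independent for c in comps)

    def test_empty_edge_list(self):
        assert decompose([]) == []


class TestEdgeSearch:
    def test_planted_sequence_is_feasible(self, planted):
        conf, inst = planted(3, seed=3, policy=("HA-H",))
        r = Realizer(inst)
        edge = pruning_edges(inst)[0]
        seq, nodes = solve_edge_dfs(edge, r)
        assert r.edge_feasible(edge, {p: seq.bit(p) for p in edge.relevant})
        assert nodes >= 1

    def test_fbs_rank_length_law(self, planted):
        """FBS node counts are exactly rank x window length."""
        from dmdgp.frequency import build_table
        conf, inst = planted(3, seed=3, policy=("HA-H",))
        r = Realizer(inst)
        edge = pruning_edges(inst)[0]
        table = build_table([(encode(conf), pruning_edges(inst))])
        seq, nodes = solve_edge_fbs(edge, r, table)
        assert nodes % edge.window_length == 0
        rank = nodes // edge.window_length
        assert rank >= 1

    def test_empty_table_falls_back_to_dfs_order(self, planted):
        from dmdgp.frequency import FrequencyTable
        conf, inst = planted(3, seed=3, policy=("HA-H",))
        r = Realizer(inst)
        edge = pruning_edges(inst)[0]
        seq_d, _ = solve_edge_dfs(edge, r)
        seq_f, _ = solve_edge_fbs(edge, r, FrequencyTable())
        assert seq_f.as_str() == seq_d.as_str()


class TestFlipSymmetry:
    def test_flip_is_involution(self):
        from dmdgp.encoding import BitString
        s = BitString((0, 1, 1, 0), 5, frozenset({6}))
        assert flip(flip(s)) == s
        assert flip(s).bits == (1, 1, 0, 1)

    def test_flip_of_length_one(self):
        from dmdgp.encoding import BitString
        assert flip(BitString((0,), 12)).bits == (1,)

    @pytest.mark.parametrize("policy,n", [(("HA-H",), 3), (("HA-HA",), 3),
                                          (("C-CA",), 3)])
    def test_exactly_two_feasible_sequences_per_independent_edge(
            self, planted, policy, n):
        """Exhaustively: an edge admits its sequence and the complete flip."""
        _, inst = planted(n, seed=5, policy=policy)
        r = Realizer(inst)
        for edge in pruning_edges(inst):
            free = [p for p in edge.relevant if p in r.free]
            assert len(free) <= 10
            feasible = []
            for combo in itertools.product((0, 1), repeat=len(free)):
                if r.edge_feasible(edge, dict(zip(free, combo))):
                    feasible.append(combo)
            assert len(feasible) == 2
            assert feasible[1] == tuple(1 - b for b in feasible[0])


class TestSolve:
    @pytest.mark.parametrize("strategy", ["dfs", "fbs"])
    def test_solution_satisfies_all_restraints(self, planted, strategy):
        from dmdgp.frequency import FrequencyTable
        conf, inst = planted(4, seed=21)
        table = FrequencyTable() if strategy == "fbs" else None
        sol, stats = solve(inst, strategy, table=table)
        worst = max(abs(sol.conformation.distance(r.i, r.j) - r.value)
                    for r in inst.restraints)
        assert worst <= 1e-6
        assert stats.total_nodes == sum(e["nodes"] for e in stats.per_edge)

    def test_no_pruning_edges_gives_zero_stats(self, planted):
        _, inst = planted(3, seed=1, policy=())
        sol, stats = solve(inst, "dfs")
        assert stats.total_nodes == 0
        assert sol.bits.bit(4) == 0

    def test_fbs_requires_table(self, planted):
        _, inst = planted(3, seed=1)
        with pytest.raises(ValueError):
            solve(inst, "fbs")

    def test_solved_string_in_bp_solution_set(self, planted):
        for seed in range(10):
            _, inst = planted(3, seed=seed)
            sol, _ = solve(inst, "dfs")
            assert sol.bits.as_str() in {b.as_str()
                                         for b in bp_reference(inst)}


class TestBPReference:
    def test_unconstrained_count_is_half_the_tree(self, planted):
        """Without pruning edges, normalization halves 2^f leaves."""
        _, inst = planted(2, seed=2, policy=())
        r = Realizer(inst)
        sols = bp_reference(inst)
        assert len(sols) == 2 ** (len(r.free) - 1)

    def test_solutions_pair_up_under_component_flips(self, planted):
        _, inst = planted(3, seed=12)
        strs = {b.as_str() for b in bp_reference(inst)}
        assert len(strs) % 2 == 0

    def test_cap_refused_with_size_report(self, planted):
        _, inst = planted(5, seed=0)
        with pytest.raises(ValueError, match="free bits"):
            bp_reference(inst, max_free_bits=4)
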