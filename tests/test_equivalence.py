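"""Pre-test, candidate sets, backtracking search, and the full pipeline."""

from __future__ import annotations

import copy
import itertools
import random

import pytest
from hypothesis import given, strategies as st

from moleq.chem_io import AtomRecord, BondRecord, MoleculeGraph, read_sdf
from moleq.equivalence import (
    are_equivalent,
    assign,
    backtrack_search,
    build_candidates,
    label_graph,
    pretest,
    undo_to,
    verify_mapping,
)
from moleq.labelling import PropertyConfig
from moleq.synthetic import (
    GenParams,
    brute_force_isomorphic,
    permuted_copy,
    perturb,
    random_molecule_graph,
)

from conftest import molblock, worked_example_molecule


def all_equal_labels_graph(edges: list[tuple[int, int]], n: int) -> MoleculeGraph:
    atoms = [AtomRecord(i, 6) for i in range(n)]
    bonds = [BondRecord(a, b, 1) for a, b in edges]
    return MoleculeGraph("abstract", atoms, bonds)


class TestPretest:
    def test_radical_cation_differs_in_charge_then_radicals(self, ammonia_pair):
        a, b = (label_graph(m) for m in ammonia_pair)
        assert pretest(a, b) == "charge"

    def test_deuterated_pair_fails_on_hydrogen_totals(self, cyclohexene_pair):
        a, b = (label_graph(m) for m in cyclohexene_pair)
        assert pretest(a, b) == "h-count"

    def test_permuted_copy_always_passes(self):
        for seed in range(25):
            g = random_molecule_graph(GenParams(n_nodes=8, seed=seed))
            h, _ = permuted_copy(g, seed + 100)
            assert pretest(label_graph(g), label_graph(h)) is None

    def test_config_mismatch_is_usage_error(self):
        g = random_molecule_graph(GenParams(n_nodes=3, seed=0))
        with pytest.raises(ValueError, match="config"):
            pretest(label_graph(g, PropertyConfig(depth=2)),
                    label_graph(g, PropertyConfig(depth=3)))

    def test_atom_count_checked_first(self):
        a = random_molecule_graph(GenParams(n_nodes=3, seed=0))
        b = random_molecule_graph(GenParams(n_nodes=4, seed=0))
        assert pretest(label_graph(a), label_graph(b)) == "atom-count"


class TestCandidates:
    def test_twin_leaf_candidates_in_self_test(self):
        g = worked_example_molecule()
        lg = label_graph(g, PropertyConfig(depth=2))
        state = build_candidates(lg, lg)
        assert state is not None
        # the two equal-labelled leaves hanging off the same node stay mutual
        # candidates; every other node is pinned to itself
        assert state.can1[2] == {2, 3}
        assert state.can1[3] == {2, 3}
        for v in (0, 1, 4, 5, 6, 7):
            assert state.can1[v] == {v}

    def test_disjoint_label_multisets_infeasible(self):
        a = all_equal_labels_graph([(0, 1)], 2)
        b = MoleculeGraph("b", [AtomRecord(0, 7), AtomRecord(1, 7)],
                          [BondRecord(0, 1, 1)])
        assert build_candidates(label_graph(a), label_graph(b)) is None

    def test_mutual_consistency_invariant(self):
        g = random_molecule_graph(GenParams(n_nodes=8, seed=3))
        h, _ = permuted_copy(g, 4)
        state = build_candidates(label_graph(g), label_graph(h))
        for v, cands in enumerate(state.can1):
            for w in cands:
                assert v in state.can2[w]
        for w, cands in enumerate(state.can2):
            for v in cands:
                assert w in state.can1[v]


class TestAssignUndo:
    def _snapshot(self, state):
        return (copy.deepcopy(state.can1), copy.deepcopy(state.can2),
                list(state.mapping), list(state.reverse))

    @given(seed=st.integers(0, 10**6))
    def test_undo_restores_state_exactly(self, seed):
        rng = random.Random(seed)
        g = random_molecule_graph(GenParams(n_nodes=7, seed=seed))
        h, _ = permuted_copy(g, seed + 1)
        state = build_candidates(label_graph(g), label_graph(h))
        before = self._snapshot(state)
        v = rng.choice([v for v in range(state.a.n) if state.can1[v]])
        w = rng.choice(sorted(state.can1[v]))
        mark = state.checkpoint()
        assign(state, v, w)
        undo_to(state, mark)
        assert self._snapshot(state) == before

    def test_assign_shrinks_total_candidates(self):
        g = random_molecule_graph(GenParams(n_nodes=8, seed=11))
        h, _ = permuted_copy(g, 12)
        state = build_candidates(label_graph(g), label_graph(h))
        before = state.total_candidates()
        v = next(v for v in range(state.a.n) if state.can1[v])
        assign(state, v, sorted(state.can1[v])[0])
        assert state.total_candidates() < before

    def test_assign_precondition_violation(self):
        g = all_equal_labels_graph([(0, 1)], 2)
        lg = label_graph(g)
        state = build_candidates(lg, lg)
        assign(state, 0, 0)
        with pytest.raises(ValueError):
            assign(state, 0, 1)

    def test_single_node_assign_completes(self):
        g = all_equal_labels_graph([], 1)
        lg = label_graph(g)
        state = build_candidates(lg, lg)
        assign(state, 0, 0)
        assert state.mapping == [0]
        assert all(not s for s in state.can1 + state.can2)


class TestBacktrackSearch:
    def test_self_test_finds_mapping(self):
        g = worked_example_molecule()
        lg = label_graph(g)
        mapping = backtrack_search(build_candidates(lg, lg))
        assert mapping is not None
        assert verify_mapping(lg, lg, mapping)

    def test_automorphism_count_by_exhaustion(self):
        """Exhaustive enumeration over label-consistent bijections gives two
        automorphisms of the worked-example topology: the identity and the
        swap of the two equal-labelled leaves."""
        g = worked_example_molecule()
        lg = label_graph(g)
        chem = [lab.chem for lab in lg.labels]
        edges = {frozenset((b.a, b.b)) for b in g.bonds}
        count = 0
        for p in itertools.permutations(range(g.n_atoms)):
            if any(chem[v] != chem[p[v]] for v in range(g.n_atoms)):
                continue
            if all((frozenset((p[a], p[b])) in edges) == (frozenset((a, b)) in edges)
                   for a in range(g.n_atoms) for b in range(a + 1, g.n_atoms)):
                count += 1
        assert count == 2

    def test_relabelled_node_rejected_even_without_pretest(self):
        g = worked_example_molecule()
        atoms = [AtomRecord(a.index, 9 if a.index == 2 else a.atomic_number)
                 for a in g.atoms]
        h = MoleculeGraph("mutated", atoms, list(g.bonds))
        lg, lh = label_graph(g), label_graph(h)
        assert pretest(lg, lh) == "label-multiset"
        state = build_candidates(lg, lh)  # bypass the pre-test deliberately
        assert state is None or backtrack_search(state) is None

    def test_path_vs_star_rejected(self):
        path = all_equal_labels_graph([(0, 1), (1, 2), (2, 3)], 4)
        star = all_equal_labels_graph([(0, 1), (0, 2), (0, 3)], 4)
        # equal-label multisets differ via bond counts; go through the raw
        # search with label-free atoms to exercise the structural pruning
        cfg = PropertyConfig(properties=("atomic_number",), depth=0)
        lp, ls = label_graph(path, cfg), label_graph(star, cfg)
        state = build_candidates(lp, ls)
        assert state is None or backtrack_search(state) is None


class TestAreEquivalent:
    def test_shuffled_sdf_rewrite_is_equivalent(self, chloropropenamide):
        shuffled, _ = permuted_copy(chloropropenamide, 99)
        verdict = are_equivalent(chloropropenamide, shuffled)
        assert verdict.equivalent
        assert verdict.mapping is not None

    def test_deuterated_pair_not_equivalent(self, cyclohexene_pair):
        verdict = are_equivalent(*cyclohexene_pair)
        assert not verdict.equivalent
        assert verdict.reject_reason == "h-count"

    def test_radical_cation_not_equivalent(self, ammonia_pair):
        verdict = are_equivalent(*ammonia_pair)
        assert not verdict.equivalent
        assert verdict.reject_reason == "charge"

    def test_empty_graphs_equivalent(self):
        a = MoleculeGraph("e1", [], [])
        b = MoleculeGraph("e2", [], [])
        verdict = are_equivalent(a, b)
        assert verdict.equivalent
        assert verdict.mapping == []

    def test_empty_vs_nonempty_fails_on_atom_count(self):
        a = MoleculeGraph("e", [], [])
        b = all_equal_labels_graph([], 1)
        verdict = are_equivalent(a, b)
        assert verdict.reject_reason == "atom-count"

    def test_disconnected_graphs_handled(self):
        # two fragments vs the same fragments listed in the other order
        atoms = [AtomRecord(0, 6), AtomRecord(1, 6), AtomRecord(2, 8), AtomRecord(3, 8)]
        a = MoleculeGraph("frag-a", atoms, [BondRecord(0, 1, 1), BondRecord(2, 3, 1)])
        b, _ = permuted_copy(a, 17)
        assert are_equivalent(a, b).equivalent

    def test_strict_mode_separates_bond_order_variants(self):
        # same adjacency and per-atom bond-order counts are impossible to
        # construct differing only per-edge on 3 nodes; use a 4-cycle with
        # alternating orders rotated, where per-atom counts also shift --
        # instead check directly that strict mode rejects an order change
        g = all_equal_labels_graph([(0, 1), (1, 2)], 3)
        h = MoleculeGraph("h", [AtomRecord(i, 6) for i in range(3)],
                          [BondRecord(0, 1, 2), BondRecord(1, 2, 1)])
        cfg = PropertyConfig(properties=("atomic_number",), depth=2)
        assert not are_equivalent(g, h, cfg, strict=True).equivalent
        assert are_equivalent(g, h, cfg, strict=False).equivalent

    def test_verdict_independent_of_depth(self):
        rng = random.Random(7)
        for _ in range(30):
            g = random_molecule_graph(GenParams(n_nodes=rng.randint(1, 8),
                                                seed=rng.randrange(2**30)))
            if rng.random() < 0.5:
                other, _ = permuted_copy(g, rng.randrange(2**30))
            else:
                other = perturb(g, "rewire-one-edge", rng.randrange(2**30)) \
                    if g.n_atoms >= 4 and g.n_bonds else g
            verdicts = {are_equivalent(g, other, PropertyConfig(depth=k)).equivalent
                        for k in range(9)}
            assert len(verdicts) == 1

    def test_colliding_hash_never_changes_verdicts(self):
        """Descriptor hash collisions may only slow the search down; with a
        constant (maximally colliding) hash every verdict must be unchanged."""
        constant_hash = lambda seq: 1  # noqa: E731
        rng = random.Random(13)
        for _ in range(25):
            g = random_molecule_graph(GenParams(n_nodes=rng.randint(1, 7),
                                                seed=rng.randrange(2**30)))
            if rng.random() < 0.5:
                other, _ = permuted_copy(g, rng.randrange(2**30))
            else:
                try:
                    other = perturb(g, "change-one-bond-order", rng.randrange(2**30))
                except ValueError:
                    other, _ = permuted_copy(g, rng.randrange(2**30))
            ref = are_equivalent(g, other)
            col = are_equivalent(g, other, hash_fn=constant_hash)
            assert ref.equivalent == col.equivalent

    def test_networkx_agrees_on_random_pairs(self):
        """Independent cross-check of verdicts against networkx's VF2."""
        import networkx as nx
        from moleq.labelling import compute_all_property_tuples

        def to_nx(g):
            G = nx.Graph()
            labels = compute_all_property_tuples(g)
            for i in range(g.n_atoms):
                G.add_node(i, label=labels[i])
            for b in g.bonds:
                G.add_edge(b.a, b.b, order=b.order)
            return G

        rng = random.Random(23)
        for _ in range(40):
            g = random_molecule_graph(GenParams(n_nodes=rng.randint(2, 9),
                                                seed=rng.randrange(2**30)))
            if rng.random() < 0.5:
                other, _ = permuted_copy(g, rng.randrange(2**30))
            else:
                try:
                    other = perturb(g, rng.choice(
                        ("rewire-one-edge", "relabel-one-atom")),
                        rng.randrange(2**30))
                except ValueError:
                    other, _ = permuted_copy(g, rng.randrange(2**30))
            expected = nx.is_isomorphic(
                to_nx(g), to_nx(other),
                node_match=lambda x, y: x["label"] == y["label"],
                edge_match=lambda x, y: x["order"] == y["order"])
            assert are_equivalent(g, other).equivalent == expected
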