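"""Deciding 2D equivalence of two labelled molecule graphs.

The test runs in two phases.  A cheap pre-test compares global totals (atoms,
bonds, hydrogens, deuterium, formal charge, unpaired electrons) and the
multiset of chemical labels; failing any of these proves non-equivalence.  If
the pre-test passes, a candidate-set backtracking search looks for a bijection
that preserves adjacency and extended labels (chemical tuple + neighbourhood
descriptor).

The search keeps, for every node v of the first graph, the set can1(v) of
label-compatible nodes of the second graph it may still map to, and
symmetrically can2(w).  Assigning v -> w removes the pair from all other sets
and intersects the candidate sets of v's neighbours with the neighbourhood of
w (and vice versa); every removal goes onto an undo journal so backtracking
restores the exact prior state.  Candidate sets only ever shrink along a
search path.

Any mapping the search returns is re-verified from scratch (bijectivity, label
equality, adjacency in both directions, bond orders in strict mode) before a
positive verdict is issued, so the verdict never rests on hash injectivity or
on the pruning logic being correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .chem_io import MoleculeGraph
from .descriptors import ExtendedLabel, HashFn, extend_labels, fnv1a64
from .labelling import PropertyConfig, compute_signature

__all__ = [
    "LabelledGraph",
    "CandidateState",
    "Verdict",
    "label_graph",
    "pretest",
    "build_candidates",
    "assign",
    "undo_to",
    "backtrack_search",
    "are_equivalent",
    "verify_mapping",
]


@dataclass
class LabelledGraph:
    """A molecule graph bundled with per-node extended labels and adjacency."""

    graph: MoleculeGraph
    labels: list[ExtendedLabel]
    config: PropertyConfig
    adjacency: list[set[int]] = field(default_factory=list)
    orders: dict[frozenset[int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != self.graph.n_atoms:
            raise ValueError("labels must cover every node")
        if not self.adjacency:
            self.adjacency = [set(ns) for ns in self.graph.adjacency()]
        if not self.orders and self.graph.bonds:
            self.orders = self.graph.bond_orders()

    @property
    def n(self) -> int:
        return self.graph.n_atoms


def label_graph(graph: MoleculeGraph,
                config: PropertyConfig = PropertyConfig(),
                hash_fn: HashFn = fnv1a64) -> LabelledGraph:
    """Attach extended labels (chemical tuple + descriptor) to a molecule."""
    return LabelledGraph(graph=graph, labels=extend_labels(graph, config, hash_fn),
                         config=config)


@dataclass
class Verdict:
    """Outcome of an equivalence test.

    A positive verdict always carries a complete, independently verified
    mapping; a negative one carries the first rejection reason encountered.
    """

    equivalent: bool
    mapping: Optional[list[int]] = None
    reject_reason: Optional[str] = None


def pretest(a: LabelledGraph, b: LabelledGraph) -> Optional[str]:
    """Necessary-condition screen; returns the first violated criterion or None.

    Criteria in fixed order: atom count, bond count, total hydrogens, total
    deuterium, total formal charge, total unpaired electrons, then equality of
    the chemical label multisets.  Passing is necessary but not sufficient.
    """
    if a.config != b.config:
        raise ValueError("graphs labelled under different configs")
    sa = compute_signature(a.graph, a.config)
    sb = compute_signature(b.graph, b.config)
    checks = [
        ("atom-count", sa.n_atoms, sb.n_atoms),
        ("bond-count", sa.n_bonds, sb.n_bonds),
        ("h-count", sa.total_h, sb.total_h),
        ("d-count", sa.total_d, sb.total_d),
        ("charge", sa.total_charge, sb.total_charge),
        ("radicals", sa.total_radicals, sb.total_radicals),
        ("label-multiset", sa.label_multiset, sb.label_multiset),
    ]
    for reason, va, vb in checks:
        if va != vb:
            return reason
    return None


@dataclass
class CandidateState:
    """Mutable search state: candidate sets, partial mapping, undo journal.

    Mutual consistency (w in can1[v] iff v in can2[w]) is maintained by doing
    every removal pairwise; the journal records each removed pair and each
    mapping extension so that :func:`undo_to` restores the state exactly.
    """

    a: LabelledGraph
    b: LabelledGraph
    can1: list[set[int]]
    can2: list[set[int]]
    mapping: list[Optional[int]]
    reverse: list[Optional[int]]
    journal: list[tuple] = field(default_factory=list)
    strict: bool = True

    def checkpoint(self) -> int:
        return len(self.journal)

    def total_candidates(self) -> int:
        return sum(len(s) for s in self.can1)


def build_candidates(a: LabelledGraph, b: LabelledGraph,
                     strict: bool = True) -> Optional[CandidateState]:
    """Initial candidate sets from extended-label equality, or None if infeasible.

    can1(v) = { w : label_a(v) == label_b(w) } and symmetrically can2; if any
    node of either graph ends up with an empty set no bijection can exist.
    """
    by_label: dict[ExtendedLabel, set[int]] = {}
    for w, lab in enumerate(b.labels):
        by_label.setdefault(lab, set()).add(w)
    can1 = [set(by_label.get(lab, ())) for lab in a.labels]
    can2: list[set[int]] = [set() for _ in range(b.n)]
    for v, cands in enumerate(can1):
        for w in cands:
            can2[w].add(v)
    if any(not s for s in can1) or any(not s for s in can2):
        return None
    return CandidateState(a=a, b=b, can1=can1, can2=can2,
                          mapping=[None] * a.n, reverse=[None] * b.n,
                          strict=strict)


def _remove_pair(state: CandidateState, v: int, w: int) -> None:
    state.can1[v].discard(w)
    state.can2[w].discard(v)
    state.journal.append(("rm", v, w))


def assign(state: CandidateState, v: int, w: int) -> None:
    """Extend the partial mapping by v -> w and propagate candidate removals.

    Clears the candidate sets of v and w (removing them pairwise, which also
    removes w from every other can1 set and v from every other can2 set), then
    intersects each unmapped neighbour u of v with the neighbourhood of w —
    in strict mode only with neighbours reached by a bond of the same order —
    and symmetrically for neighbours of w.  All removals are journaled.
    """
    if state.can1[v] is None or w not in state.can1[v]:
        raise ValueError(f"precondition violated: {w} not in can1({v})")
    if state.mapping[v] is not None or state.reverse[w] is not None:
        raise ValueError("assign on already-mapped node")
    state.mapping[v] = w
    state.reverse[w] = v
    state.journal.append(("map", v, w))

    for x in list(state.can1[v]):
        _remove_pair(state, v, x)
    for y in list(state.can2[w]):
        _remove_pair(state, y, w)

    orders_a, orders_b = state.a.orders, state.b.orders
    nbrs_w = state.b.adjacency[w]
    for u in state.a.adjacency[v]:
        if state.mapping[u] is not None:
            continue
        for x in list(state.can1[u]):
            if x not in nbrs_w:
                _remove_pair(state, u, x)
            elif state.strict and orders_a[frozenset((u, v))] != orders_b[frozenset((x, w))]:
                _remove_pair(state, u, x)
    nbrs_v = state.a.adjacency[v]
    for z in state.b.adjacency[w]:
        if state.reverse[z] is not None:
            continue
        for y in list(state.can2[z]):
            if y not in nbrs_v:
                _remove_pair(state, y, z)
            elif state.strict and orders_a[frozenset((y, v))] != orders_b[frozenset((z, w))]:
                _remove_pair(state, y, z)


def undo_to(state: CandidateState, checkpoint: int) -> None:
    """Replay the journal backwards to a checkpoint, restoring the state."""
    while len(state.journal) > checkpoint:
        op = state.journal.pop()
        if op[0] == "rm":
            _, v, w = op
            state.can1[v].add(w)
            state.can2[w].add(v)
        else:
            _, v, w = op
            state.mapping[v] = None
            state.reverse[w] = None


def backtrack_search(state: CandidateState) -> Optional[list[int]]:
    """Depth-first search for a complete mapping, or None if none exists.

    At each step the unmapped node of the first graph with the smallest
    candidate set is selected (ties broken by lowest index) and its candidates
    are tried in ascending index order; dead ends are undone via the journal.
    Returns the first complete mapping found.
    """
    n_unmapped = sum(1 for m in state.mapping if m is None)

    def recurse(remaining: int) -> bool:
        if remaining == 0:
            return True
        v = -1
        best = None
        for u in range(state.a.n):
            if state.mapping[u] is None:
                size = len(state.can1[u])
                if best is None or size < best:
                    best, v = size, u
                    if size == 0:
                        return False
        for w in sorted(state.can1[v]):
            mark = state.checkpoint()
            assign(state, v, w)
            if recurse(remaining - 1):
                return True
            undo_to(state, mark)
        return False

    if recurse(n_unmapped):
        return [w for w in state.mapping]  # complete: no Nones left
    return None


def verify_mapping(a: LabelledGraph, b: LabelledGraph,
                   mapping: list[Optional[int]], strict: bool = True) -> bool:
    """Independently check a mapping: bijective, label- and edge-preserving."""
    if len(mapping) != a.n or a.n != b.n:
        return False
    if any(w is None for w in mapping):
        return False
    if len(set(mapping)) != a.n:
        return False
    for v, w in enumerate(mapping):
        if a.labels[v].chem != b.labels[w].chem:
            return False
    orders_b = b.orders
    for bond in a.graph.bonds:
        pair = frozenset((mapping[bond.a], mapping[bond.b]))
        if pair not in orders_b:
            return False
        if strict and orders_b[pair] != bond.order:
            return False
    inverse = [0] * b.n
    for v, w in enumerate(mapping):
        inverse[w] = v
    orders_a = a.orders
    for bond in b.graph.bonds:
        pair = frozenset((inverse[bond.a], inverse[bond.b]))
        if pair not in orders_a:
            return False
        if strict and orders_a[pair] != bond.order:
            return False
    return True


def are_equivalent(mol_a: MoleculeGraph, mol_b: MoleculeGraph,
                   config: PropertyConfig = PropertyConfig(),
                   strict: bool = True,
                   hash_fn: HashFn = fnv1a64) -> Verdict:
    """Full 2D-equivalence pipeline for two normalised molecules.

    Labels both molecules (chemical tuples + depth-``config.depth``
    descriptors), runs the pre-test, builds candidate sets and searches for a
    mapping.  ``strict`` additionally requires per-edge bond-order equality;
    disabling it reproduces the adjacency-only isomorphism condition.  The
    verdict is independent of the descriptor depth — descriptors only prune.
    """
    a = label_graph(mol_a, config, hash_fn)
    b = label_graph(mol_b, config, hash_fn)
    reason = pretest(a, b)
    if reason is not None:
        return Verdict(equivalent=False, reject_reason=reason)
    if a.n == 0:
        return Verdict(equivalent=True, mapping=[])
    state = build_candidates(a, b, strict=strict)
    if state is None:
        return Verdict(equivalent=False, reject_reason="search-exhausted")
    mapping = backtrack_search(state)
    if mapping is None:
        return Verdict(equivalent=False, reject_reason="search-exhausted")
    if not verify_mapping(a, b, mapping, strict=strict):
        raise AssertionError(
            "internal error: search returned a mapping that fails independent "
            "verification")
    return Verdict(equivalent=True, mapping=mapping)
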