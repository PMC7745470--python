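"""Synthetic molecule-like graphs and a brute-force isomorphism oracle.

The generator produces connected, degree-capped random graphs whose atoms are
drawn from a small alphabet of realistic organic atom templates (C/N/O/S/Cl
with 0-3 hydrogens), so instances resemble small-molecule heavy-atom graphs
rather than arbitrary graphs.  Everything is a pure function of its seed: the
same parameters always yield byte-identical graphs.

``brute_force_isomorphic`` is an independent correctness oracle: it enumerates
all chemical-label-class-consistent bijections and checks each one directly.
It shares no candidate-set or propagation code with the search module, which
is exactly what makes it usable as ground truth in tests.  A factorial guard
restricts it to small graphs.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .chem_io import AtomRecord, BondRecord, MoleculeGraph
from .labelling import PropertyConfig, compute_all_property_tuples

__all__ = [
    "AtomTemplate",
    "GenParams",
    "DEFAULT_ALPHABET",
    "random_molecule_graph",
    "permuted_copy",
    "perturb",
    "brute_force_isomorphic",
    "PERTURB_MODES",
]


@dataclass(frozen=True)
class AtomTemplate:
    """Element + attached-hydrogen template for generated atoms."""

    atomic_number: int
    h_count: int = 0
    d_count: int = 0
    formal_charge: int = 0
    radical_electrons: int = 0


#: Organic-chemistry-flavoured default alphabet: carbons, heteroatoms, halogen.
DEFAULT_ALPHABET: tuple[AtomTemplate, ...] = (
    AtomTemplate(6, 0), AtomTemplate(6, 1), AtomTemplate(6, 2), AtomTemplate(6, 3),
    AtomTemplate(7, 0), AtomTemplate(7, 1), AtomTemplate(7, 2),
    AtomTemplate(8, 0), AtomTemplate(8, 1),
    AtomTemplate(16, 0), AtomTemplate(17, 0),
)


@dataclass(frozen=True)
class GenParams:
    """Parameters of the random-graph generator; generation is pure in these."""

    n_nodes: int
    seed: int
    label_alphabet: tuple[AtomTemplate, ...] = DEFAULT_ALPHABET
    max_degree: int = 4
    bond_order_weights: tuple[float, float, float] = (0.7, 0.25, 0.05)
    extra_edge_factor: float = 0.3  # expected extra edges per node beyond the tree

    def __post_init__(self) -> None:
        if self.n_nodes < 0:
            raise ValueError("n_nodes must be >= 0")
        if self.max_degree < 1 and self.n_nodes > 1:
            raise ValueError("max_degree too small to connect the graph")
        if not self.label_alphabet:
            raise ValueError("empty label alphabet")


def random_molecule_graph(params: GenParams) -> MoleculeGraph:
    """Connected random graph under the degree cap, atoms from the alphabet.

    Built as a random spanning tree (each new node attaches to a uniformly
    chosen earlier node with spare degree) plus extra random edges that respect
    the cap.  Bond-count label properties are always derived from the actual
    incident edges by the labelling module, so generated graphs satisfy every
    molecule-graph invariant by construction.
    """
    rng = random.Random(params.seed)
    n = params.n_nodes
    if n == 0:
        return MoleculeGraph(id=f"synth-{params.seed}", atoms=[], bonds=[])
    degree = [0] * n
    bonds: list[BondRecord] = []
    seen: set[frozenset[int]] = set()

    def order() -> int:
        return rng.choices((1, 2, 3), weights=params.bond_order_weights)[0]

    for v in range(1, n):
        anchors = [u for u in range(v) if degree[u] < params.max_degree]
        if not anchors:
            raise ValueError("degree constraints make a connected graph infeasible")
        u = rng.choice(anchors)
        bonds.append(BondRecord(u, v, order()))
        seen.add(frozenset((u, v)))
        degree[u] += 1
        degree[v] += 1

    n_extra = int(round(params.extra_edge_factor * n))
    for _ in range(n_extra):
        open_nodes = [u for u in range(n) if degree[u] < params.max_degree]
        rng.shuffle(open_nodes)
        placed = False
        for u, v in itertools.combinations(open_nodes, 2):
            if frozenset((u, v)) not in seen:
                a, b = min(u, v), max(u, v)
                bonds.append(BondRecord(a, b, order()))
                seen.add(frozenset((a, b)))
                degree[a] += 1
                degree[b] += 1
                placed = True
                break
        if not placed:
            break

    atoms = []
    h_count, d_count = [], []
    for i in range(n):
        t = rng.choice(params.label_alphabet)
        atoms.append(AtomRecord(i, t.atomic_number, None,
                                t.formal_charge, t.radical_electrons))
        h_count.append(t.h_count)
        d_count.append(t.d_count)
    return MoleculeGraph(id=f"synth-{params.seed}", atoms=atoms, bonds=bonds,
                         h_count=h_count, d_count=d_count)


def permuted_copy(g: MoleculeGraph, seed: int) -> tuple[MoleculeGraph, list[int]]:
    """Uniformly relabelled copy of ``g`` plus the permutation as a witness.

    The returned list maps old index -> new index and is a certified
    isomorphism from ``g`` to the copy.
    """
    rng = random.Random(seed)
    perm = list(range(g.n_atoms))
    rng.shuffle(perm)
    atoms: list[Optional[AtomRecord]] = [None] * g.n_atoms
    h = [0] * g.n_atoms
    d = [0] * g.n_atoms
    for a in g.atoms:
        j = perm[a.index]
        atoms[j] = AtomRecord(j, a.atomic_number, a.mass_number,
                              a.formal_charge, a.radical_electrons)
        h[j] = g.h_count[a.index]
        d[j] = g.d_count[a.index]
    bonds = sorted((BondRecord(min(perm[b.a], perm[b.b]),
                               max(perm[b.a], perm[b.b]), b.order)
                    for b in g.bonds), key=lambda b: (b.a, b.b))
    return MoleculeGraph(id=f"{g.id}-perm", atoms=atoms, bonds=bonds,
                         h_count=h, d_count=d), perm


PERTURB_MODES = ("relabel-one-atom", "rewire-one-edge", "change-one-bond-order",
                 "add-one-radical", "swap-H-for-D")


def perturb(g: MoleculeGraph, mode: str, seed: int) -> MoleculeGraph:
    """Apply exactly one structural or chemical modification to a copy of ``g``.

    Modes mirror the chemistry the equivalence test must distinguish: changed
    element, rewired bond, changed bond order, an added unpaired electron, and
    a hydrogen swapped for deuterium.  Raises ``ValueError`` when the graph has
    no applicable site for the requested mode.
    """
    rng = random.Random(seed)
    atoms = [AtomRecord(a.index, a.atomic_number, a.mass_number,
                        a.formal_charge, a.radical_electrons) for a in g.atoms]
    bonds = list(g.bonds)
    h = list(g.h_count)
    d = list(g.d_count)

    if mode == "relabel-one-atom":
        if not atoms:
            raise ValueError("no atom to relabel")
        i = rng.randrange(len(atoms))
        old = atoms[i]
        new_z = rng.choice([z for z in (6, 7, 8, 15, 16, 17) if z != old.atomic_number])
        atoms[i] = AtomRecord(old.index, new_z, old.mass_number,
                              old.formal_charge, old.radical_electrons)
    elif mode == "rewire-one-edge":
        if len(atoms) < 4 or not bonds:
            raise ValueError("need >= 4 nodes and an edge to rewire")
        existing = {b.endpoints for b in bonds}
        candidates = [(i, u, v) for i, b in enumerate(bonds)
                      for u, v in itertools.combinations(range(len(atoms)), 2)
                      if frozenset((u, v)) not in existing]
        if not candidates:
            raise ValueError("graph is complete; nothing to rewire")
        i, u, v = rng.choice(candidates)
        bonds[i] = BondRecord(u, v, bonds[i].order)
    elif mode == "change-one-bond-order":
        if not bonds:
            raise ValueError("no bond to change")
        i = rng.randrange(len(bonds))
        b = bonds[i]
        new_order = rng.choice([o for o in (1, 2, 3) if o != b.order])
        bonds[i] = BondRecord(b.a, b.b, new_order)
    elif mode == "add-one-radical":
        if not atoms:
            raise ValueError("no atom for a radical")
        i = rng.randrange(len(atoms))
        old = atoms[i]
        atoms[i] = AtomRecord(old.index, old.atomic_number, old.mass_number,
                              old.formal_charge, old.radical_electrons + 1)
    elif mode == "swap-H-for-D":
        sites = [i for i in range(len(atoms)) if h[i] >= 1]
        if not sites:
            raise ValueError("no hydrogen to swap for deuterium")
        i = rng.choice(sites)
        h[i] -= 1
        d[i] += 1
    else:
        raise ValueError(f"unknown perturbation mode {mode!r}")

    return MoleculeGraph(id=f"{g.id}-{mode}", atoms=atoms, bonds=bonds,
                         h_count=h, d_count=d)


def brute_force_isomorphic(a: MoleculeGraph, b: MoleculeGraph,
                           config: PropertyConfig = PropertyConfig(),
                           strict: bool = True,
                           max_nodes: int = 10) -> bool:
    """Exhaustive labelled-isomorphism oracle for small graphs.

    Groups nodes by chemical label, enumerates every bijection that respects
    the grouping (a product of per-class permutations), and tests adjacency —
    plus per-edge bond orders in strict mode — directly against the edge sets.
    Intended as ground truth in tests; guarded to ``max_nodes`` nodes.
    """
    if a.n_atoms > max_nodes or b.n_atoms > max_nodes:
        raise ValueError(f"brute-force oracle limited to {max_nodes} nodes")
    if a.n_atoms != b.n_atoms or a.n_bonds != b.n_bonds:
        return False
    la = compute_all_property_tuples(a, config)
    lb = compute_all_property_tuples(b, config)

    classes_a: dict[tuple, list[int]] = {}
    classes_b: dict[tuple, list[int]] = {}
    for v, lab in enumerate(la):
        classes_a.setdefault(lab, []).append(v)
    for w, lab in enumerate(lb):
        classes_b.setdefault(lab, []).append(w)
    if set(classes_a) != set(classes_b):
        return False
    if any(len(classes_a[lab]) != len(classes_b[lab]) for lab in classes_a):
        return False

    ea = a.bond_orders()
    eb = b.bond_orders()
    labs = list(classes_a)
    perms_per_class = [itertools.permutations(classes_b[lab]) for lab in labs]
    for choice in itertools.product(*perms_per_class):
        mapping = [0] * a.n_atoms
        for lab_nodes, perm in zip((classes_a[lab] for lab in labs), choice):
            for v, w in zip(lab_nodes, perm):
                mapping[v] = w
        ok = True
        for pair, order in ea.items():
            u, v = tuple(pair)
            img = frozenset((mapping[u], mapping[v]))
            if img not in eb or (strict and eb[img] != order):
                ok = False
                break
        if ok:
            return True
    return False
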