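"""Chemical atom labels and whole-molecule signatures.

Every atom receives a tuple of integer properties — its chemical label.  Two
atoms get the same tuple exactly when all enabled properties agree, which is
what makes the label usable for candidate pruning in the isomorphism search.
Bond-count properties count incident *heavy-atom* bonds only: hydrogens were
collapsed into ``h_count``/``d_count`` and are not single bonds here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .chem_io import MoleculeGraph

__all__ = [
    "PROPERTY_ORDER",
    "PropertyConfig",
    "PropertyTuple",
    "MoleculeSignature",
    "compute_property_tuple",
    "compute_all_property_tuples",
    "compute_signature",
]

#: The fixed, comparable ordering of the supported atom properties.
PROPERTY_ORDER: tuple[str, ...] = (
    "atomic_number",
    "h_count",
    "d_count",
    "formal_charge",
    "radical_electrons",
    "single_bond_count",
    "double_bond_count",
    "triple_bond_count",
)

#: A chemical label: one integer per enabled property, in config order.
PropertyTuple = tuple[int, ...]


@dataclass(frozen=True)
class PropertyConfig:
    """Which atom properties enter the label, and the neighbourhood depth k.

    ``depth`` is the number of neighbour-sum refinement rounds used by the
    descriptor stage; 6 is the default working depth (deeper refinement stops
    paying off around there for small organic molecules, mirroring common
    circular-fingerprint practice).
    """

    properties: tuple[str, ...] = PROPERTY_ORDER
    depth: int = 6

    def __post_init__(self) -> None:
        if not self.properties:
            raise ValueError("at least one property must be enabled")
        unknown = set(self.properties) - set(PROPERTY_ORDER)
        if unknown:
            raise ValueError(f"unknown properties: {sorted(unknown)}")
        if len(set(self.properties)) != len(self.properties):
            raise ValueError("duplicate properties in config")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")

    @classmethod
    def from_names(cls, names: Sequence[str] | None, depth: int = 6) -> "PropertyConfig":
        """Build a config from property names, keeping the canonical order."""
        if not names:
            return cls(depth=depth)
        chosen = tuple(p for p in PROPERTY_ORDER if p in set(names))
        unknown = set(names) - set(PROPERTY_ORDER)
        if unknown:
            raise ValueError(f"unknown properties: {sorted(unknown)}")
        return cls(properties=chosen, depth=depth)


@dataclass(frozen=True)
class MoleculeSignature:
    """Global totals plus the sorted multiset of chemical labels.

    Equality of signatures is a necessary condition for molecule equivalence:
    any isomorphism preserves every total and maps the label multiset onto
    itself.  The signature also serves as the exact-match lookup key when
    partitioning collections into equivalence classes.
    """

    n_atoms: int
    n_bonds: int
    total_h: int
    total_d: int
    total_charge: int
    total_radicals: int
    label_multiset: tuple[PropertyTuple, ...] = field(default=())

    def key(self) -> tuple:
        """A hashable canonical form for dictionary lookup."""
        return (self.n_atoms, self.n_bonds, self.total_h, self.total_d,
                self.total_charge, self.total_radicals, self.label_multiset)


def _hd_counts(graph: MoleculeGraph) -> tuple[list[int], list[int]]:
    """Per-atom H/D counts as seen by the label model.

    In hydrogen-only records the atoms *are* explicit hydrogen isotopes, so
    each such node counts its own isotope here; otherwise H2/D2/HD would be
    indistinguishable (their collapsed counts are all zero).
    """
    h = list(graph.h_count)
    d = list(graph.d_count)
    for a in graph.atoms:
        if a.atomic_number == 1:
            if a.mass_number == 2:
                d[a.index] += 1
            else:
                h[a.index] += 1
    return h, d


def _bond_order_counts(graph: MoleculeGraph) -> list[list[int]]:
    # counts[v] = [single, double, triple] incident heavy-atom bonds
    counts = [[0, 0, 0] for _ in graph.atoms]
    for b in graph.bonds:
        counts[b.a][b.order - 1] += 1
        counts[b.b][b.order - 1] += 1
    return counts


def compute_property_tuple(graph: MoleculeGraph, atom_index: int,
                           config: PropertyConfig = PropertyConfig()) -> PropertyTuple:
    """The chemical label of one atom, as a tuple in config property order."""
    return compute_all_property_tuples(graph, config)[atom_index]


def compute_all_property_tuples(graph: MoleculeGraph,
                                config: PropertyConfig = PropertyConfig()
                                ) -> list[PropertyTuple]:
    """Chemical labels for every atom (one pass over the bond list)."""
    order_counts = _bond_order_counts(graph)
    h_counts, d_counts = _hd_counts(graph)
    labels: list[PropertyTuple] = []
    for a in graph.atoms:
        values = {
            "atomic_number": a.atomic_number,
            "h_count": h_counts[a.index],
            "d_count": d_counts[a.index],
            "formal_charge": a.formal_charge,
            "radical_electrons": a.radical_electrons,
            "single_bond_count": order_counts[a.index][0],
            "double_bond_count": order_counts[a.index][1],
            "triple_bond_count": order_counts[a.index][2],
        }
        labels.append(tuple(values[p] for p in config.properties))
    return labels


def compute_signature(graph: MoleculeGraph,
                      config: PropertyConfig = PropertyConfig()) -> MoleculeSignature:
    """Global signature: atom/bond/H/D/charge/radical totals + label multiset."""
    labels = compute_all_property_tuples(graph, config)
    h_counts, d_counts = _hd_counts(graph)
    return MoleculeSignature(
        n_atoms=graph.n_atoms,
        n_bonds=graph.n_bonds,
        total_h=sum(h_counts),
        total_d=sum(d_counts),
        total_charge=sum(a.formal_charge for a in graph.atoms),
        total_radicals=sum(a.radical_electrons for a in graph.atoms),
        label_multiset=tuple(sorted(labels)),
    )
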