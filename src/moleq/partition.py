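"""Partitioning a molecule stream into equivalence classes.

Molecules are read one at a time.  Each record's global signature (totals plus
chemical-label multiset) keys a list of class representatives that could
possibly be equivalent to it; the record is tested with the full equivalence
pipeline only against those, joins the first matching class, and otherwise
founds a new class with itself as representative.  Because equivalence is
transitive, first-match and best-match semantics produce the same partition.

Memory holds only representatives and class metadata, never all member graphs,
so arbitrarily long streams can be processed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .chem_io import MoleculeGraph
from .descriptors import HashFn, fnv1a64
from .equivalence import LabelledGraph, backtrack_search, build_candidates, label_graph
from .labelling import PropertyConfig, compute_signature

__all__ = ["EquivalenceClass", "ClassIndex", "PartitionResult", "partition_stream"]


@dataclass
class EquivalenceClass:
    """One class: a representative molecule plus all member record ids."""

    class_id: int
    representative: MoleculeGraph
    member_ids: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class _Rep:
    cls: EquivalenceClass
    labelled: LabelledGraph


@dataclass
class ClassIndex:
    """Signature-keyed lists of representatives (insertion-ordered)."""

    buckets: dict[tuple, list[_Rep]] = field(default_factory=dict)

    def candidates(self, key: tuple) -> list[_Rep]:
        return self.buckets.get(key, [])

    def add(self, key: tuple, rep: _Rep) -> None:
        self.buckets.setdefault(key, []).append(rep)


@dataclass
class PartitionResult:
    classes: list[EquivalenceClass]
    n_records: int
    n_isomorphism_tests: int
    n_pretest_rejections: int
    rejects: list[tuple[str, str]] = field(default_factory=list)  # (id, error)

    def size_histogram(self) -> dict[int, int]:
        hist: dict[int, int] = {}
        for c in self.classes:
            hist[c.size] = hist.get(c.size, 0) + 1
        return dict(sorted(hist.items()))


def partition_stream(records: Iterable[MoleculeGraph],
                     config: PropertyConfig = PropertyConfig(),
                     strict: bool = True,
                     hash_fn: HashFn = fnv1a64) -> PartitionResult:
    """Single-pass partition of molecule records into equivalence classes.

    Records sharing no signature key are never compared, so collections of
    molecules with pairwise different formulas resolve with zero isomorphism
    tests.  Deterministic given the input order; the multiset of class sizes
    is invariant under reordering (representatives may differ).
    """
    index = ClassIndex()
    classes: list[EquivalenceClass] = []
    n_iso = 0
    n_pre = 0
    for graph in records:
        key = compute_signature(graph, config).key()
        labelled: Optional[LabelledGraph] = None
        home: Optional[EquivalenceClass] = None
        for rep in index.candidates(key):
            # Same signature key => the pre-test criteria all hold already.
            if labelled is None:
                labelled = label_graph(graph, config, hash_fn)
            n_iso += 1
            state = build_candidates(labelled, rep.labelled, strict=strict)
            if state is None:
                n_pre += 1
                continue
            if graph.n_atoms == 0 or backtrack_search(state) is not None:
                home = rep.cls
                break
        if home is None:
            if labelled is None:
                labelled = label_graph(graph, config, hash_fn)
            home = EquivalenceClass(class_id=len(classes), representative=graph)
            classes.append(home)
            index.add(key, _Rep(cls=home, labelled=labelled))
        home.member_ids.append(graph.id)
    return PartitionResult(classes=classes,
                           n_records=sum(c.size for c in classes),
                           n_isomorphism_tests=n_iso,
                           n_pretest_rejections=n_pre)
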