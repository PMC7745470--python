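"""Iterative neighbourhood descriptors (Morgan/ECFP-style refinement).

Each node starts from a hash of its chemical label, d0(v) = hash(l(v)).
Round i then replaces every value by the sum of its neighbours' round i-1
values:

    d_i(v) = sum over neighbours w of d_{i-1}(w)

so d_i(v) summarises the labelled neighbourhood of v up to distance i.  The
combined descriptor d(v) = hash(d_0(v), ..., d_k(v)) folds the whole refinement
trajectory into one integer and is attached to the chemical label as the
structural half of an :class:`ExtendedLabel`.

All sums are 64-bit wrap-around and the hash is an unsalted FNV-1a over the
little-endian byte encoding of the integer sequence, so descriptor tables are
bit-for-bit reproducible across platforms and runs.  Hash collisions can only
make candidate sets larger than ideal (or let the pre-test pass spuriously);
they can never produce a wrong verdict, because equivalence is ultimately
established by an explicitly verified mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, NamedTuple, Sequence

from .chem_io import MoleculeGraph
from .labelling import PropertyConfig, PropertyTuple, compute_all_property_tuples

__all__ = [
    "fnv1a64",
    "seed_descriptor",
    "iterate_descriptors",
    "combine_descriptor",
    "extend_labels",
    "DescriptorTable",
    "ExtendedLabel",
    "HashFn",
]

_MASK64 = (1 << 64) - 1
_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3

HashFn = Callable[[Sequence[int]], int]


def fnv1a64(values: Sequence[int]) -> int:
    """64-bit FNV-1a over the little-endian bytes of a signed-int sequence."""
    h = _FNV_OFFSET
    for x in values:
        for byte in (x & _MASK64).to_bytes(8, "little"):
            h ^= byte
            h = (h * _FNV_PRIME) & _MASK64
    return h


class ExtendedLabel(NamedTuple):
    """Chemical label plus combined neighbourhood descriptor.

    Two extended labels are equal only when *both* components are equal, so a
    descriptor hash collision can never merge chemically distinct atoms.
    """

    chem: PropertyTuple
    descriptor: int


@dataclass(frozen=True)
class DescriptorTable:
    """Per-node refinement rows (d_0 .. d_k) at depth ``k``."""

    rounds: tuple[tuple[int, ...], ...]  # rounds[v] has k+1 entries
    k: int

    def __post_init__(self) -> None:
        if any(len(r) != self.k + 1 for r in self.rounds):
            raise ValueError("each row must have exactly k+1 entries")

    def row(self, v: int) -> tuple[int, ...]:
        return self.rounds[v]


def seed_descriptor(label: PropertyTuple, hash_fn: HashFn = fnv1a64) -> int:
    """d_0 for an atom: a deterministic 64-bit hash of its chemical label."""
    return hash_fn(label)


def iterate_descriptors(seeds: Sequence[int],
                        edges: Iterable[tuple[int, int]],
                        k: int) -> DescriptorTable:
    """Run ``k`` neighbour-sum refinement rounds from per-node seed values.

    Works on any undirected graph given as an edge list over ``range(len(seeds))``;
    seeds may be supplied externally (they need no particular semantics).  Each
    round costs one pass over the edge list, O(k*|E|) total.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    edge_list = [(a, b) for a, b in edges]
    n = len(seeds)
    for a, b in edge_list:
        if not (0 <= a < n and 0 <= b < n) or a == b:
            raise ValueError(f"bad edge ({a}, {b})")
    rows: list[list[int]] = [[s & _MASK64] for s in seeds]
    cur = [s & _MASK64 for s in seeds]
    for _ in range(k):
        nxt = [0] * n
        for a, b in edge_list:
            nxt[a] = (nxt[a] + cur[b]) & _MASK64
            nxt[b] = (nxt[b] + cur[a]) & _MASK64
        for v in range(n):
            rows[v].append(nxt[v])
        cur = nxt
    return DescriptorTable(rounds=tuple(tuple(r) for r in rows), k=k)


def combine_descriptor(row: Sequence[int], hash_fn: HashFn = fnv1a64) -> int:
    """d(v): hash of the full refinement row (order-sensitive)."""
    return hash_fn(row)


def extend_labels(graph: MoleculeGraph,
                  config: PropertyConfig = PropertyConfig(),
                  hash_fn: HashFn = fnv1a64) -> list[ExtendedLabel]:
    """Chemical label + combined descriptor for every atom of a molecule."""
    chem = compute_all_property_tuples(graph, config)
    seeds = [seed_descriptor(c, hash_fn) for c in chem]
    table = iterate_descriptors(seeds, ((b.a, b.b) for b in graph.bonds), config.depth)
    return [ExtendedLabel(chem=c, descriptor=combine_descriptor(table.row(v), hash_fn))
            for v, c in enumerate(chem)]
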