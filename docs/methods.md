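# Methods

## Model and scope

A molecule is a labelled undirected graph over its heavy atoms. Two
molecules are equivalent when a bijection between their atom sets preserves
adjacency and every enabled atom property. This is 2D constitution only:
coordinates, stereo parity fields and aromaticity perception are out of
scope, and aromatic (order 4) bond records are rejected rather than guessed
at — inputs must be kekulised upstream (a `kekulize` hook on the parser is
the supported entry point for that).

### Atom labels

The label is a tuple of integers in a fixed order: atomic number, attached
hydrogens, attached deuteriums, formal charge, unpaired electrons, and
counts of incident single/double/triple bonds. Two conventions matter:

* **Bond counts exclude hydrogens.** A terminal =CH₂ carbon has two
  hydrogens and zero single bonds. Hydrogen attachment is fully captured by
  the H/D count properties; counting H bonds again as single bonds would be
  redundant and would change the reference label table.
* **Explicit-H records.** Records consisting solely of hydrogen isotopes
  (H₂, D₂, HD, bare H radicals) keep their atoms explicit, since there is no
  heavy atom to collapse onto. For such nodes the label's H/D count fields
  carry the node's own isotope (an H node counts one hydrogen, a D node one
  deuterium); without this, H₂ and D₂ would be indistinguishable. Mixed
  records never contain explicit H after normalisation, so the convention is
  unambiguous.

Labels permit any subset of the eight properties (`PropertyConfig`); the
default enables all eight. Real-valued extensions (partial charges, radii)
are deliberately not in the default set: label equality is exact, so floats
would have to be pre-quantised by the caller.

Implicit-hydrogen handling is defined entirely by this package's own
convention: only explicit H/D atoms in the connection table contribute to
the counts (the V2000 valence column is ignored). Tritium and heavier
hydrogen isotopes are a hard error by default; `permissive_isotopes` demotes
them to ordinary hydrogen with a warning. Bridging hydrogens, and charged or
radical explicit hydrogens attached to a heavy atom, are errors because
collapsing them would silently lose information.

## Neighbourhood descriptors

Refinement starts from `d₀(v) = hash(ℓ(v))` and iterates neighbour sums,
`dᵢ(v) = Σ_{(v,w)∈E} dᵢ₋₁(w)`, for `k` rounds; the combined descriptor
hashes the whole row `(d₀ … d_k)` order-sensitively. Numerical choices:

* **Hash**: unsalted 64-bit FNV-1a over the little-endian two's-complement
  byte encoding of the integer sequence. No per-run randomisation, so
  descriptor tables are identical across platforms, runs and processes.
* **Arithmetic**: all sums are 64-bit wrap-around. On native 64-bit values
  this matches unsigned overflow semantics exactly.
* **Aggregation**: the plain neighbour *sum* is kept even though it loses
  information (different neighbour multisets can share a sum); the search
  phase compensates, and the verdict never depends on descriptor
  distinctiveness.
* **Depth**: default `k = 6`. Deeper refinement stops shrinking candidate
  sets for small organic molecules around that depth, consistent with
  common circular-fingerprint practice (diameter 4–6); `--depth` exposes it.
* **Collision policy**: equality of extended labels compares the chemical
  tuple *and* the descriptor integer, never a hash of the pair. A collision
  can therefore only enlarge candidate sets or let the pre-test pass
  spuriously — both cost time, never correctness. The suite asserts this by
  re-running verdicts under a deliberately constant hash.

`iterate_descriptors` accepts externally supplied seeds on an arbitrary edge
list, which is how the refinement worked example (whose seed values are
arbitrary by construction) is reproduced directly. One round touches each
edge twice; total work is O(k·|E|).

## Equivalence test

* **Pre-test** compares, in fixed order: atom count, bond count, total H,
  total D, total charge, total unpaired electrons, then the *multiset* of
  chemical labels (a bijection preserves multiplicities, so multiset
  equality is the correct — and strictly stronger — form of label-set
  comparison). The first violated criterion is reported as the rejection
  reason. The pre-test uses chemical labels only, so the possible rejection
  reasons do not depend on the refinement depth; descriptor-level
  infeasibility surfaces at candidate construction instead and is reported
  as `search-exhausted`.
* **Candidate sets** pair nodes with equal extended labels; an empty set on
  either side ends the test immediately.
* **Search**: depth-first. Select an unmapped node with the
  minimum-cardinality candidate set (ties: lowest index), try its candidates
  in ascending index order, propagate — the assigned pair leaves all other
  sets, and each unmapped neighbour's candidate set is intersected with the
  image's neighbourhood — and journal every removal so a dead end restores
  the exact prior state. Candidate totals are non-increasing along any
  search path. The deterministic tie-breaks make search trees, and thus
  returned mappings, reproducible.
* **Strict bond orders** (default): candidate propagation and final
  verification additionally require `order(u,v) = order(f(u),f(v))` on every
  edge. Per-atom bond-order counts do not provably force per-edge orders, so
  adjacency-only matching admits a theoretical false-positive class;
  `--paper-faithful` restores the adjacency-only condition for comparison.
* **Post-hoc verification**: every positive verdict is re-checked from
  scratch — bijectivity, chemical-label equality, edge preservation in both
  directions, bond orders in strict mode. A verification failure raises an
  internal error rather than ever returning a silently wrong verdict.

Empty graphs are equivalent to each other by the vacuous bijection; an
empty/non-empty pair fails on atom count. Disconnected records are kept as
single graphs and need no special casing — label classes plus adjacency
propagation already confine candidates within components.

## Partitioning

The stream partitioner keys an index of class representatives by the full
molecule signature (totals + sorted label multiset, serialised canonically).
Each record is tested only against same-key representatives, in creation
order, and joins the first equivalent class; transitivity of equivalence
makes first-match and exhaustive-match semantics coincide. Memory holds
representatives and member ids only. The class-size multiset is invariant
under input reordering; the representatives themselves may differ.

## Synthetic data and what it shows

The generator produces connected graphs via a random spanning tree plus
extra edges under a degree cap of 4, with atoms drawn from an alphabet of
realistic organic templates (C/N/O/S/Cl carrying 0–3 hydrogens) and bond
orders weighted 0.70/0.25/0.05 towards single bonds — degree and composition
statistics resembling small-molecule heavy-atom graphs. Generation is a pure
function of its parameters. Perturbation modes (element change, edge rewire,
bond-order change, added radical, H→D swap) mirror the chemistry the test
must distinguish.

The generator does **not** enforce valence rules, rings with realistic
strain, or real isotope/charge distributions; passing the randomized suites
therefore demonstrates correctness of the graph algorithm on molecule-like
topologies, not chemical validity handling. Correctness on real files is
separately exercised by the hand-built reference molecules (acrylamide
derivative, ammonia/radical cation, cyclohexene/d₃-cyclohexene) and by
cross-checks against RDKit's reader and networkx's VF2 matcher.

The brute-force oracle enumerates label-class-consistent bijections
exhaustively (guarded to ≤ 10 nodes) and shares no pruning code with the
search; randomized agreement suites run it against the full pipeline at
several depths. Problem sizes in the shipped suites — 1000 random pairs of
up to 8 atoms for oracle agreement and depth independence, 1000 permuted
twins for pre-test safety, 200 records in 50 planted classes for partition
recovery — keep the whole suite under half a minute while the factorial
oracle remains exact; the planted partition certifies its ground truth by
drawing base molecules until signatures are pairwise distinct, which proves
non-equivalence without invoking the search under test.

## Known limitations

* No aromaticity perception, SMILES/InChI support, stereochemistry, or
  V3000 connection tables.
* Subgraph isomorphism / maximum common substructure are out of scope.
* The search is exponential in the worst case (as any isomorphism
  backtracking is); descriptors make molecule-sized instances fast but give
  no worst-case guarantee on adversarial regular graphs.
* Equality of real-valued label extensions is exact; callers must quantise.
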