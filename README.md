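# moleq — 2D molecule equivalence testing

`moleq` decides whether two molecules have the same 2D constitution — the same
atoms, bonds, formal charges, isotopes (hydrogen vs. deuterium) and unpaired
electrons, ignoring stereochemistry and geometry — and partitions molecule
collections (SDF files) into equivalence classes. It is aimed at
cheminformatics workflows that deduplicate structure sets or check database
membership, where popular toolkits have historically conflated e.g. ammonia
with its radical cation, or cyclohexene with its deuterated isotopologue.

## The method

A molecule is modelled as a labelled graph `G = (V, E)`: heavy atoms are
nodes, bonds are edges, and explicit hydrogens/deuteriums are collapsed into
per-atom counts. Each atom `v` carries a chemical label

```
ℓ(v) = (Z, #H, #D, charge, unpaired e⁻, #single, #double, #triple)
```

and two molecules are **equivalent** iff there is a bijection `f : V₁ → V₂`
with `{f(u), f(v)} ∈ E₂ ⇔ {u, v} ∈ E₁` and `ℓ₁(v) = ℓ₂(f(v))` — labelled
graph isomorphism.

To make the search fast, every node also receives an iteratively refined
**neighbourhood descriptor** (closely related to Morgan/ECFP invariants):

```
d₀(v) = hash(ℓ(v))
dᵢ(v) = Σ_{(v,w) ∈ E} dᵢ₋₁(w)          (64-bit wrap-around)
d(v)  = hash(d₀(v), d₁(v), …, d_k(v))
```

with default depth `k = 6` and an unsalted 64-bit FNV-1a hash, so results are
bit-for-bit reproducible. The equivalence test then runs in two phases:

1. **Pre-test** — compare atom, bond, H, D, charge and radical totals, then
   the multiset of chemical labels; any mismatch proves non-equivalence.
2. **Candidate-set backtracking** — each node `v ∈ V₁` starts with the
   candidate set `can₁(v) = {w ∈ V₂ : (ℓ, d)(v) = (ℓ, d)(w)}`. The search
   repeatedly assigns the node with the smallest candidate set, intersects
   neighbouring candidate sets with the image's neighbourhood, and undoes
   removals from a journal on dead ends.

Descriptors only prune: the verdict is provably identical for every `k ≥ 0`,
and hash collisions can at worst slow the search down, because every positive
answer is re-verified as an explicit label- and edge-preserving bijection.

Partitioning reads an SDF stream record by record, looks up each molecule's
global signature in a representative index, and runs the pairwise test only
against representatives with the same signature.

## Worked example

Parsing 2-chloroprop-1-enamide (CH₂=C(Cl)–C(=O)–NH₂, atoms ordered C, C, C,
Cl, O, N with four explicit hydrogens) and printing each atom's label:

```python
from moleq import read_sdf, compute_all_property_tuples
mol = read_sdf(open("chloropropenamide.mol").read())[0]
for i, lab in enumerate(compute_all_property_tuples(mol), 1):
    print(i, lab)
```

```
1 (6, 2, 0, 0, 0, 0, 1, 0)
2 (6, 0, 0, 0, 0, 2, 1, 0)
3 (6, 0, 0, 0, 0, 2, 1, 0)
4 (17, 0, 0, 0, 0, 1, 0, 0)
5 (8, 0, 0, 0, 0, 0, 1, 0)
6 (7, 2, 0, 0, 0, 1, 0, 0)
```

Atom 1 is the terminal =CH₂ carbon: atomic number 6, two hydrogens, one
double bond and — note — zero single bonds, because bonds to collapsed
hydrogens are not counted. Atom 4 is the chlorine (17, one single bond);
atom 6 the amide nitrogen (7, two hydrogens, one single bond).

Descriptor refinement on an abstract 8-node tree (seeds chosen freely,
depth 3) shows how structurally distinct atoms separate:

```python
from moleq.descriptors import iterate_descriptors
t = iterate_descriptors([5, 3, 7, 7, 5, 3, 10, 2],
                        [(0,1), (0,4), (1,2), (1,3), (4,5), (5,6), (5,7)], 3)
for v, name in enumerate("ABCDEFGH"):
    print(name, t.row(v))
```

```
A (5, 8, 27, 39)
B (3, 19, 14, 65)
C (7, 3, 19, 14)
D (7, 3, 19, 14)
E (5, 8, 25, 41)
F (3, 17, 14, 59)
G (10, 3, 17, 14)
H (2, 3, 17, 14)
```

A and E share a label and symmetric direct neighbourhoods (rounds 0–1 equal)
but separate at round 2 (27 vs 25); the twin leaves C and D stay identical
forever; G and H have mirror-image surroundings (equal rounds ≥ 1) but
different own labels, so their combined descriptors still differ.

## Command line

```bash
moleq equiv a.sdf b.sdf --print-mapping   # exit 0 = equivalent, 1 = not, 2 = error
moleq partition in.sdf -o classes.tsv --summary summary.json
moleq describe mol.sdf --depth 6          # per-atom d0..dk and d(v) as TSV
moleq synth -n 8 -m 10 --twins -o gen.sdf # random test molecules as SDF
```

Global flags: `--depth` (default 6), `--properties` (subset of the eight
label properties), `--paper-faithful` (match adjacency only, without
per-edge bond-order equality), `--config` (YAML with `properties`/`depth`).

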