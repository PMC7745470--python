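"""Shared fixtures: hand-built MOL blocks and reference graphs."""

from __future__ import annotations

import pytest
from hypothesis import settings

from moleq.chem_io import AtomRecord, BondRecord, MoleculeGraph, read_sdf

settings.register_profile("suite", derandomize=True, max_examples=25)
settings.load_profile("suite")


def molblock(name: str, atoms: list[str], bonds: list[tuple[int, int, int]],
             props: list[str] | None = None) -> str:
    """Assemble a minimal V2000 MOL block (1-based atom indices in bonds)."""
    lines = [name, "  test", "",
             f"{len(atoms):3d}{len(bonds):3d}  0  0  0  0  0  0  0  0999 V2000"]
    for s in atoms:
        lines.append(f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {s:<3}"
                     "0  0  0  0  0  0  0  0  0  0  0  0")
    for a, b, o in bonds:
        lines.append(f"{a:3d}{b:3d}{o:3d}  0")
    lines.extend(props or [])
    lines.append("M  END")
    return "\n".join(lines)


# 2-chloroprop-1-enamide, CH2=C(Cl)-C(=O)-NH2, heavy atoms in the reference
# order C,C,C,Cl,O,N followed by the four explicit hydrogens.
CHLOROPROPENAMIDE_BLOCK = molblock(
    "2-chloroprop-1-enamide",
    ["C", "C", "C", "Cl", "O", "N", "H", "H", "H", "H"],
    [(1, 2, 2), (2, 3, 1), (2, 4, 1), (3, 5, 2), (3, 6, 1),
     (1, 7, 1), (1, 8, 1), (6, 9, 1), (6, 10, 1)],
)

#: The eight expected property rows (config order) for the six heavy atoms.
CHLOROPROPENAMIDE_LABELS = [
    (6, 2, 0, 0, 0, 0, 1, 0),
    (6, 0, 0, 0, 0, 2, 1, 0),
    (6, 0, 0, 0, 0, 2, 1, 0),
    (17, 0, 0, 0, 0, 1, 0, 0),
    (8, 0, 0, 0, 0, 0, 1, 0),
    (7, 2, 0, 0, 0, 1, 0, 0),
]

AMMONIA_BLOCK = molblock(
    "ammonia", ["N", "H", "H", "H"],
    [(1, 2, 1), (1, 3, 1), (1, 4, 1)],
)

# Ammonia radical cation: same connectivity, +1 charge and one unpaired
# electron on the nitrogen (CTfile doublet code 2).
AMMONIA_CATION_BLOCK = molblock(
    "ammonia-radical-cation", ["N", "H", "H", "H"],
    [(1, 2, 1), (1, 3, 1), (1, 4, 1)],
    ["M  CHG  1   1   1", "M  RAD  1   1   2"],
)


def _cyclohexene_atoms_bonds(n_deuterium: int):
    atoms = ["C"] * 6
    bonds = [(1, 2, 2), (2, 3, 1), (3, 4, 1), (4, 5, 1), (5, 6, 1), (6, 1, 1)]
    h_per_atom = [1, 1, 2, 2, 2, 2]
    props = []
    idx = 7
    d_left = n_deuterium
    for heavy, count in enumerate(h_per_atom, start=1):
        for _ in range(count):
            atoms.append("H")
            bonds.append((heavy, idx, 1))
            if d_left > 0:
                props.append(f"M  ISO  1 {idx:3d}   2")
                d_left -= 1
            idx += 1
    return atoms, bonds, props


CYCLOHEXENE_BLOCK = molblock("cyclohex-1-ene", *_cyclohexene_atoms_bonds(0))
D3_CYCLOHEXENE_BLOCK = molblock("d3-cyclohex-1-ene", *_cyclohexene_atoms_bonds(3))

# The descriptor worked example: 8 nodes A..H with printed seed values and the
# unique edge set consistent with every printed refinement cell.
WORKED_EXAMPLE_SEEDS = [5, 3, 7, 7, 5, 3, 10, 2]
WORKED_EXAMPLE_EDGES = [(0, 1), (0, 4), (1, 2), (1, 3), (4, 5), (5, 6), (5, 7)]
WORKED_EXAMPLE_ROUNDS = {
    "A": (5, 8, 27, 39),
    "B": (3, 19, 14, 65),
    "C": (7, 3, 19, 14),
    "D": (7, 3, 19, 14),
    "E": (5, 8, 25, 41),
    "F": (3, 17, 14, 59),
    "G": (10, 3, 17, 14),
    "H": (2, 3, 17, 14),
}


def worked_example_molecule() -> MoleculeGraph:
    """The worked-example topology as a molecule whose chemical label classes
    reproduce the colour classes: {A,E}, {B,F}, {C,D}, {G}, {H}."""
    elements = [6, 6, 8, 8, 6, 6, 16, 17]  # A B C D E F G H
    atoms = [AtomRecord(i, z) for i, z in enumerate(elements)]
    bonds = [BondRecord(a, b, 1) for a, b in WORKED_EXAMPLE_EDGES]
    return MoleculeGraph("worked-example", atoms, bonds)


@pytest.fixture
def chloropropenamide() -> MoleculeGraph:
    return read_sdf(CHLOROPROPENAMIDE_BLOCK)[0]


@pytest.fixture
def ammonia_pair() -> tuple[MoleculeGraph, MoleculeGraph]:
    return read_sdf(AMMONIA_BLOCK)[0], read_sdf(AMMONIA_CATION_BLOCK)[0]


@pytest.fixture
def cyclohexene_pair() -> tuple[MoleculeGraph, MoleculeGraph]:
    return read_sdf(CYCLOHEXENE_BLOCK)[0], read_sdf(D3_CYCLOHEXENE_BLOCK)[0]
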