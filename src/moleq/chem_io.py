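"""Reading and writing molecules as MDL MOL / SDF (V2000) connection tables.

The reader normalises each record into a :class:`MoleculeGraph`: a heavy-atom
graph in which explicit hydrogen and deuterium atoms are collapsed into
per-atom ``h_count`` / ``d_count`` fields.  Records that consist solely of
hydrogen isotopes (H2, D2, HD, a bare H radical record, ...) keep their atoms
explicit — there is no heavy atom to attach them to.

Only the V2000 connection table is supported: counts line, atom block, bond
block and the ``M  CHG`` / ``M  ISO`` / ``M  RAD`` property lines.  Coordinates
and stereo parity fields are ignored; equivalence here is 2D constitution only.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator, Optional, TextIO

__all__ = [
    "AtomRecord",
    "BondRecord",
    "MoleculeGraph",
    "RawMolecule",
    "ParseError",
    "UnsupportedFeatureError",
    "parse_sdf",
    "collapse_hydrogens",
    "read_sdf",
    "write_sdf",
    "graph_to_tables",
]


class ParseError(ValueError):
    """Malformed connection-table input."""


class UnsupportedFeatureError(ValueError):
    """Input uses a feature outside the supported model (e.g. aromatic bonds)."""


# CTfile "M  RAD" codes: 1 = singlet (paired), 2 = doublet, 3 = triplet.
# The atom label tracks *unpaired electrons*, hence the 0/1/2 mapping.
_RAD_CODE_TO_ELECTRONS = {0: 0, 1: 0, 2: 1, 3: 2}

# Old-style atom-block charge column codes (superseded by any M  CHG/RAD line).
_CHARGE_CODES = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}

_ELEMENTS = (
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr "
    "Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og"
).split()
SYMBOL_TO_NUMBER = {s: i + 1 for i, s in enumerate(_ELEMENTS)}
NUMBER_TO_SYMBOL = {i + 1: s for i, s in enumerate(_ELEMENTS)}
# Isotope shorthand symbols for hydrogen.
SYMBOL_TO_NUMBER["D"] = 1
SYMBOL_TO_NUMBER["T"] = 1


@dataclass(frozen=True)
class AtomRecord:
    """One atom: element, optional isotope mass number, charge, radicals."""

    index: int
    atomic_number: int
    mass_number: Optional[int] = None
    formal_charge: int = 0
    radical_electrons: int = 0

    def __post_init__(self) -> None:
        if self.atomic_number < 1:
            raise ValueError(f"atomic_number must be >= 1, got {self.atomic_number}")
        if self.radical_electrons < 0:
            raise ValueError("radical_electrons must be >= 0")
        if self.mass_number is not None and self.mass_number < self.atomic_number:
            raise ValueError(
                f"mass_number {self.mass_number} < atomic_number {self.atomic_number}"
            )


@dataclass(frozen=True)
class BondRecord:
    """One bond between two atom indices, with order 1, 2 or 3."""

    a: int
    b: int
    order: int

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-loop bond")
        if self.order not in (1, 2, 3):
            raise ValueError(f"bond order must be 1, 2 or 3, got {self.order}")

    @property
    def endpoints(self) -> frozenset[int]:
        return frozenset((self.a, self.b))


@dataclass
class RawMolecule:
    """A parsed record before hydrogen collapsing: atoms exactly as written."""

    id: str
    atoms: list[AtomRecord]
    bonds: list[BondRecord]


@dataclass
class MoleculeGraph:
    """Heavy-atom molecular graph with per-atom H/D counts.

    ``atoms[i].index == i`` always holds; bonds reference these indices.  For
    hydrogen-only records the "heavy" atoms are the explicit H/D atoms
    themselves and all ``h_count``/``d_count`` entries are zero.
    """

    id: str
    atoms: list[AtomRecord]
    bonds: list[BondRecord]
    h_count: list[int] = field(default_factory=list)
    d_count: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if not self.h_count:
            self.h_count = [0] * n
        if not self.d_count:
            self.d_count = [0] * n
        seen: set[frozenset[int]] = set()
        for b in self.bonds:
            if not (0 <= b.a < n and 0 <= b.b < n):
                raise ValueError(f"bond endpoint out of range: {b}")
            if b.endpoints in seen:
                raise ValueError(f"duplicate bond {sorted(b.endpoints)}")
            seen.add(b.endpoints)
        if any(h < 0 for h in self.h_count) or any(d < 0 for d in self.d_count):
            raise ValueError("negative hydrogen/deuterium count")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def adjacency(self) -> list[list[int]]:
        """Neighbour lists, each sorted ascending."""
        adj: list[list[int]] = [[] for _ in self.atoms]
        for b in self.bonds:
            adj[b.a].append(b.b)
            adj[b.b].append(b.a)
        for lst in adj:
            lst.sort()
        return adj

    def bond_orders(self) -> dict[frozenset[int], int]:
        return {b.endpoints: b.order for b in self.bonds}


def _int_field(line: str, start: int, end: int, what: str, record: int) -> int:
    raw = line[start:end].strip()
    try:
        return int(raw) if raw else 0
    except ValueError:
        raise ParseError(f"record {record}: bad {what} field {raw!r}") from None


def _parse_block(lines: list[str], record_index: int, record_id: str,
                 kekulize: Optional[Callable[[list[str]], list[str]]]) -> RawMolecule:
    if len(lines) < 4:
        raise ParseError(f"record {record_index}: truncated header")
    counts = lines[3]
    if "V3000" in counts:
        raise UnsupportedFeatureError(f"record {record_index}: V3000 is not supported")
    n_atoms = _int_field(counts, 0, 3, "atom count", record_index)
    n_bonds = _int_field(counts, 3, 6, "bond count", record_index)
    if len(counts[:3].strip()) == 0:
        raise ParseError(f"record {record_index}: malformed counts line {counts!r}")

    atom_lines = lines[4:4 + n_atoms]
    bond_lines = lines[4 + n_atoms:4 + n_atoms + n_bonds]
    if len(atom_lines) != n_atoms or len(bond_lines) != n_bonds:
        raise ParseError(f"record {record_index}: counts line promises "
                         f"{n_atoms} atoms / {n_bonds} bonds, block is shorter")
    if kekulize is not None:
        bond_lines = kekulize(bond_lines)

    symbols: list[str] = []
    block_charges: list[int] = []
    for i, line in enumerate(atom_lines):
        sym = line[31:34].strip() or line.split()[3] if len(line) >= 34 else line.split()[3]
        if sym not in SYMBOL_TO_NUMBER:
            raise ParseError(f"record {record_index}: unknown element symbol {sym!r} "
                             f"(atom {i + 1})")
        symbols.append(sym)
        code = _int_field(line, 36, 39, "charge code", record_index) if len(line) >= 39 else 0
        if code == 4:  # old-style doublet radical code
            block_charges.append(0)
        elif code not in _CHARGE_CODES:
            raise ParseError(f"record {record_index}: bad charge code {code}")
        else:
            block_charges.append(_CHARGE_CODES[code])

    bonds: list[BondRecord] = []
    seen_pairs: set[frozenset[int]] = set()
    for i, line in enumerate(bond_lines):
        a = _int_field(line, 0, 3, "bond atom", record_index) - 1
        b = _int_field(line, 3, 6, "bond atom", record_index) - 1
        order = _int_field(line, 6, 9, "bond order", record_index)
        if not (0 <= a < n_atoms and 0 <= b < n_atoms) or a == b:
            raise ParseError(f"record {record_index}: bond {i + 1} endpoints out of range")
        if order not in (1, 2, 3):
            raise UnsupportedFeatureError(
                f"record {record_index}: bond order {order} unsupported "
                "(aromatic/query bonds must be kekulised upstream)")
        pair = frozenset((a, b))
        if pair in seen_pairs:
            raise ParseError(f"record {record_index}: duplicate bond {a + 1}-{b + 1}")
        seen_pairs.add(pair)
        bonds.append(BondRecord(a, b, order))

    prop_entries: dict[str, list[tuple[int, int]]] = {"CHG": [], "RAD": [], "ISO": []}
    for line in lines[4 + n_atoms + n_bonds:]:
        tag = line[:6]
        if tag in ("M  CHG", "M  RAD", "M  ISO"):
            try:
                parts = line.split()
                count = int(parts[2])
                pairs = [(int(parts[3 + 2 * j]) - 1, int(parts[4 + 2 * j]))
                         for j in range(count)]
            except (IndexError, ValueError):
                raise ParseError(f"record {record_index}: malformed property line "
                                 f"{line.rstrip()!r}") from None
            for idx, _ in pairs:
                if not 0 <= idx < n_atoms:
                    raise ParseError(f"record {record_index}: property line references "
                                     f"atom {idx + 1} out of range")
            prop_entries[tag[3:]].extend(pairs)
        elif tag == "M  END":
            break

    # CTfile rule: the presence of any M CHG or M RAD line supersedes *all*
    # atom-block charge/radical columns.
    if prop_entries["CHG"] or prop_entries["RAD"]:
        charges = {i: 0 for i in range(n_atoms)}
        charges.update(dict(prop_entries["CHG"]))
    else:
        charges = {i: c for i, c in enumerate(block_charges)}
    radicals: dict[int, int] = {}
    for idx, code in prop_entries["RAD"]:
        if code not in _RAD_CODE_TO_ELECTRONS:
            raise ParseError(f"record {record_index}: bad radical code {code}")
        radicals[idx] = _RAD_CODE_TO_ELECTRONS[code]
    isotopes = dict(prop_entries["ISO"])

    atoms = []
    for i, sym in enumerate(symbols):
        mass: Optional[int] = isotopes.get(i)
        if mass is None and sym == "D":
            mass = 2
        elif mass is None and sym == "T":
            mass = 3
        atoms.append(AtomRecord(
            index=i,
            atomic_number=SYMBOL_TO_NUMBER[sym],
            mass_number=mass if mass else None,
            formal_charge=charges.get(i, 0),
            radical_electrons=radicals.get(i, 0),
        ))
    return RawMolecule(id=record_id, atoms=atoms, bonds=bonds)


def parse_sdf(stream: TextIO | str | Iterable[str],
              kekulize: Optional[Callable[[list[str]], list[str]]] = None,
              ) -> Iterator[RawMolecule]:
    """Parse an SDF stream (or a single MOL block) into raw molecule records.

    Yields one :class:`RawMolecule` per ``$$$$``-terminated block (a trailing
    block without the separator — a bare MOL file — is also accepted).
    ``M  CHG`` / ``M  RAD`` / ``M  ISO`` property lines override the atom-block
    columns.  Atom order is preserved exactly as written.

    A ``kekulize`` callable, if given, may rewrite the bond-block lines of each
    record before bond orders are validated; without it, aromatic (order 4)
    bonds raise :class:`UnsupportedFeatureError`.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]

    block: list[str] = []
    record_index = 0
    for line in lines:
        if line.strip() == "$$$$":
            if any(ln.strip() for ln in block):
                name = block[0].strip() if block else ""
                yield _parse_block(block, record_index,
                                   name or str(record_index), kekulize)
                record_index += 1
            block = []
        else:
            block.append(line)
    if any(ln.strip() for ln in block):
        name = block[0].strip() if block else ""
        yield _parse_block(block, record_index, name or str(record_index), kekulize)


def collapse_hydrogens(raw: RawMolecule, permissive_isotopes: bool = False) -> MoleculeGraph:
    """Fold explicit H/D atoms into per-heavy-atom counts.

    Each explicit hydrogen (mass absent or 1) bonded to a heavy atom increments
    that atom's ``h_count``; mass-2 hydrogen increments ``d_count``.  Records
    made up entirely of hydrogen isotopes keep their atoms explicit.

    Raises :class:`UnsupportedFeatureError` for bridging hydrogens (degree > 1),
    charged or radical explicit hydrogens attached to a heavy atom (collapsing
    them would silently discard the charge/radical), free hydrogens floating in
    a mixed record, and — unless ``permissive_isotopes`` — tritium and heavier
    hydrogen isotopes (which are then counted as ordinary H with a warning).
    """
    is_h = [a.atomic_number == 1 for a in raw.atoms]
    if all(is_h) and raw.atoms:
        # H-only record: nothing to collapse onto.
        atoms = [AtomRecord(i, a.atomic_number, a.mass_number,
                            a.formal_charge, a.radical_electrons)
                 for i, a in enumerate(raw.atoms)]
        return MoleculeGraph(raw.id, atoms, list(raw.bonds))

    degree = [0] * len(raw.atoms)
    for b in raw.bonds:
        degree[b.a] += 1
        degree[b.b] += 1

    heavy_index: dict[int, int] = {}
    atoms: list[AtomRecord] = []
    for a in raw.atoms:
        if is_h[a.index]:
            continue
        heavy_index[a.index] = len(atoms)
        atoms.append(AtomRecord(len(atoms), a.atomic_number, a.mass_number,
                                a.formal_charge, a.radical_electrons))

    h_count = [0] * len(atoms)
    d_count = [0] * len(atoms)
    bonds: list[BondRecord] = []
    for b in raw.bonds:
        ha, hb = is_h[b.a], is_h[b.b]
        if ha and hb:
            raise UnsupportedFeatureError(
                f"record {raw.id!r}: H-H bond in a record with heavy atoms")
        if ha or hb:
            h, heavy = (b.a, b.b) if ha else (b.b, b.a)
            if degree[h] > 1:
                raise UnsupportedFeatureError(
                    f"record {raw.id!r}: bridging hydrogen (atom {h + 1} has "
                    f"degree {degree[h]})")
            if b.order != 1:
                raise UnsupportedFeatureError(
                    f"record {raw.id!r}: hydrogen with bond order {b.order}")
            hatom = raw.atoms[h]
            if hatom.formal_charge != 0 or hatom.radical_electrons != 0:
                raise UnsupportedFeatureError(
                    f"record {raw.id!r}: charged/radical explicit hydrogen "
                    f"(atom {h + 1}) cannot be collapsed without information loss")
            mass = hatom.mass_number
            if mass is None or mass == 1:
                h_count[heavy_index[heavy]] += 1
            elif mass == 2:
                d_count[heavy_index[heavy]] += 1
            else:
                if not permissive_isotopes:
                    raise UnsupportedFeatureError(
                        f"record {raw.id!r}: hydrogen isotope mass {mass} "
                        "(only H and D are modelled)")
                warnings.warn(f"record {raw.id!r}: counting mass-{mass} hydrogen "
                              "as ordinary H", stacklevel=2)
                h_count[heavy_index[heavy]] += 1
        else:
            bonds.append(BondRecord(heavy_index[b.a], heavy_index[b.b], b.order))

    for a in raw.atoms:
        if is_h[a.index] and degree[a.index] == 0:
            raise UnsupportedFeatureError(
                f"record {raw.id!r}: unbonded explicit hydrogen (atom "
                f"{a.index + 1}) in a record with heavy atoms")

    return MoleculeGraph(raw.id, atoms, bonds, h_count, d_count)


def read_sdf(source: TextIO | str,
             permissive_isotopes: bool = False,
             kekulize: Optional[Callable[[list[str]], list[str]]] = None,
             ) -> list[MoleculeGraph]:
    """Parse and hydrogen-collapse every record of an SDF stream or text."""
    return [collapse_hydrogens(raw, permissive_isotopes)
            for raw in parse_sdf(source, kekulize)]


def _atom_line(symbol: str) -> str:
    return f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {symbol:<3}0  0  0  0  0  0  0  0  0  0  0  0"


def write_sdf(graphs: Iterable[MoleculeGraph], stream: TextIO = sys.stdout) -> None:
    """Emit graphs as minimal V2000 SDF blocks with explicit H/D atoms.

    Collapsed hydrogen/deuterium counts are expanded back into explicit atoms
    (deuterium via ``M  ISO``), so a write/read round trip reproduces the graph.
    """
    for g in graphs:
        n_extra = sum(g.h_count) + sum(g.d_count)
        n_atoms = g.n_atoms + n_extra
        n_bonds = g.n_bonds + n_extra
        lines = [g.id, "  moleq", "",
                 f"{n_atoms:3d}{n_bonds:3d}  0  0  0  0  0  0  0  0999 V2000"]
        iso: list[tuple[int, int]] = []
        chg: list[tuple[int, int]] = []
        rad: list[tuple[int, int]] = []
        for a in g.atoms:
            lines.append(_atom_line(NUMBER_TO_SYMBOL[a.atomic_number]))
            if a.mass_number is not None:
                iso.append((a.index + 1, a.mass_number))
            if a.formal_charge:
                chg.append((a.index + 1, a.formal_charge))
            if a.radical_electrons:
                rad.append((a.index + 1, a.radical_electrons + 1))
        bond_lines = [f"{b.a + 1:3d}{b.b + 1:3d}{b.order:3d}  0" for b in g.bonds]
        next_idx = g.n_atoms + 1
        for heavy in range(g.n_atoms):
            for _ in range(g.h_count[heavy]):
                lines.append(_atom_line("H"))
                bond_lines.append(f"{heavy + 1:3d}{next_idx:3d}  1  0")
                next_idx += 1
            for _ in range(g.d_count[heavy]):
                lines.append(_atom_line("H"))
                iso.append((next_idx, 2))
                bond_lines.append(f"{heavy + 1:3d}{next_idx:3d}  1  0")
                next_idx += 1
        lines.extend(bond_lines)
        for tag, entries in (("CHG", chg), ("ISO", iso), ("RAD", rad)):
            for i in range(0, len(entries), 8):
                chunk = entries[i:i + 8]
                body = "".join(f"{idx:4d}{val:4d}" for idx, val in chunk)
                lines.append(f"M  {tag}{len(chunk):3d}{body}")
        lines.append("M  END")
        lines.append("$$$$")
        stream.write("\n".join(lines) + "\n")


def graph_to_tables(g: MoleculeGraph) -> tuple[str, str]:
    """Debug writer: the normalised graph as (nodes TSV, edges TSV)."""
    node_rows = ["index\tatomic_number\tmass_number\tformal_charge\t"
                 "radical_electrons\th_count\td_count"]
    for a in g.atoms:
        node_rows.append(f"{a.index}\t{a.atomic_number}\t"
                         f"{a.mass_number if a.mass_number is not None else ''}\t"
                         f"{a.formal_charge}\t{a.radical_electrons}\t"
                         f"{g.h_count[a.index]}\t{g.d_count[a.index]}")
    edge_rows = ["a\tb\torder"]
    for b in sorted(g.bonds, key=lambda b: (b.a, b.b)):
        edge_rows.append(f"{b.a}\t{b.b}\t{b.order}")
    return "\n".join(node_rows) + "\n", "\n".join(edge_rows) + "\n"
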