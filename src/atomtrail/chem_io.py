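"""MDL MOL / RXN (V2000) reading and writing.

Connection tables are the interchange currency of atom mapping: metabolite
structures travel as MOL files and per-reaction atom-atom mappings as RXN
files whose atom blocks carry map numbers (column 61-63 of each atom line).
This module parses both into plain domain objects and writes them back,
preserving the mapping as a relation rather than as raw map numbers.

Only the V2000 dialect is supported; V3000 input is rejected outright
because the upstream mapping tools this package consumes emit V2000.
Atom indices are 1-based everywhere, following the MOL convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .errors import CapacityError, MappingIntegrityError, MolParseError

log = logging.getLogger(__name__)

#: Element symbols accepted in atom blocks. Deliberately a whitelist: a
#: garbled fixed-width line usually surfaces as a nonsense symbol, and an
#: early, located error beats a silently wrong molecule.
KNOWN_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Mn", "Fe", "Co", "Ni", "Cu",
    "Zn", "As", "Se", "Br", "Mo", "I", "W",
}

ATOMIC_NUMBER = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Mn": 25, "Fe": 26,
    "Co": 27, "Ni": 28, "Cu": 29, "Zn": 30, "As": 33, "Se": 34, "Br": 35,
    "Mo": 42, "I": 53, "W": 74,
}

# Legacy ccc charge field of the V2000 atom line (M  CHG lines override).
_LEGACY_CHARGE = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}


@dataclass(frozen=True)
class Atom:
    element: str
    charge: int = 0


@dataclass(frozen=True)
class Bond:
    a: int  # 1-based atom index
    b: int
    order: int


@dataclass
class Molecule:
    """A metabolite as a labeled graph over heavy (and explicit H) atoms.

    ``atoms[i-1]`` is the atom with original file index ``i``.
    ``canonical_order``, when set, is a permutation of ``1..n_atoms``:
    ``canonical_order[k]`` is the original index of the atom at canonical
    position ``k+1``.
    """

    name: str
    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    canonical_order: tuple[int, ...] | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)

    def element(self, i: int) -> str:
        return self.atoms[i - 1].element

    def charge(self, i: int) -> int:
        return self.atoms[i - 1].charge

    @property
    def carbon_count(self) -> int:
        return sum(1 for a in self.atoms if a.element == "C")

    def carbons(self) -> list[int]:
        """Original 1-based indices of carbon atoms, in file order."""
        return [i for i, a in enumerate(self.atoms, 1) if a.element == "C"]

    def canonical_carbons(self) -> list[int]:
        """Original indices of carbons in canonical position order.

        Requires ``canonical_order``; carbon position ``p`` (1-based) in the
        ABC sense is ``canonical_carbons()[p-1]``.
        """
        if self.canonical_order is None:
            raise ValueError(f"{self.name}: canonical_order not computed")
        return [i for i in self.canonical_order if self.element(i) == "C"]

    def neighbors(self, i: int) -> list[tuple[int, int]]:
        """(neighbor index, bond order) pairs of atom ``i``."""
        out = []
        for b in self.bonds:
            if b.a == i:
                out.append((b.b, b.order))
            elif b.b == i:
                out.append((b.a, b.order))
        return out

    def check(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        n = self.n_atoms
        for b in self.bonds:
            if not (1 <= b.a <= n and 1 <= b.b <= n):
                raise ValueError(f"{self.name}: bond {b} references missing atom")
            if b.a == b.b:
                raise ValueError(f"{self.name}: self-bond on atom {b.a}")
        if self.canonical_order is not None:
            if sorted(self.canonical_order) != list(range(1, n + 1)):
                raise ValueError(f"{self.name}: canonical_order is not a permutation")


@dataclass
class MappedReaction:
    """Substrates, products and an atom-atom map between their atoms.

    The map is a set of ``((s_instance, s_atom), (p_instance, p_atom))``
    pairs; instances are 1-based positions in the substrate/product lists,
    atoms are 1-based indices into the respective molecule.
    """

    reaction_id: str
    substrates: list[Molecule] = field(default_factory=list)
    products: list[Molecule] = field(default_factory=list)
    atom_map: set[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=set)
    reversible: bool = False
    external_ids: set[tuple[str, str]] = field(default_factory=set)

    def substrate(self, inst: int) -> Molecule:
        return self.substrates[inst - 1]

    def product(self, inst: int) -> Molecule:
        return self.products[inst - 1]


# ---------------------------------------------------------------------------
# MOL reading


def _parse_counts_line(line: str, lineno: int) -> tuple[int, int]:
    if "V3000" in line:
        raise MolParseError("V3000 connection tables are not supported; "
                            "convert to V2000", lineno)
    try:
        n_atoms = int(line[0:3])
        n_bonds = int(line[3:6])
    except (ValueError, IndexError):
        raise MolParseError(f"malformed counts line {line!r}", lineno) from None
    if n_atoms < 0 or n_bonds < 0:
        raise MolParseError(f"negative counts in {line!r}", lineno)
    return n_atoms, n_bonds


def _read_mol_lines(lines: list[str], offset: int, name: str | None
                    ) -> tuple[Molecule, list[int]]:
    """Parse one MOL block given as a list of lines.

    ``offset`` is the 0-based index of the block's first line in the
    enclosing file (for error reporting). Returns the molecule and the
    per-atom map numbers (0 = unmapped).
    """
    if len(lines) < 4:
        raise MolParseError("MOL block shorter than header", offset + 1)
    header_name = lines[0].strip()
    mol_name = name if name is not None else header_name
    n_atoms, n_bonds = _parse_counts_line(lines[3], offset + 4)

    atom_first = 4
    bond_first = atom_first + n_atoms
    if len(lines) < bond_first + n_bonds:
        raise MolParseError(
            f"counts line promises {n_atoms} atoms / {n_bonds} bonds but the "
            f"block has only {len(lines) - 4} table lines", offset + 4)

    atoms: list[Atom] = []
    map_numbers: list[int] = []
    for k in range(n_atoms):
        line = lines[atom_first + k]
        lineno = offset + atom_first + k + 1
        if len(line) >= 34:
            sym = line[31:34].strip()
        else:
            parts = line.split()
            if len(parts) < 4:
                raise MolParseError(f"truncated atom line {line!r}", lineno)
            sym = parts[3]
        if sym not in KNOWN_ELEMENTS:
            raise MolParseError(f"unknown element symbol {sym!r}", lineno)
        charge = 0
        if len(line) >= 39:
            try:
                legacy = int(line[36:39])
            except ValueError:
                legacy = 0
            if legacy == 4:
                log.warning("%s: doublet radical flag on atom %d ignored",
                            mol_name, k + 1)
            else:
                charge = _LEGACY_CHARGE.get(legacy, 0)
        mapnum = 0
        if len(line) >= 63:
            try:
                mapnum = int(line[60:63])
            except ValueError:
                mapnum = 0
        atoms.append(Atom(sym, charge))
        map_numbers.append(mapnum)

    bonds: list[Bond] = []
    for k in range(n_bonds):
        line = lines[bond_first + k]
        lineno = offset + bond_first + k + 1
        try:
            a = int(line[0:3])
            b = int(line[3:6])
            order = int(line[6:9])
        except (ValueError, IndexError):
            raise MolParseError(f"malformed bond line {line!r}", lineno) from None
        if not (1 <= a <= n_atoms and 1 <= b <= n_atoms):
            raise MolParseError(
                f"bond references atom outside 1..{n_atoms}", lineno)
        if a == b:
            raise MolParseError(f"self-bond on atom {a}", lineno)
        bonds.append(Bond(a, b, order))

    # Property block: honor charges, ignore the rest with a note.
    for k in range(bond_first + n_bonds, len(lines)):
        line = lines[k]
        if line.startswith("M  END"):
            break
        if line.startswith("M  CHG"):
            fields = line.split()
            try:
                n_entries = int(fields[2])
                pairs = fields[3:3 + 2 * n_entries]
                for idx, chg in zip(pairs[0::2], pairs[1::2]):
                    i = int(idx)
                    if not 1 <= i <= n_atoms:
                        raise ValueError
                    atoms[i - 1] = replace(atoms[i - 1], charge=int(chg))
            except (ValueError, IndexError):
                raise MolParseError(f"malformed M  CHG line {line!r}",
                                    offset + k + 1) from None
        elif line.startswith(("M  ISO", "M  RAD")):
            log.warning("%s: property line %r ignored", mol_name, line.strip())

    mol = Molecule(mol_name, atoms, bonds)
    mol.check()
    return mol, map_numbers


def read_mol(text: str, name: str | None = None) -> Molecule:
    """Parse a V2000 MOL file into a :class:`Molecule` (file atom order)."""
    mol, _ = _read_mol_lines(text.splitlines(), 0, name)
    return mol


# ---------------------------------------------------------------------------
# MOL writing


def _emit_order(m: Molecule) -> list[int]:
    return list(m.canonical_order) if m.canonical_order is not None \
        else list(range(1, m.n_atoms + 1))


def _mol_block(m: Molecule, map_numbers: dict[int, int] | None = None) -> str:
    """Render a V2000 MOL block; atoms in canonical order when present.

    ``map_numbers`` keys are original atom indices.
    """
    if m.n_atoms > 999 or m.n_bonds > 999:
        raise CapacityError(
            f"{m.name}: {m.n_atoms} atoms / {m.n_bonds} bonds exceed the "
            "V2000 3-digit field width")
    order = _emit_order(m)
    new_index = {orig: k + 1 for k, orig in enumerate(order)}
    lines = [m.name, "  atomtrail", "",
             f"{m.n_atoms:>3}{m.n_bonds:>3}  0  0  0  0  0  0  0  0999 V2000"]
    charged = []
    for orig in order:
        atom = m.atoms[orig - 1]
        mapnum = (map_numbers or {}).get(orig, 0)
        lines.append(
            f"{0.0:>10.4f}{0.0:>10.4f}{0.0:>10.4f} {atom.element:<3}"
            + " 0  0" + "  0" * 7 + f"{mapnum:>3}" + "  0  0")
        if atom.charge:
            charged.append((new_index[orig], atom.charge))
    for b in sorted((min(new_index[b.a], new_index[b.b]),
                     max(new_index[b.a], new_index[b.b]), b.order)
                    for b in m.bonds):
        lines.append(f"{b[0]:>3}{b[1]:>3}{b[2]:>3}  0  0  0  0")
    for i, chg in charged:
        lines.append(f"M  CHG  1{i:>4}{chg:>4}")
    lines.append("M  END")
    return "\n".join(lines) + "\n"


def write_mol(m: Molecule) -> str:
    """Serialize to V2000 text; atoms in canonical order when computed."""
    m.check()
    return _mol_block(m)


# ---------------------------------------------------------------------------
# RXN


def read_rxn(text: str, reaction_id: str | None = None) -> MappedReaction:
    """Parse a V2000 RXN file, reconstructing the atom map.

    Shared nonzero map numbers pair substrate and product atoms; 0 means
    unmapped. A nonzero number must appear on exactly one substrate atom
    and exactly one product atom, otherwise the mapping is not a bijection
    and a :class:`MappingIntegrityError` is raised.
    """
    lines = text.splitlines()
    if not lines or not lines[0].startswith("$RXN"):
        raise MolParseError("missing $RXN header", 1)
    if "V3000" in lines[0]:
        raise MolParseError("V3000 RXN files are not supported", 1)
    if len(lines) < 5:
        raise MolParseError("RXN header truncated", len(lines))
    rxn_name = lines[1].strip()
    try:
        n_sub = int(lines[4][0:3])
        n_prod = int(lines[4][3:6])
    except (ValueError, IndexError):
        raise MolParseError(f"malformed RXN counts line {lines[4]!r}", 5) from None

    # Split into $MOL blocks.
    starts = [k for k, line in enumerate(lines) if line.startswith("$MOL")]
    if len(starts) != n_sub + n_prod:
        raise MolParseError(
            f"header promises {n_sub}+{n_prod} molecules but file contains "
            f"{len(starts)} $MOL blocks", 5)
    starts.append(len(lines))

    molecules: list[tuple[Molecule, list[int]]] = []
    for k in range(len(starts) - 1):
        first = starts[k] + 1
        block = lines[first:starts[k + 1]]
        # trim trailing blanks after M  END
        for end, line in enumerate(block):
            if line.startswith("M  END"):
                block = block[:end + 1]
                break
        molecules.append(_read_mol_lines(block, first, None))

    substrates = [m for m, _ in molecules[:n_sub]]
    products = [m for m, _ in molecules[n_sub:]]

    sub_seen: dict[int, tuple[int, int]] = {}
    prod_seen: dict[int, tuple[int, int]] = {}
    for side, seen, mols in (("substrate", sub_seen, molecules[:n_sub]),
                             ("product", prod_seen, molecules[n_sub:])):
        for inst, (mol, mapnums) in enumerate(mols, 1):
            for atom_idx, num in enumerate(mapnums, 1):
                if num == 0:
                    continue
                if num in seen:
                    raise MappingIntegrityError(
                        f"{rxn_name or reaction_id}: map number {num} appears "
                        f"on more than one {side} atom")
                seen[num] = (inst, atom_idx)

    dangling = set(sub_seen) ^ set(prod_seen)
    if dangling:
        raise MappingIntegrityError(
            f"{rxn_name or reaction_id}: map numbers {sorted(dangling)} "
            "appear on one side of the reaction only")

    atom_map = {(sub_seen[num], prod_seen[num]) for num in sub_seen}
    return MappedReaction(
        reaction_id=reaction_id or rxn_name or "reaction",
        substrates=substrates, products=products, atom_map=atom_map)


def write_rxn(r: MappedReaction) -> str:
    """Serialize a reaction to V2000 RXN text.

    Map numbers are regenerated deterministically (pairs numbered in
    substrate instance/emitted-atom order); unmapped atoms get 0.
    """
    for m in r.substrates + r.products:
        m.check()
    pair_order = []
    for (s, p) in r.atom_map:
        s_mol = r.substrate(s[0])
        emitted_pos = _emit_order(s_mol).index(s[1])
        pair_order.append((s[0], emitted_pos, s, p))
    pair_order.sort(key=lambda t: (t[0], t[1]))
    sub_nums: list[dict[int, int]] = [{} for _ in r.substrates]
    prod_nums: list[dict[int, int]] = [{} for _ in r.products]
    for num, (_, _, s, p) in enumerate(pair_order, 1):
        sub_nums[s[0] - 1][s[1]] = num
        prod_nums[p[0] - 1][p[1]] = num

    parts = ["$RXN", r.reaction_id, "", " atomtrail",
             f"{len(r.substrates):>3}{len(r.products):>3}"]
    text = "\n".join(parts) + "\n"
    for mol, nums in zip(r.substrates, sub_nums):
        text += "$MOL\n" + _mol_block(mol, nums)
    for mol, nums in zip(r.products, prod_nums):
        text += "$MOL\n" + _mol_block(mol, nums)
    return text
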