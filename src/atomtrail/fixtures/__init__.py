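"""Offline toy central-carbon fixture set and random-molecule generator.

Everything tests and demos need is generated from connection tables
embedded below — no downloads, no binary data. The set covers:

* a condensed, cofactor-free glycolysis (glucose -> pyruvate in the ten
  classic steps, open-chain sugar structures, phosphate groups carried on
  the skeletons but no ATP/NAD bookkeeping);
* pyruvate dehydrogenase with acetyl-CoA restricted to its 2-carbon
  acetyl moiety (C1 = carbonyl, C2 = methyl, the convention under which
  a methyl-labeled pyruvate yields C2-labeled acetyl-CoA);
* glutaminase, glutamate decarboxylase (GABA) and a thiolase-style
  condensation (stoichiometric coefficient 2);
* fumarase, whose symmetric substrate exercises the symmetry machinery;
* a full cofactor-bearing hexokinase (real ATP/ADP structures, built
  programmatically) to demonstrate cofactor omission;
* benzene (orbit tests) and an identity pyruvate transport.

Carbon fates encode textbook biochemistry: glucose C1 (the aldehyde
carbon) travels C1 -> F16BP C1 -> DHAP C1 -> GAP C3 -> pyruvate C3
(methyl), and decarboxylation fates follow the carboxyl carbons. Atom
maps are carbon-complete; heteroatoms are left unmapped (the carbon model
never consults them).

All structures are written in conventional chain numbering (C1 = the
most oxidized chain end), which is also documented per metabolite in
``CHAIN_NUMBERING_NOTES`` where it matters.
"""

from __future__ import annotations

import random
from pathlib import Path

from .. import chem_io
from ..chem_io import Atom, Bond, MappedReaction, Molecule

__all__ = [
    "MOLECULE_NAMES", "REACTION_NAMES", "molecule", "reaction",
    "build_fixture_store", "random_molecule", "GLYCOLYSIS_PATH",
    "PDH_PATH", "ALDOLASE_ERROR_SWAP", "TOY_GLYCOLYSIS_CSV",
    "GLUTAMINE_GABA_STORE_CSV", "GLUTAMINE_GABA_CUSTOM_CSV",
    "HEXOKINASE_FULL_CSV", "THIOLASE_CSV",
]

# ---------------------------------------------------------------------------
# Structures: (space-separated element symbols, bonds (a, b, order))
# Atom indices are 1-based; carbons always listed first in chain order.

_GLUCOSE_BONDS = [(1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (5, 6, 1),
                  (1, 7, 2), (2, 8, 1), (3, 9, 1), (4, 10, 1), (5, 11, 1),
                  (6, 12, 1)]

_STRUCTURES: dict[str, tuple[str, list[tuple[int, int, int]]]] = {
    # open-chain aldose: C1 = aldehyde
    "glucose": ("C C C C C C O O O O O O", _GLUCOSE_BONDS),
    "G6P": ("C C C C C C O O O O O O P O O O",
            _GLUCOSE_BONDS + [(12, 13, 1), (13, 14, 2), (13, 15, 1),
                              (13, 16, 1)]),
    # open-chain ketose: C2 = keto
    "F6P": ("C C C C C C O O O O O O P O O O",
            [(1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (5, 6, 1),
             (1, 7, 1), (2, 8, 2), (3, 9, 1), (4, 10, 1), (5, 11, 1),
             (6, 12, 1), (12, 13, 1), (13, 14, 2), (13, 15, 1), (13, 16, 1)]),
    "F16BP": ("C C C C C C O O O O O O P O O O P O O O",
              [(1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (5, 6, 1),
               (1, 7, 1), (2, 8, 2), (3, 9, 1), (4, 10, 1), (5, 11, 1),
               (6, 12, 1), (12, 13, 1), (13, 14, 2), (13, 15, 1),
               (13, 16, 1), (7, 17, 1), (17, 18, 2), (17, 19, 1),
               (17, 20, 1)]),
    # C1 = phospho-methylene (from F16BP C1), C2 = keto, C3 = hydroxymethyl
    "DHAP": ("C C C O O O P O O O",
             [(1, 2, 1), (2, 3, 1), (1, 4, 1), (2, 5, 2), (3, 6, 1),
              (4, 7, 1), (7, 8, 2), (7, 9, 1), (7, 10, 1)]),
    # C1 = aldehyde, C3 = phospho-methylene
    "GAP": ("C C C O O O P O O O",
            [(1, 2, 1), (2, 3, 1), (1, 4, 2), (2, 5, 1), (3, 6, 1),
             (6, 7, 1), (7, 8, 2), (7, 9, 1), (7, 10, 1)]),
    # 1,3-bisphosphoglycerate: acyl phosphate on C1, ester phosphate on C3
    "BPG13": ("C C C O O O O P O O O P O O O",
              [(1, 2, 1), (2, 3, 1), (1, 4, 2), (1, 5, 1), (2, 6, 1),
               (3, 7, 1), (5, 8, 1), (8, 9, 2), (8, 10, 1), (8, 11, 1),
               (7, 12, 1), (12, 13, 2), (12, 14, 1), (12, 15, 1)]),
    "PG3": ("C C C O O O O P O O O",
            [(1, 2, 1), (2, 3, 1), (1, 4, 2), (1, 5, 1), (2, 6, 1),
             (3, 7, 1), (7, 8, 1), (8, 9, 2), (8, 10, 1), (8, 11, 1)]),
    "PG2": ("C C C O O O O P O O O",
            [(1, 2, 1), (2, 3, 1), (1, 4, 2), (1, 5, 1), (2, 6, 1),
             (3, 7, 1), (6, 8, 1), (8, 9, 2), (8, 10, 1), (8, 11, 1)]),
    "PEP": ("C C C O O O P O O O",
            [(1, 2, 1), (2, 3, 2), (1, 4, 2), (1, 5, 1), (2, 6, 1),
             (6, 7, 1), (7, 8, 2), (7, 9, 1), (7, 10, 1)]),
    # C1 = carboxyl, C2 = keto, C3 = methyl
    "pyruvate": ("C C C O O O",
                 [(1, 2, 1), (2, 3, 1), (1, 4, 2), (1, 5, 1), (2, 6, 2)]),
    # acetyl moiety only (C1 = carbonyl, C2 = methyl); the CoA arm is not
    # modeled — carboxylate oxygens stand in for the thioester linkage
    "acetyl-CoA": ("C C O O", [(1, 2, 1), (1, 3, 2), (1, 4, 1)]),
    "acetoacetate": ("C C C C O O O",
                     [(1, 2, 1), (2, 3, 1), (3, 4, 1), (1, 5, 2), (1, 6, 1),
                      (3, 7, 2)]),
    "CO2": ("C O O", [(1, 2, 2), (1, 3, 2)]),
    "water": ("O", []),
    "ammonia": ("N", []),
    # C1 = alpha-carboxyl, C2 = alpha carbon, C5 = side-chain amide/carboxyl
    "glutamine": ("C C C C C N O O O N",
                  [(1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (2, 6, 1),
                   (1, 7, 2), (1, 8, 1), (5, 9, 2), (5, 10, 1)]),
    "glutamate": ("C C C C C N O O O O",
                  [(1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (2, 6, 1),
                   (1, 7, 2), (1, 8, 1), (5, 9, 2), (5, 10, 1)]),
    # C1 = carboxyl (glutamate's former C5), C4 = amine-bearing carbon
    "GABA": ("C C C C N O O",
             [(1, 2, 1), (2, 3, 1), (3, 4, 1), (4, 5, 1), (1, 6, 2),
              (1, 7, 1)]),
    "fumarate": ("C C C C O O O O",
                 [(1, 2, 1), (2, 3, 2), (3, 4, 1), (1, 5, 2), (1, 6, 1),
                  (4, 7, 2), (4, 8, 1)]),
    "malate": ("C C C C O O O O O",
               [(1, 2, 1), (2, 3, 1), (3, 4, 1), (1, 5, 2), (1, 6, 1),
                (2, 7, 1), (4, 8, 2), (4, 9, 1)]),
    # Kekulé benzene; full automorphism enumeration still yields one orbit
    "benzene": ("C C C C C C",
                [(1, 2, 2), (2, 3, 1), (3, 4, 2), (4, 5, 1), (5, 6, 2),
                 (6, 1, 1)]),
}


def _adenosine_phosphates(n_phosphates: int) -> tuple[str, list]:
    """Adenosine 5'-mono/di/tri-phosphate connection table.

    Adenine atoms 1-10 (carbons 2,4,5,6,9), ribose atoms 11-19
    (carbons 11-15 = C1'..C5'), then the phosphate chain. The atom
    ordering is identical for every chain length, so ATP -> ADP carbon
    maps are the identity on atom indices.
    """
    elements: list[str] = []
    bonds: list[tuple[int, int, int]] = []

    def add(symbol: str) -> int:
        elements.append(symbol)
        return len(elements)

    n1, c2, n3, c4, c5 = add("N"), add("C"), add("N"), add("C"), add("C")
    c6, n6, n7, c8, n9 = add("C"), add("N"), add("N"), add("C"), add("N")
    bonds += [(n1, c2, 2), (c2, n3, 1), (n3, c4, 2), (c4, c5, 1),
              (c5, c6, 2), (c6, n1, 1), (c6, n6, 1), (c5, n7, 1),
              (n7, c8, 2), (c8, n9, 1), (n9, c4, 1)]
    c1p, c2p, c3p, c4p, c5p = add("C"), add("C"), add("C"), add("C"), add("C")
    o4p, o2p, o3p, o5p = add("O"), add("O"), add("O"), add("O")
    bonds += [(c1p, c2p, 1), (c2p, c3p, 1), (c3p, c4p, 1), (c4p, o4p, 1),
              (o4p, c1p, 1), (c1p, n9, 1), (c2p, o2p, 1), (c3p, o3p, 1),
              (c4p, c5p, 1), (c5p, o5p, 1)]
    prev = o5p
    for i in range(n_phosphates):
        p = add("P")
        bonds.append((prev, p, 1))
        bonds.append((p, add("O"), 2))
        bonds.append((p, add("O"), 1))
        if i < n_phosphates - 1:
            prev = add("O")
            bonds.append((p, prev, 1))
        else:
            bonds.append((p, add("O"), 1))
    return " ".join(elements), bonds


_STRUCTURES["ATP"] = _adenosine_phosphates(3)
_STRUCTURES["ADP"] = _adenosine_phosphates(2)

#: Carbon atom indices of the adenosine scaffold (same in ATP and ADP).
_ADENOSINE_CARBONS = [2, 4, 5, 6, 9, 11, 12, 13, 14, 15]

MOLECULE_NAMES = tuple(sorted(_STRUCTURES))

CHAIN_NUMBERING_NOTES = {
    "glucose": "C1 = aldehyde carbon ([1-13C1]glucose labels it)",
    "pyruvate": "C1 = carboxyl, C2 = keto, C3 = methyl",
    "acetyl-CoA": "acetyl moiety: C1 = carbonyl, C2 = methyl",
    "glutamate": "C1 = alpha-carboxyl, C5 = side-chain carboxyl",
    "GABA": "C1 = carboxyl (glutamate C5 lineage)",
}


def molecule(name: str) -> Molecule:
    """A fresh :class:`Molecule` for a fixture structure (file order)."""
    elements, bonds = _STRUCTURES[name]
    mol = Molecule(name,
                   [Atom(sym) for sym in elements.split()],
                   [Bond(a, b, o) for a, b, o in bonds])
    mol.check()
    return mol


# ---------------------------------------------------------------------------
# Reactions: carbon-complete atom maps over file-order atom indices.


def _identity(n: int, si: int = 1, pi: int = 1):
    return [((si, k), (pi, k)) for k in range(1, n + 1)]


_REACTIONS: dict[str, dict] = {
    "HK": dict(substrates=["glucose"], products=["G6P"], reversible=False,
               carbon_map=_identity(6),
               ids=[("KEGG", "R00299"), ("MetaCyc", "GLUCOKIN-RXN")]),
    "HK_ATP": dict(substrates=["glucose", "ATP"], products=["G6P", "ADP"],
                   reversible=False,
                   carbon_map=_identity(6)
                   + [((2, c), (2, c)) for c in _ADENOSINE_CARBONS],
                   ids=[("MetaCyc", "GLUCOKIN-RXN-FULL"),
                        ("BRENDA", "BR27111")]),
    "PGI": dict(substrates=["G6P"], products=["F6P"], reversible=True,
                carbon_map=_identity(6),
                ids=[("KEGG", "R00771"), ("MetaCyc", "PGLUCISOM-RXN")]),
    "PFK": dict(substrates=["F6P"], products=["F16BP"], reversible=False,
                carbon_map=_identity(6),
                ids=[("KEGG", "R00756"), ("MetaCyc", "6PFRUCTPHOS-RXN")]),
    # retro-aldol split: C1-C3 -> DHAP, C4-C6 -> GAP (GAP C1 = old C4)
    "ALDO": dict(substrates=["F16BP"], products=["DHAP", "GAP"],
                 reversible=True,
                 carbon_map=[((1, 1), (1, 1)), ((1, 2), (1, 2)),
                             ((1, 3), (1, 3)), ((1, 4), (2, 1)),
                             ((1, 5), (2, 2)), ((1, 6), (2, 3))],
                 ids=[("KEGG", "R01068"), ("MetaCyc", "F16ALDOLASE-RXN")]),
    # isomerization flips the chain: DHAP C1 (phospho end) -> GAP C3
    "TPI": dict(substrates=["DHAP"], products=["GAP"], reversible=True,
                carbon_map=[((1, 1), (1, 3)), ((1, 2), (1, 2)),
                            ((1, 3), (1, 1))],
                ids=[("KEGG", "R01015"),
                     ("MetaCyc", "TRIOSEPISOMERIZATION-RXN")]),
    "GAPDH": dict(substrates=["GAP"], products=["BPG13"], reversible=True,
                  carbon_map=_identity(3),
                  ids=[("KEGG", "R01061"), ("MetaCyc", "GAPOXNPHOSPHN-RXN")]),
    "PGK": dict(substrates=["BPG13"], products=["PG3"], reversible=True,
                carbon_map=_identity(3),
                ids=[("KEGG", "R01512"), ("MetaCyc", "PHOSGLYPHOS-RXN")]),
    "PGM": dict(substrates=["PG3"], products=["PG2"], reversible=True,
                carbon_map=_identity(3),
                ids=[("KEGG", "R01518"), ("MetaCyc", "3PGAREARR-RXN")]),
    "ENO": dict(substrates=["PG2"], products=["PEP", "water"],
                reversible=True, carbon_map=_identity(3),
                ids=[("KEGG", "R00658"), ("MetaCyc", "2PGADEHYDRAT-RXN")]),
    "PK": dict(substrates=["PEP"], products=["pyruvate"], reversible=False,
               carbon_map=_identity(3),
               ids=[("KEGG", "R00200"), ("MetaCyc", "PEPDEPHOS-RXN")]),
    # decarboxylation: carboxyl -> CO2, keto -> acetyl C1, methyl -> C2
    "PDH": dict(substrates=["pyruvate"], products=["acetyl-CoA", "CO2"],
                reversible=False,
                carbon_map=[((1, 1), (2, 1)), ((1, 2), (1, 1)),
                            ((1, 3), (1, 2))],
                ids=[("KEGG", "R00209"), ("MetaCyc", "PYRUVDEH-RXN")]),
    "GLS": dict(substrates=["glutamine", "water"],
                products=["glutamate", "ammonia"], reversible=False,
                carbon_map=_identity(5),
                ids=[("KEGG", "R00256"), ("MetaCyc", "GLUTAMIN-RXN"),
                     ("BRENDA", "BS35102")]),
    # alpha-decarboxylation: C1 -> CO2; chain reverses its numbering
    "GAD": dict(substrates=["glutamate"], products=["GABA", "CO2"],
                reversible=False,
                carbon_map=[((1, 1), (2, 1)), ((1, 2), (1, 4)),
                            ((1, 3), (1, 3)), ((1, 4), (1, 2)),
                            ((1, 5), (1, 1))],
                ids=[("KEGG", "R00261"), ("MetaCyc", "GLUTDECARBOX-RXN")]),
    # hydration across the double bond (OH placed on C2)
    "FUM": dict(substrates=["fumarate", "water"], products=["malate"],
                reversible=True, carbon_map=_identity(4),
                ids=[("KEGG", "R01082"), ("MetaCyc", "FUMHYDR-RXN")]),
    # Claisen condensation of two acetyl units
    "THL": dict(substrates=["acetyl-CoA", "acetyl-CoA"],
                products=["acetoacetate"], reversible=True,
                carbon_map=[((1, 1), (1, 3)), ((1, 2), (1, 4)),
                            ((2, 1), (1, 1)), ((2, 2), (1, 2))],
                ids=[("KEGG", "R00238"),
                     ("MetaCyc", "ACETOACETYL-COA-SYN-RXN")]),
    "PYRT": dict(substrates=["pyruvate"], products=["pyruvate"],
                 reversible=True, carbon_map=_identity(3),
                 ids=[("MetaCyc", "TRANS-RXN-PYR")]),
}

REACTION_NAMES = tuple(sorted(_REACTIONS))

GLYCOLYSIS_PATH = ["HK", "PGI", "PFK", "ALDO", "TPI", "GAPDH", "PGK",
                   "PGM", "ENO", "PK"]
#: Glycolysis continued through pyruvate dehydrogenase.
PDH_PATH = GLYCOLYSIS_PATH + ["PDH"]

#: Documented single-error injection for the aldolase entry: swapping
#: these two product-side letters exchanges the fates of F16BP's C1 and
#: C3 lineages (the two termini of the DHAP half), rerouting a C1
#: glucose label from the pyruvate methyl carbon to the carboxyl carbon
#: (and onward into CO2 at PDH). The letters refer to the toy glycolysis
#: model built with default options, where the aldolase entry reads
#: ``F16BP (abcdef) -> DHAP (aeb) + GAP (cdf)``.
ALDOLASE_ERROR_SWAP = ("b", "e")


def reaction(name: str) -> MappedReaction:
    """A fresh :class:`MappedReaction` fixture (file-order indices)."""
    spec = _REACTIONS[name]
    return MappedReaction(
        reaction_id=name,
        substrates=[molecule(n) for n in spec["substrates"]],
        products=[molecule(n) for n in spec["products"]],
        atom_map=set(spec["carbon_map"]),
        reversible=spec["reversible"],
        external_ids=set(spec["ids"]))


# ---------------------------------------------------------------------------
# Model CSVs

TOY_GLYCOLYSIS_CSV = """\
reaction,substrates,reversibility,products
HK [KEGG:R00299],glucose [MetaCyc:GLC],irreversible,G6P
PGI [KEGG:R00771],G6P,reversible,F6P
PFK [KEGG:R00756],F6P,irreversible,F16BP
ALDO [KEGG:R01068],F16BP,reversible,DHAP + GAP
TPI [KEGG:R01015],DHAP,reversible,GAP
GAPDH [KEGG:R01061],GAP,reversible,BPG13
PGK [KEGG:R01512],BPG13,reversible,PG3
PGM [KEGG:R01518],PG3,reversible,PG2
ENO [KEGG:R00658],PG2,reversible,PEP
PK [KEGG:R00200],PEP,irreversible,pyruvate [MetaCyc:PYRUVATE]
PDH [KEGG:R00209],pyruvate,irreversible,acetyl-CoA {C:2} + CO2
"""

GLUTAMINE_GABA_STORE_CSV = """\
reaction,substrates,reversibility,products
GLS [MetaCyc:GLUTAMIN-RXN],glutamine [MetaCyc:GLN],irreversible,glutamate [MetaCyc:GLT]
GAD [KEGG:R00261],glutamate,irreversible,GABA + CO2
"""

#: Same network with the GABA step supplied as a custom user mapping
#: (letters in canonical carbon order, consistent with the store-derived
#: glutaminase entry above it).
GLUTAMINE_GABA_CUSTOM_CSV = """\
reaction,substrates,reversibility,products
GLS [MetaCyc:GLUTAMIN-RXN],glutamine,irreversible,glutamate
GAD [custom:GAD-MANUAL],glutamate (abcde),irreversible,GABA (bcde) + CO2 (a)
"""

HEXOKINASE_FULL_CSV = """\
reaction,substrates,reversibility,products
HK [MetaCyc:GLUCOKIN-RXN-FULL],glucose + ATP,irreversible,G6P + ADP
"""

THIOLASE_CSV = """\
reaction,substrates,reversibility,products
THL [KEGG:R00238],2 acetyl-CoA,reversible,acetoacetate
"""

FUMARASE_CSV = """\
reaction,substrates,reversibility,products
FUM [KEGG:R01082],fumarate,reversible,malate
"""

_MODEL_FILES = {
    "toy_glycolysis.csv": TOY_GLYCOLYSIS_CSV,
    "glutamine_gaba_store.csv": GLUTAMINE_GABA_STORE_CSV,
    "glutamine_gaba_custom.csv": GLUTAMINE_GABA_CUSTOM_CSV,
    "hexokinase_full.csv": HEXOKINASE_FULL_CSV,
    "thiolase.csv": THIOLASE_CSV,
    "fumarase.csv": FUMARASE_CSV,
}

_METABOLITE_IDS = [
    ("KEGG", "C00022", "pyruvate"),
    ("KEGG", "C00024", "acetyl-CoA"),
    ("KEGG", "C00025", "glutamate"),
    ("KEGG", "C00031", "glucose"),
    ("KEGG", "C00064", "glutamine"),
    ("MetaCyc", "4-AMINO-BUTYRATE", "GABA"),
    ("MetaCyc", "ACETYL-COA", "acetyl-CoA"),
    ("MetaCyc", "ADP", "ADP"),
    ("MetaCyc", "ATP", "ATP"),
    ("MetaCyc", "CARBON-DIOXIDE", "CO2"),
    ("MetaCyc", "FUM", "fumarate"),
    ("MetaCyc", "GLC", "glucose"),
    ("MetaCyc", "GLN", "glutamine"),
    ("MetaCyc", "GLT", "glutamate"),
    ("MetaCyc", "GLUCOSE-6P", "G6P"),
    ("MetaCyc", "PYRUVATE", "pyruvate"),
]

_ALIASES = [
    ("D-glucose", "glucose"),
    ("L-glutamate", "glutamate"),
    ("L-glutamine", "glutamine"),
    ("alpha-D-glucose", "glucose"),
    ("gamma-aminobutyrate", "GABA"),
    ("glucose 6-phosphate", "G6P"),
]


def build_fixture_store(directory: str | Path) -> Path:
    """Write the complete fixture store into ``directory``.

    Emits one RXN file per curated reaction, one MOL file per structure
    (under ``molecules/``), the store index, metabolite-identifier and
    alias tables, and the example model CSVs. Output is deterministic:
    identical bytes on every call.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index_rows = ["database,identifier,file,reversibility"]
    for name in REACTION_NAMES:
        r = reaction(name)
        (directory / f"{name}.rxn").write_text(chem_io.write_rxn(r))
        rev = "reversible" if r.reversible else "irreversible"
        for db, ident in sorted(r.external_ids):
            index_rows.append(f"{db},{ident},{name}.rxn,{rev}")
    (directory / "index.csv").write_text("\n".join(index_rows) + "\n")
    (directory / "metabolites.csv").write_text(
        "database,identifier,name\n"
        + "\n".join(f"{db},{ident},{name}"
                    for db, ident, name in _METABOLITE_IDS) + "\n")
    (directory / "aliases.csv").write_text(
        "alias,name\n"
        + "\n".join(f"{alias},{name}" for alias, name in _ALIASES) + "\n")
    mol_dir = directory / "molecules"
    mol_dir.mkdir(exist_ok=True)
    for name in MOLECULE_NAMES:
        (mol_dir / f"{name}.mol").write_text(chem_io.write_mol(molecule(name)))
    for filename, text in _MODEL_FILES.items():
        (directory / filename).write_text(text)
    return directory


# ---------------------------------------------------------------------------
# Random molecules for property tests

_RANDOM_ELEMENTS = ["C", "C", "C", "C", "C", "C", "C", "N", "O", "O"]
_MAX_VALENCE = {"C": 4, "N": 3, "O": 2}


def random_molecule(seed: int, n_heavy: int = 8) -> Molecule:
    """Deterministic, connected, valence-plausible random molecule.

    A random spanning tree over ``n_heavy`` atoms drawn from {C, N, O}
    with occasional double bonds and extra ring-closing edges, capped by
    standard valences. The same seed always yields the same molecule.
    """
    if n_heavy < 1:
        raise ValueError("n_heavy must be >= 1")
    rng = random.Random(seed)
    elements = [rng.choice(_RANDOM_ELEMENTS) for _ in range(n_heavy)]
    valence = {i: _MAX_VALENCE[elements[i - 1]] for i in range(1, n_heavy + 1)}
    bonds: list[Bond] = []
    for i in range(2, n_heavy + 1):
        candidates = [j for j in range(1, i) if valence[j] >= 1]
        if not candidates:  # all earlier valences spent: chain onto previous
            candidates = [i - 1]
        j = rng.choice(candidates)
        order = 2 if (valence[j] >= 2 and valence[i] >= 2
                      and rng.random() < 0.15) else 1
        bonds.append(Bond(j, i, order))
        valence[i] -= order
        valence[j] -= order
    # occasional ring closure
    if n_heavy >= 4 and rng.random() < 0.3:
        open_atoms = [i for i in valence if valence[i] >= 1]
        rng.shuffle(open_atoms)
        existing = {(min(b.a, b.b), max(b.a, b.b)) for b in bonds}
        for a in open_atoms:
            partners = [b for b in open_atoms
                        if b != a and (min(a, b), max(a, b)) not in existing]
            if partners:
                b = partners[0]
                bonds.append(Bond(min(a, b), max(a, b), 1))
                valence[a] -= 1
                valence[b] -= 1
                break
    mol = Molecule(f"rand-{seed}", [Atom(e) for e in elements], bonds)
    mol.check()
    return mol
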