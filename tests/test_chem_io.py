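"""MOL/RXN V2000 round trips, error handling, and an RDKit cross-check."""

import pytest
from rdkit import Chem, RDLogger

import atomtrail as at
from atomtrail import fixtures as fx
from atomtrail.chem_io import Atom, Molecule
from atomtrail.errors import CapacityError, MappingIntegrityError, MolParseError

RDLogger.DisableLog("rdApp.*")

MINIMAL_MOL = """methane skeleton
  test

  1  0  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0  0  0  0  0  0  0  0  0  0  0
M  END
"""


def bond_multiset(m):
    return sorted((min(b.a, b.b), max(b.a, b.b), b.order) for b in m.bonds)


class TestReadMol:
    def test_minimal_single_carbon(self):
        m = at.read_mol(MINIMAL_MOL)
        assert m.n_atoms == 1
        assert m.n_bonds == 0
        assert m.atoms[0] == Atom("C")
        assert m.canonical_order is None

    def test_glutamine_has_five_carbons(self):
        text = at.write_mol(fx.molecule("glutamine"))
        m = at.read_mol(text)
        assert m.carbon_count == 5

    def test_fumarate_composition_by_hand_count(self):
        # HOOC-CH=CH-COOH: 4 C, 4 O; bonds: 3 C-C + 4 C-O = 7
        m = at.read_mol(at.write_mol(fx.molecule("fumarate")))
        assert m.carbon_count == 4
        assert sum(a.element == "O" for a in m.atoms) == 4
        assert m.n_bonds == 7

    @pytest.mark.parametrize("mutation, match", [
        (lambda t: t.replace("V2000", "V3000"), "V3000"),
        (lambda t: t.replace("  1  0", " xx  0"), "counts"),
        (lambda t: t.replace(" C  ", " Xx "), "element"),
    ])
    def test_malformed_input_errors_name_the_line(self, mutation, match):
        with pytest.raises(MolParseError, match=match) as exc:
            at.read_mol(mutation(MINIMAL_MOL))
        assert exc.value.line is not None

    def test_block_shorter_than_counts_promise(self):
        text = MINIMAL_MOL.replace("  1  0", "  2  1")
        with pytest.raises(MolParseError):
            at.read_mol(text)

    def test_charge_via_property_block(self):
        text = MINIMAL_MOL.replace("M  END", "M  CHG  1   1  -1\nM  END")
        assert at.read_mol(text).atoms[0].charge == -1


class TestWriteMol:
    def test_round_trip_every_fixture_molecule(self):
        for name in fx.MOLECULE_NAMES:
            m = fx.molecule(name)
            m2 = at.read_mol(at.write_mol(m))
            assert m2.atoms == m.atoms, name
            assert bond_multiset(m2) == bond_multiset(m), name

    def test_canonical_order_persists_through_file(self):
        m = at.canonical_order(fx.molecule("glutamate"))
        reread = at.read_mol(at.write_mol(m))
        expected = at.reorder_to_canonical(m)
        assert reread.atoms == expected.atoms
        assert bond_multiset(reread) == bond_multiset(expected)

    def test_capacity_error_above_999_atoms(self):
        big = Molecule("too-big", [Atom("C")] * 1000, [])
        with pytest.raises(CapacityError):
            at.write_mol(big)


class TestRxn:
    def test_identity_reaction_yields_identity_map(self):
        r = at.read_rxn(at.write_rxn(fx.reaction("PYRT")))
        assert r.atom_map == {((1, k), (1, k)) for k in (1, 2, 3)}

    def test_glutaminase_maps_all_five_carbons_element_matched(self):
        r = at.read_rxn(at.write_rxn(fx.reaction("GLS")))
        carbon_pairs = [(s, p) for s, p in r.atom_map
                        if r.substrate(s[0]).element(s[1]) == "C"]
        assert len(carbon_pairs) == 5
        for s, p in r.atom_map:
            assert r.substrate(s[0]).element(s[1]) == \
                r.product(p[0]).element(p[1])

    def test_duplicate_map_number_is_integrity_error(self):
        text = at.write_rxn(fx.reaction("PYRT"))
        # first substrate atom carries map 1; give it map 2 as well -> the
        # number 2 now appears on two substrate atoms
        lines = text.splitlines()
        atom_lines = [i for i, l in enumerate(lines) if len(l) > 62
                      and l.endswith("  0  0")
                      and l[60:63].strip() not in ("", "0")]
        first = atom_lines[0]
        lines[first] = lines[first][:60] + "  2" + lines[first][63:]
        with pytest.raises(MappingIntegrityError, match="map number 2"):
            at.read_rxn("\n".join(lines))

    def test_one_sided_map_number_is_integrity_error(self):
        text = at.write_rxn(fx.reaction("PYRT"))
        lines = text.splitlines()
        atom_lines = [i for i, l in enumerate(lines) if len(l) > 62
                      and l.endswith("  0  0")
                      and l[60:63].strip() not in ("", "0")]
        lines[atom_lines[0]] = (lines[atom_lines[0]][:60] + "  9"
                                + lines[atom_lines[0]][63:])
        with pytest.raises(MappingIntegrityError, match="one side"):
            at.read_rxn("\n".join(lines))

    def test_header_molecule_count_mismatch(self):
        text = at.write_rxn(fx.reaction("PYRT"))
        with pytest.raises(MolParseError, match="MOL blocks"):
            at.read_rxn(text.replace("  1  1", "  2  1", 1))

    @pytest.mark.parametrize("name", fx.REACTION_NAMES)
    def test_read_write_read_is_identity(self, name):
        r1 = fx.reaction(name)
        r2 = at.read_rxn(at.write_rxn(r1))
        assert [m.atoms for m in r2.substrates] == \
            [m.atoms for m in r1.substrates]
        assert [bond_multiset(m) for m in r2.products] == \
            [bond_multiset(m) for m in r1.products]
        assert r2.atom_map == r1.atom_map
        r3 = at.read_rxn(at.write_rxn(r2))
        assert r3.atom_map == r2.atom_map


class TestRdkitOracle:
    """Independent parser agreement on every written fixture file."""

    @pytest.mark.parametrize("name", fx.MOLECULE_NAMES)
    def test_atom_and_bond_counts(self, name):
        m = fx.molecule(name)
        rd = Chem.MolFromMolBlock(at.write_mol(m), sanitize=False)
        assert rd is not None
        assert rd.GetNumAtoms() == m.n_atoms
        assert rd.GetNumBonds() == m.n_bonds

    def test_rxn_map_numbers_balanced(self):
        from rdkit.Chem import AllChem
        rxn = AllChem.ReactionFromRxnBlock(at.write_rxn(fx.reaction("GLS")))
        assert rxn.GetNumReactantTemplates() == 2
        assert rxn.GetNumProductTemplates() == 2
        sub_nums = {a.GetAtomMapNum()
                    for i in range(rxn.GetNumReactantTemplates())
                    for a in rxn.GetReactantTemplate(i).GetAtoms()
                    if a.GetAtomMapNum()}
        prod_nums = {a.GetAtomMapNum()
                     for i in range(rxn.GetNumProductTemplates())
                     for a in rxn.GetProductTemplate(i).GetAtoms()
                     if a.GetAtomMapNum()}
        assert sub_nums == prod_nums
        assert len(sub_nums) == 5
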