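"""ABC model assembly: lettering, omission, custom mappings, symmetry."""

import pytest

import atomtrail as at
from atomtrail import fixtures as fx
from atomtrail.abc_builder import apply_symmetry, merge_custom_mapping
from atomtrail.errors import BuildError
from atomtrail.model_format import ABCEntry, ABCSpecies


def build(csv_text, store, **kwargs):
    return at.build_abc_model(at.parse_model_csv(csv_text), store, **kwargs)


def assert_letters_conserved(entry):
    subs = entry.side_letters("substrates")
    prods = entry.side_letters("products")
    assert sorted(subs) == sorted(set(subs))
    assert sorted(prods) == sorted(set(prods))
    assert set(subs) == set(prods)


class TestBuild:
    def test_glutaminase_identity_entry(self, store):
        abc = build(fx.GLUTAMINE_GABA_STORE_CSV, store)
        assert abc.entries_for("GLS")[0].equation() == \
            "glutamine (abcde) -> glutamate (abcde)"

    def test_transport_identity_letters(self, store):
        abc = build("T [MetaCyc:TRANS-RXN-PYR],pyruvate,reversible,pyruvate\n",
                    store)
        assert abc.entries[0].equation() == "pyruvate (abc) <-> pyruvate (abc)"

    def test_decarboxylation_drops_the_carboxyl_letter_in_order(self, store):
        abc = build(fx.GLUTAMINE_GABA_STORE_CSV, store)
        gad = abc.entries_for("GAD")[0]
        assert gad.equation() == "glutamate (abcde) -> GABA (bcde) + CO2 (a)"

    def test_letter_conservation_on_every_balanced_entry(self, store):
        for csv_text in fx._MODEL_FILES.values():
            for entry in build(csv_text, store).entries:
                assert_letters_conserved(entry)

    def test_deterministic_byte_identical_output(self, store):
        a = at.write_abc(build(fx.TOY_GLYCOLYSIS_CSV, store))
        b = at.write_abc(build(fx.TOY_GLYCOLYSIS_CSV, store))
        assert a == b

    def test_acetyl_moiety_conserves_three_letters(self, glycolysis_abc):
        pdh = glycolysis_abc.entries_for("PDH")[0]
        assert pdh.equation() == "pyruvate (abc) -> acetyl-CoA (bc) + CO2 (a)"
        assert_letters_conserved(pdh)

    def test_carbon_limit_annotation_mismatch_is_error(self, store):
        text = ("PDH [KEGG:R00209],pyruvate,irreversible,"
                "acetyl-CoA {C:3} + CO2\n")
        with pytest.raises(BuildError, match="declared with 3"):
            build(text, store)

    def test_coefficient_two_expands_instances(self, store):
        abc = build(fx.THIOLASE_CSV, store)
        thl = abc.entries[0]
        assert [s.letters for s in thl.substrates] == ["ab", "cd"]
        assert_letters_conserved(thl)

    def test_unresolved_identifier_names_reaction(self, store):
        with pytest.raises(BuildError, match="R99999"):
            build("X [KEGG:R99999],glucose,irreversible,G6P\n", store)

    def test_reaction_without_id_or_letters_rejected(self, store):
        with pytest.raises(BuildError, match="cannot resolve"):
            build("X,glucose,irreversible,G6P\n", store)

    def test_model_metabolite_absent_from_stored_reaction(self, store):
        text = "GLS [MetaCyc:GLUTAMIN-RXN],glutamine + pyruvate,ir,glutamate\n"
        with pytest.raises(BuildError, match="pyruvate"):
            build(text, store)

    def test_carbon_bearing_leftover_requires_explicit_omission(self, store):
        # PDH without CO2 in the model row
        text = "PDH [KEGG:R00209],pyruvate,irreversible,acetyl-CoA\n"
        with pytest.raises(BuildError, match="CO2"):
            build(text, store)
        abc = build(text, store, omit=("CO2",))
        assert abc.entries[0].equation() == "pyruvate (abc) -> acetyl-CoA (bc)"

    def test_zero_carbon_participants_auto_omitted(self, store):
        # stored glutaminase consumes water and releases ammonia
        abc = build(fx.GLUTAMINE_GABA_STORE_CSV, store)
        names = [s.name for s in abc.entries_for("GLS")[0].substrates]
        assert names == ["glutamine"]


class TestOmission:
    def test_hexokinase_with_cofactors_then_omitted(self, store):
        full = build(fx.HEXOKINASE_FULL_CSV, store).entries[0]
        assert full.substrates[1].name == "ATP"
        assert len(full.side_letters("substrates")) == 16
        assert_letters_conserved(full)

        text = ("HK [MetaCyc:GLUCOKIN-RXN-FULL],glucose,irreversible,G6P\n")
        slim = build(text, store, omit=("ATP", "ADP")).entries[0]
        assert slim.equation() == "glucose (abcdef) -> G6P (abcdef)"

    def test_omitting_nothing_is_identity(self, store):
        r = store.reactions["GLS"]
        r2 = at.omit_metabolites(r, [])
        assert r2.atom_map == r.atom_map
        assert [m.name for m in r2.substrates] == \
            [m.name for m in r.substrates]

    def test_omitting_absent_metabolite_is_error(self, store):
        with pytest.raises(BuildError, match="absent"):
            at.omit_metabolites(store.reactions["GLS"], ["ATP"])

    def test_omitting_a_whole_side_is_error(self, store):
        with pytest.raises(BuildError, match="empty"):
            at.omit_metabolites(store.reactions["GLS"],
                                ["glutamine", "water"])


class TestCustomMappings:
    def test_consistent_manual_gaba_reaction_accepted(self, store):
        abc = build(fx.GLUTAMINE_GABA_CUSTOM_CSV, store)
        gad = abc.entries_for("GAD")[0]
        assert gad.provenance == "user"
        # identical strings to the store-derived route
        derived = build(fx.GLUTAMINE_GABA_STORE_CSV, store).entries_for("GAD")[0]
        assert gad.substrates == derived.substrates
        assert gad.products == derived.products

    def test_wrong_length_string_cites_expected_count(self, store):
        text = ("GAD [custom:X],glutamate (abcd),irreversible,"
                "GABA (bcd) + CO2 (a)\n")
        with pytest.raises(BuildError, match="5 carbons"):
            build(text, store)

    def test_novel_metabolites_accepted_at_their_word(self, store):
        text = "NOVEL [custom:N1],widgetol (ab),irreversible,gadgetate (ba)\n"
        entry = build(text, store).entries[0]
        assert entry.provenance == "user"
        assert entry.equation() == "widgetol (ab) -> gadgetate (ba)"

    def test_mismatched_letter_sets_rejected(self):
        rxn = at.parse_model_csv(
            "X [custom:C],A (ab),irreversible,B (ac)\n").reactions[0]
        with pytest.raises(BuildError, match="do not match"):
            merge_custom_mapping(rxn, {})


class TestSymmetry:
    def test_fumarate_expansion_gives_two_orbit_variants(self, store):
        abc = build(fx.FUMARASE_CSV, store, symmetry="expand")
        entries = abc.entries_for("FUM")
        assert len(entries) == 2
        assert entries[0].substrates[0].letters == "abcd"
        # the variant applies the carbon automorphism (1 2)(3 4)
        assert entries[1].substrates[0].letters == "badc"
        assert entries[0].products == entries[1].products

    def test_asymmetric_entries_unchanged_under_any_mode(self, store):
        for mode in ("ignore", "expand", "canonical"):
            abc = build(fx.GLUTAMINE_GABA_STORE_CSV, store, symmetry=mode)
            assert len(abc.entries_for("GAD")) == 1
            assert abc.entries_for("GAD")[0].equation() == \
                "glutamate (abcde) -> GABA (bcde) + CO2 (a)"

    def test_canonical_mode_single_minimal_entry(self, store):
        abc = build(fx.FUMARASE_CSV, store, symmetry="canonical")
        entries = abc.entries_for("FUM")
        assert len(entries) == 1
        assert entries[0].substrates[0].letters == "abcd"

    def test_apply_symmetry_rejects_unknown_mode(self):
        entry = ABCEntry("R", [ABCSpecies("A", "a")], [ABCSpecies("A", "a")])
        with pytest.raises(ValueError):
            apply_symmetry(entry, {}, "bogus")
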