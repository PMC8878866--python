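"""Label tracing, error injection, and model diffing."""

import pytest

import atomtrail as at
from atomtrail import fixtures as fx
from atomtrail.errors import TraceError
from atomtrail.tracer import LOST, LabelPosition, label, merged_view

# glucose C4-C6 enter glyceraldehyde 3-phosphate directly at the aldol
# split, so their path skips the triose-phosphate isomerase step
LOWER_PATH = [r for r in fx.GLYCOLYSIS_PATH if r != "TPI"]


def positions(state):
    return sorted((p.metabolite, p.tag, p.position) for p in state)


class TestTrace:
    def test_glucose_c1_reaches_pyruvate_methyl(self, glycolysis_abc):
        state = at.trace(glycolysis_abc, label("glucose", 1),
                         fx.GLYCOLYSIS_PATH)
        assert positions(state) == [("pyruvate", "1", 3)]

    def test_pyruvate_methyl_continues_to_acetyl_c2(self, glycolysis_abc):
        state = at.trace(glycolysis_abc, label("pyruvate", 3), ["PDH"])
        assert positions(state) == [("acetyl-CoA", "1", 2)]

    def test_identity_transport_leaves_label_unchanged(self, store):
        abc = at.build_abc_model(at.parse_model_csv(
            "T [MetaCyc:TRANS-RXN-PYR],pyruvate,reversible,pyruvate\n"), store)
        start = label("pyruvate", 2)
        assert at.trace(abc, start, ["T", "T", "T"]) == start

    def test_unconnected_step_is_error_naming_the_gap(self, glycolysis_abc):
        with pytest.raises(TraceError, match="PDH"):
            at.trace(glycolysis_abc, label("glucose", 1), ["PDH"])

    def test_unknown_reaction_is_error(self, glycolysis_abc):
        with pytest.raises(TraceError, match="NOPE"):
            at.trace(glycolysis_abc, label("glucose", 1), ["NOPE"])

    def test_position_outside_carbon_range_is_error(self, glycolysis_abc):
        with pytest.raises(TraceError, match="position 7"):
            at.trace(glycolysis_abc, label("glucose", 7), ["HK"])

    def test_reversible_round_trip_returns_start(self, glycolysis_abc):
        for start in (label("PG3", 1), label("PG3", 2), label("PG3", 3)):
            out = at.trace(glycolysis_abc, start, ["PGM", "PGM"])
            assert out == start

    def test_co2_released_early_rides_along(self, store):
        abc = at.build_abc_model(
            at.parse_model_csv(fx.GLUTAMINE_GABA_STORE_CSV), store)
        state = at.trace(abc, label("glutamine", 1), ["GLS", "GAD"])
        assert positions(state) == [("CO2", "1", 1)]

    def test_letter_leaving_retained_system_reports_lost(self, store):
        text = "PDH [KEGG:R00209],pyruvate,irreversible,acetyl-CoA\n"
        abc = at.build_abc_model(at.parse_model_csv(text), store,
                                 omit=("CO2",))
        state = at.trace(abc, label("pyruvate", 1), ["PDH"])
        assert positions(state) == [(LOST, "1", 0)]

    def test_symmetric_expansion_unions_both_fates(self, store):
        abc = at.build_abc_model(at.parse_model_csv(fx.FUMARASE_CSV), store,
                                 symmetry="expand")
        state = at.trace(abc, label("fumarate", 1), ["FUM"])
        assert merged_view(state) == {"malate": [1, 2]}

    def test_exhaustive_glucose_fates_are_bijective(self, glycolysis_abc):
        """All six glucose carbons partition into six distinct fates."""
        for model in (glycolysis_abc,
                      at.inject_error(glycolysis_abc, "ALDO",
                                      fx.ALDOLASE_ERROR_SWAP)):
            fates = set()
            for carbon in (1, 2, 3):
                fates |= at.trace(model, label("glucose", carbon, tag="1"),
                                  fx.GLYCOLYSIS_PATH)
            for carbon in (4, 5, 6):
                fates |= at.trace(model, label("glucose", carbon, tag="2"),
                                  LOWER_PATH)
            assert len(fates) == 6
            assert {p.metabolite for p in fates} == {"pyruvate"}
            for tag in ("1", "2"):
                assert sorted(p.position for p in fates if p.tag == tag) == \
                    [1, 2, 3]


class TestInjectError:
    def test_documented_aldolase_error_reroutes_c1(self, glycolysis_abc):
        bad = at.inject_error(glycolysis_abc, "ALDO", fx.ALDOLASE_ERROR_SWAP)
        state = at.trace(bad, label("glucose", 1), fx.GLYCOLYSIS_PATH)
        assert positions(state) == [("pyruvate", "1", 1)]

    def test_error_then_pdh_sends_label_into_co2(self, glycolysis_abc):
        bad = at.inject_error(glycolysis_abc, "ALDO", fx.ALDOLASE_ERROR_SWAP)
        state = at.trace(bad, label("glucose", 1), fx.PDH_PATH)
        assert positions(state) == [("CO2", "1", 1)]

    def test_injected_model_remains_well_formed(self, glycolysis_abc):
        bad = at.inject_error(glycolysis_abc, "ALDO", fx.ALDOLASE_ERROR_SWAP)
        bad.check()
        for entry in bad.entries:
            assert set(entry.side_letters("substrates")) == \
                set(entry.side_letters("products"))

    def test_self_swap_changes_nothing(self, glycolysis_abc):
        same = at.inject_error(glycolysis_abc, "ALDO", ("b", "b"))
        assert at.diff_models(glycolysis_abc, same) == []

    def test_absent_letter_is_error(self, glycolysis_abc):
        with pytest.raises(TraceError, match="'z'"):
            at.inject_error(glycolysis_abc, "ALDO", ("b", "z"))

    def test_unknown_reaction_is_error(self, glycolysis_abc):
        with pytest.raises(TraceError):
            at.inject_error(glycolysis_abc, "NOPE", ("a", "b"))


class TestDiffModels:
    def test_self_diff_empty(self, glycolysis_abc):
        assert at.diff_models(glycolysis_abc, glycolysis_abc) == []

    def test_injection_touches_exactly_one_reaction(self, glycolysis_abc):
        bad = at.inject_error(glycolysis_abc, "ALDO", fx.ALDOLASE_ERROR_SWAP)
        diffs = at.diff_models(glycolysis_abc, bad)
        assert diffs
        assert {d.reaction for d in diffs} == {"ALDO"}
        assert all(d.metabolite == "DHAP" for d in diffs)

    def test_mismatched_reaction_sets_rejected(self, glycolysis_abc, store):
        other = at.build_abc_model(at.parse_model_csv(fx.FUMARASE_CSV), store)
        with pytest.raises(ValueError, match="different reactions"):
            at.diff_models(glycolysis_abc, other)

    def test_expand_vs_ignore_differs_only_in_symmetric_entries(self, store):
        model = at.parse_model_csv(fx.FUMARASE_CSV)
        plain = at.build_abc_model(model, store)
        expanded = at.build_abc_model(model, store, symmetry="expand")
        diffs = at.diff_models(plain, expanded)
        assert diffs
        assert {d.reaction for d in diffs} == {"FUM"}


class TestViews:
    def test_merged_view_pools_instance_tags(self):
        state = frozenset({LabelPosition("pyruvate", "1", 3),
                           LabelPosition("pyruvate", "2", 1),
                           LabelPosition("CO2", "1", 1)})
        assert merged_view(state) == {"CO2": [1], "pyruvate": [1, 3]}
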