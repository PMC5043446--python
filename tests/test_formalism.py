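"""Parsing, validation and serialization of the knowledge representation."""

import pytest

from procdesign.formalism import (
    DslError,
    parse_incomplete_model,
    parse_library,
    serialize_incomplete_model,
    serialize_library,
    validate_library,
)

MINIMAL = """
library tiny

entity protein {
  var mol
}
"""

BINDING = """
library binding_demo

entity protein {
  var mol
}

process binding(p1: protein, p2: protein, pc: protein) {
  const k_b in [0, 10]
}

process irreversible : binding {
  reaction p1 + p2 -> pc [k_b]
}

process reversible : binding {
  const k_u in [0, 10]
  reaction p1 + p2 <-> pc [k_b, k_u]
}
"""


class TestParseLibrary:
    def test_toggle_fixture_has_five_template_entities(self, toggle_lib):
        assert len(toggle_lib.entities) == 5
        assert set(toggle_lib.entities) == {
            "gene", "protein", "bound_factor", "inducer", "complex",
        }

    def test_minimal_document_one_entity_zero_processes(self):
        lib = parse_library(MINIMAL)
        assert list(lib.entities) == ["protein"]
        assert lib.processes == {}

    def test_undeclared_parent_is_an_error(self):
        text = MINIMAL + "\nprocess orphan(p: protein) : ghost {\n}\n"
        with pytest.raises(DslError, match="ghost"):
            parse_library(text)

    def test_duplicate_entity_name_rejected_with_line(self):
        text = MINIMAL + "\nentity protein {\n  var mol\n}\n"
        with pytest.raises(DslError, match="line"):
            parse_library(text)

    def test_syntax_error_reports_line(self):
        with pytest.raises(DslError, match="line 5"):
            parse_library("library x\n\nentity a {\n  var mol\n  wat?\n}\n")

    def test_reversible_sugar_expands_to_two_reactions(self):
        lib = parse_library(BINDING)
        assert len(lib.processes["reversible"].reactions) == 2
        fwd, bwd = lib.processes["reversible"].reactions
        assert fwd.reactants == bwd.products
        assert fwd.products == bwd.reactants

    def test_optional_sugar_creates_absent_present_pair(self, toggle_lib):
        assert toggle_lib.processes["dimerization"].modifier == "optional"
        kids = {p.name for p in toggle_lib.children("dimerization")}
        assert kids == {"dimerization.absent", "dimerization.present"}
        assert toggle_lib.processes["dimerization.absent"].reactions == []
        assert len(toggle_lib.processes["dimerization.present"].reactions) == 2


class TestConstantInheritance:
    def test_leaf_exposes_union_of_own_and_ancestor_constants(self):
        lib = parse_library(BINDING)
        irr = {c.name for c in lib.all_constants("irreversible")}
        rev = {c.name for c in lib.all_constants("reversible")}
        assert irr == {"k_b"}
        assert rev == {"k_b", "k_u"}

    def test_children_inherit_parent_slots(self):
        lib = parse_library(BINDING)
        assert lib.all_slots("irreversible") == lib.all_slots("binding")

    def test_every_rate_symbol_housed_in_one_declaration(self, toggle_lib):
        for proc in toggle_lib.processes.values():
            slots = dict(toggle_lib.all_slots(proc.name))
            for rx in proc.reactions:
                for sym in rx.rate.symbols():
                    if "." in sym:
                        slot, cname = sym.split(".", 1)
                        ent = toggle_lib.entities[slots[slot]]
                        assert ent.const(cname) is not None
                    else:
                        decls = [
                            c for c in toggle_lib.all_constants(proc.name)
                            if c.name == sym
                        ]
                        assert len(decls) == 1


class TestValidateLibrary:
    def test_fixture_libraries_validate_clean(self, toggle_lib, osc_lib):
        assert validate_library(toggle_lib) == []
        assert validate_library(osc_lib) == []

    def test_undeclared_rate_symbol_flagged(self):
        lib = parse_library(BINDING)
        # forge a reaction with an unknown symbol on a leaf
        from procdesign.formalism import RateLawTemplate, ReactionTemplate, SpeciesRef, Term

        bad = ReactionTemplate(
            (Term(SpeciesRef("p1")),), (), RateLawTemplate("mass-action", k="nope")
        )
        lib.processes["irreversible"].reactions.append(bad)
        findings = validate_library(lib)
        assert [k for k, _ in findings] == ["unresolved"]
        assert "nope" in findings[0][1]

    def test_parent_cycle_flagged(self):
        lib = parse_library(BINDING)
        lib.processes["binding"].parent = "reversible"
        assert any(k == "cycle" for k, _ in validate_library(lib))


class TestRoundTrip:
    def test_serialize_parse_identity_on_fixtures(self, toggle_lib, osc_lib):
        for lib in (toggle_lib, osc_lib):
            text = serialize_library(lib)
            again = serialize_library(parse_library(text))
            assert text == again

    def test_model_round_trip(self, toggle_lib, toggle_model):
        text = serialize_incomplete_model(toggle_model)
        again = parse_incomplete_model(text, toggle_lib)
        assert serialize_incomplete_model(again) == text


class TestParseIncompleteModel:
    def test_toggle_entity_instances(self, toggle_model):
        assert set(toggle_model.entities) == {
            "gA", "gB", "A", "B", "S", "R", "AgB", "BgA", "SA", "RB", "AB",
        }

    def test_type_mismatch_on_slot_binding(self, toggle_lib):
        text = (
            "model bad\n"
            "entity S : inducer { mol = 0 }\n"
            "entity A : protein { mol = 0 }\n"
            "entity gB : gene { mol = 1 }\n"
            "entity AgB : bound_factor { mol = 0 }\n"
            # inducer bound where a protein slot is expected
            "process b : binding_a(S, gB, AgB)\n"
        )
        with pytest.raises(DslError, match="type|protein"):
            parse_incomplete_model(text, toggle_lib)

    def test_unknown_template_reference(self, toggle_lib):
        with pytest.raises(DslError, match="unknown template"):
            parse_incomplete_model("model bad\nentity X : nonsense\n", toggle_lib)

    def test_oscillator_instances_preserve_inner_node(self, osc_model, osc_lib):
        proteins = [e for e in osc_model.entities.values() if e.template == "protein"]
        assert len(proteins) == 3
        inhibitions = [p for p in osc_model.processes if p.template == "inhibits"]
        assert len(inhibitions) == 3
        unresolved = [
            p for p in osc_model.processes if not osc_lib.is_leaf(p.template)
        ]
        assert [p.template for p in unresolved] == ["auto_interaction"]
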