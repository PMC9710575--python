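"""SBML parsing, feature gating, function inlining and local-parameter lifting."""

import pytest
import sympy as sp
from lxml import etree

from odelift.fixtures import FixtureSpec, generate
from odelift.sbml_ingest import (
    ArityMismatchError,
    DefinitionCycleError,
    SBMLFormatError,
    SBMLParseError,
    UnsupportedLevelError,
    check_supported,
    inline_all,
    inline_function_definitions,
    lift_local_parameters,
    parse_sbml,
)

from .conftest import math, sbml_doc


class TestParse:
    def test_minimal_document(self, ab_document):
        model = parse_sbml(ab_document)
        assert len(model.species) == 2
        assert len(model.reactions) == 1
        k1, A = sp.Symbol("k1"), sp.Symbol("A")
        assert model.reactions[0].kinetic_law == k1 * A
        assert model.species[0].initial_concentration == "2"

    def test_event_detection(self):
        doc = sbml_doc("<listOfEvents><event id='e1'/></listOfEvents>")
        assert parse_sbml(doc).events_present

    def test_generator_round_trip(self):
        """Parsing a generated document recovers exactly the generated ids."""
        sbml, manifest = generate(FixtureSpec(n_species=5, n_reactions=4, seed=7))
        model = parse_sbml(sbml)
        assert [s.id for s in model.species] == manifest.species_ids
        assert sorted(p.id for p in model.global_parameters) == sorted(
            manifest.parameter_values
        )
        assert [r.id for r in model.reactions] == [r["id"] for r in manifest.reactions]

    def test_entity_conservation_against_raw_xml_count(self):
        """Parse never drops an entity present in the document."""
        sbml, _ = generate(FixtureSpec(n_species=6, n_reactions=5, seed=3,
                                       include_rules=True))
        model = parse_sbml(sbml)
        root = etree.fromstring(sbml.encode())
        def count(tag):
            return len(root.findall(f".//{{*}}{tag}"))
        assert len(model.species) == count("species")
        assert len(model.reactions) == count("reaction")
        assert len(model.global_parameters) == count("parameter")

    def test_malformed_xml(self):
        with pytest.raises(SBMLParseError):
            parse_sbml("<sbml level='3'")

    def test_non_sbml_root(self):
        with pytest.raises(SBMLFormatError):
            parse_sbml("<notes><p>hi</p></notes>")

    def test_level_one_rejected(self):
        doc = "<sbml xmlns='http://www.sbml.org/sbml/level1' level='1' version='2'><model/></sbml>"
        with pytest.raises(UnsupportedLevelError):
            parse_sbml(doc)

    def test_duplicate_ids_rejected(self):
        body = """
        <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
        <listOfSpecies>
          <species id="A" compartment="c" constant="false" boundaryCondition="false" hasOnlySubstanceUnits="false"/>
        </listOfSpecies>
        <listOfParameters><parameter id="A" value="1" constant="true"/></listOfParameters>
        """
        with pytest.raises(SBMLParseError):
            parse_sbml(sbml_doc(body))

    def test_cn_variants_parse_exactly(self):
        body = f"""
        <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
        <listOfParameters><parameter id="p" value="1" constant="true"/></listOfParameters>
        <listOfInitialAssignments>
          <initialAssignment symbol="p">{math('<apply><plus/>'
              '<cn type="e-notation">15<sep/>-2</cn>'
              '<cn type="rational">1<sep/>4</cn></apply>')}</initialAssignment>
        </listOfInitialAssignments>
        """
        model = parse_sbml(sbml_doc(body))
        assert model.initial_assignments["p"] == sp.Rational(2, 5)


class TestGating:
    def test_parameter_rate_rule_rejected(self):
        body = f"""
        <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
        <listOfParameters><parameter id="k" value="1" constant="false"/></listOfParameters>
        <listOfRules><rateRule variable="k">{math('<cn type="integer">1</cn>')}</rateRule></listOfRules>
        """
        report = check_supported(parse_sbml(sbml_doc(body)))
        assert not report.supported
        assert any(f == "parameter rate rule" for f, _, _ in report.violations)

    def test_irrational_initial_assignment_rejected(self):
        body = f"""
        <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
        <listOfParameters><parameter id="k" value="1" constant="true"/></listOfParameters>
        <listOfInitialAssignments>
          <initialAssignment symbol="k">{math('<apply><exp/><cn type="integer">1</cn></apply>')}</initialAssignment>
        </listOfInitialAssignments>
        """
        report = check_supported(parse_sbml(sbml_doc(body)))
        assert not report.supported
        assert [f for f, _, _ in report.violations] == ["irrational parameter value"]

    def test_plain_mass_action_model_supported(self, ab_document):
        report = check_supported(parse_sbml(ab_document))
        assert report.supported
        assert report.violations == ()

    def test_algebraic_rule_rejected(self):
        body = f"""
        <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
        <listOfRules><algebraicRule>{math('<cn type="integer">0</cn>')}</algebraicRule></listOfRules>
        """
        report = check_supported(parse_sbml(sbml_doc(body)))
        assert any(f == "algebraic rule" for f, _, _ in report.violations)

    def test_nonconstant_compartment_rejected(self):
        body = '<listOfCompartments><compartment id="c" size="1" constant="false"/></listOfCompartments>'
        report = check_supported(parse_sbml(sbml_doc(body)))
        assert any(f == "non-constant compartment" for f, _, _ in report.violations)

    def test_nan_literal_rejected(self):
        body = """
        <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
        <listOfParameters><parameter id="k" value="NaN" constant="true"/></listOfParameters>
        """
        report = check_supported(parse_sbml(sbml_doc(body)))
        assert any(f == "non-finite value" for f, _, _ in report.violations)

    def test_gated_models_run_the_full_pipeline(self):
        """Gating soundness: a supported verdict means conversion succeeds."""
        from odelift.pipeline import convert

        for seed in range(5):
            sbml, _ = generate(
                FixtureSpec(n_species=4, n_reactions=3, kinetics="mixed", seed=seed,
                            include_boundary=seed % 2 == 0, include_rules=seed % 2 == 1)
            )
            assert check_supported(parse_sbml(sbml)).supported
            convert(sbml)  # must not raise


class TestInlineFunctions:
    f, g = sp.Function("f"), sp.Function("g")
    a, b, k1, x1 = sp.symbols("a b k1 x1")

    def test_single_substitution(self):
        defs = {"f": (("a", "b"), self.a * self.b)}
        assert inline_function_definitions(self.f(self.k1, self.x1), defs) == self.k1 * self.x1

    def test_nested_expansion(self):
        defs = {"f": (("a",), self.g(self.a) + 1), "g": (("a",), 2 * self.a)}
        assert inline_function_definitions(self.f(self.x1), defs) == 2 * self.x1 + 1

    def test_self_recursion_raises(self):
        defs = {"f": (("a",), self.f(self.a) + 1)}
        with pytest.raises(DefinitionCycleError):
            inline_function_definitions(self.f(self.x1), defs)

    def test_arity_mismatch_raises(self):
        defs = {"f": (("a", "b"), self.a + self.b)}
        with pytest.raises(ArityMismatchError):
            inline_function_definitions(self.f(self.x1), defs)

    def test_inline_all_through_sbml(self):
        body = f"""
        <listOfFunctionDefinitions>
          <functionDefinition id="hill">
            {math('<lambda><bvar><ci>s</ci></bvar><bvar><ci>K</ci></bvar>'
                  '<apply><divide/><ci>s</ci><apply><plus/><ci>K</ci><ci>s</ci></apply></apply></lambda>')}
          </functionDefinition>
        </listOfFunctionDefinitions>
        <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
        <listOfSpecies>
          <species id="A" compartment="c" initialConcentration="1" boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
        </listOfSpecies>
        <listOfParameters><parameter id="Km" value="2" constant="true"/></listOfParameters>
        <listOfReactions>
          <reaction id="R1" reversible="false">
            <listOfReactants><speciesReference species="A" stoichiometry="1" constant="true"/></listOfReactants>
            <kineticLaw>{math('<apply><ci>hill</ci><ci>A</ci><ci>Km</ci></apply>')}</kineticLaw>
          </reaction>
        </listOfReactions>
        """
        model = inline_all(parse_sbml(sbml_doc(body)))
        A, Km = sp.symbols("A Km")
        assert model.reactions[0].kinetic_law == A / (Km + A)


class TestLiftLocals:
    def _doc(self, shadow_global: bool):
        param = '<listOfParameters><parameter id="k" value="7" constant="true"/></listOfParameters>' if shadow_global else ""
        body = f"""
        <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
        <listOfSpecies>
          <species id="A" compartment="c" initialConcentration="1" boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
          <species id="B" compartment="c" initialConcentration="1" boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
        </listOfSpecies>
        {param}
        <listOfReactions>
          <reaction id="R1" reversible="false">
            <listOfReactants><speciesReference species="A" stoichiometry="1" constant="true"/></listOfReactants>
            <kineticLaw>{math('<apply><times/><ci>k</ci><ci>A</ci></apply>')}
              <listOfLocalParameters><localParameter id="k" value="0.5"/></listOfLocalParameters>
            </kineticLaw>
          </reaction>
          <reaction id="R2" reversible="false">
            <listOfReactants><speciesReference species="B" stoichiometry="1" constant="true"/></listOfReactants>
            <kineticLaw>{math('<apply><times/><ci>k</ci><ci>B</ci></apply>')}
              <listOfLocalParameters><localParameter id="k" value="0.25"/></listOfLocalParameters>
            </kineticLaw>
          </reaction>
        </listOfReactions>
        """
        return sbml_doc(body)

    def test_distinct_fresh_ids_per_reaction(self):
        model = lift_local_parameters(parse_sbml(self._doc(False)))
        lifted = [p for p in model.global_parameters if p.origin is not None]
        assert len(lifted) == 2
        assert len({p.id for p in lifted}) == 2
        assert model.reactions[0].kinetic_law.free_symbols == {
            sp.Symbol(lifted[0].id), sp.Symbol("A")
        }

    def test_local_shadows_global(self):
        model = lift_local_parameters(parse_sbml(self._doc(True)))
        lifted_ids = {p.id for p in model.global_parameters if p.origin is not None}
        law_syms = {str(s) for s in model.reactions[0].kinetic_law.free_symbols}
        assert "k" not in law_syms
        assert law_syms & lifted_ids

    def test_idempotence(self):
        once = lift_local_parameters(parse_sbml(self._doc(True)))
        assert lift_local_parameters(once) == once

    def test_no_locals_is_identity(self, ab_document):
        model = parse_sbml(ab_document)
        assert lift_local_parameters(model) == model
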