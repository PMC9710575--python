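"""Canonical naming, value resolution and ODE right-hand-side assembly."""

from fractions import Fraction

import pytest
import sympy as sp

from odelift.fixtures import FixtureSpec, generate
from odelift.network_model import build_network
from odelift.ode_assembly import (
    TIME_SYMBOL,
    assemble_odes,
    build_name_map,
    resolve_values,
    species_assignment_constraints,
)
from odelift.pipeline import convert
from odelift.sbml_ingest import inline_all, lift_local_parameters, parse_sbml

from .conftest import math, sbml_doc

x1, x2, x3, k1, k2, k3 = sp.symbols("x1 x2 x3 k1 k2 k3")


def _prepare(doc):
    model = lift_local_parameters(inline_all(parse_sbml(doc)))
    net = build_network(model)
    return model, net, build_name_map(net)


class TestNameMap:
    def test_species_follow_document_order(self, ab_document):
        _, _, nm = _prepare(ab_document)
        assert nm.species_map == {"A": "x1", "B": "x2"}

    def test_parameter_ordering_globals_compartments_locals(self):
        body = f"""
        <listOfCompartments><compartment id="cell" size="1" constant="true"/></listOfCompartments>
        <listOfSpecies>
          <species id="A" compartment="cell" initialConcentration="1" boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
        </listOfSpecies>
        <listOfParameters><parameter id="k" value="1" constant="true"/></listOfParameters>
        <listOfReactions>
          <reaction id="R1" reversible="false">
            <listOfReactants><speciesReference species="A" stoichiometry="1" constant="true"/></listOfReactants>
            <kineticLaw>{math('<apply><times/><ci>kf</ci><ci>A</ci></apply>')}
              <listOfLocalParameters><localParameter id="kf" value="2"/></listOfLocalParameters>
            </kineticLaw>
          </reaction>
        </listOfReactions>
        """
        _, _, nm = _prepare(sbml_doc(body))
        assert nm.parameter_map == {"k": "k1", "cell": "k2", "R1_kf": "k3"}

    def test_bijection_round_trip(self, ab_document):
        _, _, nm = _prepare(ab_document)
        assert nm.to_math(nm.to_sbml("x2")) == "x2"
        assert nm.to_sbml(nm.to_math("A")) == "A"


class TestAssemble:
    def test_textbook_mass_action(self, ab_document):
        model, net, nm = _prepare(ab_document)
        ode = assemble_odes(net, model, nm)
        assert ode.variables == [x1, x2]
        assert ode.equations[0] == -k1 * x1
        assert ode.equations[1] == k1 * x1
        assert ode.is_autonomous

    def test_boundary_species_is_pinned(self):
        doc = sbml_doc(
            """
        <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
        <listOfSpecies>
          <species id="A" compartment="c" initialConcentration="1" boundaryCondition="true" constant="false" hasOnlySubstanceUnits="false"/>
          <species id="B" compartment="c" initialConcentration="0" boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
        </listOfSpecies>
        <listOfParameters><parameter id="k1" value="1" constant="true"/></listOfParameters>
        <listOfReactions>
          <reaction id="R1" reversible="false">
            <listOfReactants><speciesReference species="A" stoichiometry="1" constant="true"/></listOfReactants>
            <listOfProducts><speciesReference species="B" stoichiometry="1" constant="true"/></listOfProducts>
            <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML"><apply><times/><ci>k1</ci><ci>A</ci></apply></math></kineticLaw>
          </reaction>
        </listOfReactions>
        """
        )
        model, net, nm = _prepare(doc)
        ode = assemble_odes(net, model, nm)
        assert ode.equations[0] == 0
        assert ode.equations[1] == k1 * x1

    def test_rate_rule_with_time_makes_system_nonautonomous(self):
        doc = sbml_doc(
            f"""
        <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
        <listOfSpecies>
          <species id="C" compartment="c" initialConcentration="0" boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
        </listOfSpecies>
        <listOfParameters><parameter id="k2" value="3" constant="true"/></listOfParameters>
        <listOfRules>
          <rateRule variable="C">{math('<apply><times/><ci>k2</ci>'
              '<csymbol encoding="text" definitionURL="http://www.sbml.org/sbml/symbols/time">t</csymbol></apply>')}</rateRule>
        </listOfRules>
        """
        )
        model, net, nm = _prepare(doc)
        ode = assemble_odes(net, model, nm)
        assert ode.equations[0] == k1 * TIME_SYMBOL  # k2 maps to k1 (only parameter)
        assert not ode.is_autonomous

    def test_compartment_division(self):
        doc = sbml_doc(
            """
        <listOfCompartments><compartment id="c" size="2" constant="true"/></listOfCompartments>
        <listOfSpecies>
          <species id="A" compartment="c" initialConcentration="1" boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
        </listOfSpecies>
        <listOfParameters><parameter id="k1" value="1" constant="true"/></listOfParameters>
        <listOfReactions>
          <reaction id="R1" reversible="false">
            <listOfReactants><speciesReference species="A" stoichiometry="1" constant="true"/></listOfReactants>
            <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML"><apply><times/><ci>k1</ci><ci>A</ci></apply></math></kineticLaw>
          </reaction>
        </listOfReactions>
        """
        )
        model, net, nm = _prepare(doc)
        assert assemble_odes(net, model, nm).equations[0] == -k1 * x1 / 2
        undivided = assemble_odes(net, model, nm, compartment_division=False)
        assert undivided.equations[0] == -k1 * x1


class TestResolveValues:
    def test_initial_assignment_wins_over_declared(self):
        doc = sbml_doc(
            f"""
        <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
        <listOfParameters><parameter id="k" value="2" constant="true"/></listOfParameters>
        <listOfInitialAssignments>
          <initialAssignment symbol="k">{math('<apply><divide/><cn type="integer">3</cn><cn type="integer">2</cn></apply>')}</initialAssignment>
        </listOfInitialAssignments>
        """
        )
        model, net, nm = _prepare(doc)
        params, _ = resolve_values(model, nm)
        assert params[sp.Symbol(nm.parameter_map["k"])] == Fraction(3, 2)

    def test_amount_divided_by_compartment_size(self):
        doc = sbml_doc(
            """
        <listOfCompartments><compartment id="c" size="2" constant="true"/></listOfCompartments>
        <listOfSpecies>
          <species id="A" compartment="c" initialAmount="4" boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
        </listOfSpecies>
        """
        )
        model, net, nm = _prepare(doc)
        _, initials = resolve_values(model, nm)
        assert initials[x1] == Fraction(2)

    def test_dependency_ordered_evaluation(self):
        doc = sbml_doc(
            f"""
        <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
        <listOfParameters>
          <parameter id="k1" constant="true" value="1"/>
          <parameter id="k2" constant="true" value="1"/>
        </listOfParameters>
        <listOfInitialAssignments>
          <initialAssignment symbol="k1">{math('<apply><divide/><cn type="integer">1</cn><cn type="integer">3</cn></apply>')}</initialAssignment>
          <initialAssignment symbol="k2">{math('<apply><times/><cn type="integer">2</cn><ci>k1</ci></apply>')}</initialAssignment>
        </listOfInitialAssignments>
        """
        )
        model, net, nm = _prepare(doc)
        params, _ = resolve_values(model, nm)
        assert params[sp.Symbol(nm.parameter_map["k2"])] == Fraction(2, 3)


class TestAssignmentConstraints:
    DOC = sbml_doc(
        f"""
    <listOfCompartments><compartment id="c" size="1" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" initialConcentration="1" boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
      <species id="B" compartment="c" initialConcentration="1" boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
      <species id="C" compartment="c" boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
    </listOfSpecies>
    <listOfRules>
      <assignmentRule variable="C">{math('<apply><plus/><ci>A</ci><ci>B</ci></apply>')}</assignmentRule>
    </listOfRules>
    """
    )

    def test_rule_becomes_formal_constraint(self):
        model, net, nm = _prepare(self.DOC)
        constraints = species_assignment_constraints(model, nm)
        assert len(constraints) == 1
        assert constraints[0].left == x3
        assert constraints[0].right == x1 + x2

    def test_assignment_species_has_no_ode(self):
        model, net, nm = _prepare(self.DOC)
        ode = assemble_odes(net, model, nm)
        assert x3 not in ode.variables
        assert len(ode.variables) == 2

    def test_no_rules_gives_empty_list(self, ab_document):
        model, net, nm = _prepare(ab_document)
        assert species_assignment_constraints(model, nm) == []


class TestSystemInvariants:
    @pytest.mark.parametrize("seed", range(6))
    def test_symbol_closure_and_one_equation_per_species(self, seed):
        """Free symbols stay within {x, k, t}; each species has exactly one
        of an ODE or an assignment constraint."""
        sbml, manifest = generate(
            FixtureSpec(n_species=5, n_reactions=4, kinetics="mixed", seed=seed,
                        include_rules=True, include_boundary=seed % 2 == 0)
        )
        ds = convert(sbml)
        ode = ds.ode_system
        nm = ode.name_map
        allowed = set(nm.species_symbols()) | set(nm.parameter_symbols()) | {TIME_SYMBOL}
        for f in ode.equations:
            assert f.free_symbols <= allowed
        with_ode = {str(v) for v in ode.variables}
        with_rule = {
            str(c.left) for c in ode.constraints if c.kind == "species-assignment"
        }
        assert with_ode | with_rule == set(nm.species_map.values())
        assert not (with_ode & with_rule)
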