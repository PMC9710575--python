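"""Shared fixtures: toy networks and small hand-written SBML documents."""

from __future__ import annotations

import pytest

from odelift.fixtures import named_toys

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def sbml_doc(body: str, model_id: str = "m") -> str:
    """Wrap model body XML in an SBML Level 3 Version 2 skeleton."""
    return (
        f'<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<sbml xmlns="{SBML_NS}" level="3" version="2">\n'
        f'<model id="{model_id}">\n{body}\n</model>\n</sbml>\n'
    )


def math(expr_xml: str) -> str:
    return f'<math xmlns="{MATHML_NS}">{expr_xml}</math>'


#: one compartment of size 1, species A and B, reaction A -> B with law k1*A
AB_BODY = """
<listOfCompartments><compartment id="cell" size="1" constant="true"/></listOfCompartments>
<listOfSpecies>
  <species id="A" compartment="cell" initialConcentration="2" boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
  <species id="B" compartment="cell" initialConcentration="0.5" boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>
</listOfSpecies>
<listOfParameters><parameter id="k1" value="0.1" constant="true"/></listOfParameters>
<listOfReactions>
  <reaction id="R1" reversible="false">
    <listOfReactants><speciesReference species="A" stoichiometry="1" constant="true"/></listOfReactants>
    <listOfProducts><speciesReference species="B" stoichiometry="1" constant="true"/></listOfProducts>
    <kineticLaw><math xmlns="http://www.w3.org/1998/Math/MathML"><apply><times/><ci>k1</ci><ci>A</ci></apply></math></kineticLaw>
  </reaction>
</listOfReactions>
"""


@pytest.fixture(scope="session")
def ab_document() -> str:
    return sbml_doc(AB_BODY)


@pytest.fixture(scope="session")
def toys() -> dict:
    return named_toys()
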