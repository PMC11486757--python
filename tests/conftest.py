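"""Shared fixtures: toy networks, noise-free scenarios, an SBML text fixture."""

from __future__ import annotations

from dataclasses import replace

import pytest

from chemoflux.synthetic_data import ChemostatScenario, ToyModelSpec, load_preset, make_toy_model

TOY_SPECS = {
    "chain": ToyModelSpec(topology="chain"),
    "chain_detour": ToyModelSpec(topology="chain_detour"),
    "dual_substrate": ToyModelSpec(topology="dual_substrate", include_ngam=True),
    "branched_tca": ToyModelSpec(topology="branched_tca", include_ngam=True),
}


@pytest.fixture(params=sorted(TOY_SPECS), ids=sorted(TOY_SPECS))
def toy_case(request):
    """(name, model, known optimal solution) for every committed toy network."""
    name = request.param
    model, known = make_toy_model(TOY_SPECS[name])
    return name, model, known


@pytest.fixture()
def dual_substrate():
    model, known = make_toy_model(TOY_SPECS["dual_substrate"])
    return model, known


@pytest.fixture()
def low_noise_free() -> ChemostatScenario:
    return replace(load_preset("low"), noise_cv={})


@pytest.fixture()
def high_noise_free() -> ChemostatScenario:
    return replace(load_preset("high"), noise_cv={})


# Hand-written SBML L3 + fbc document: 5 species, 7 reactions, objective on
# BIOMASS.  Mirrors the dual-substrate toy without the maintenance reaction.
SBML_7RXN = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="toy7" fbc:strict="true">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="GLC" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="GLU" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="PREC" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="ATP" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="ACE" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb_uptake" value="-10" constant="true"/>
      <parameter id="zero" value="0" constant="true"/>
      <parameter id="ub_default" value="1000" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="EX_glc" reversible="true" fast="false" fbc:lowerFluxBound="lb_uptake" fbc:upperFluxBound="zero">
        <listOfReactants><speciesReference species="GLC" stoichiometry="1" constant="true"/></listOfReactants>
      </reaction>
      <reaction id="EX_glu" reversible="true" fast="false" fbc:lowerFluxBound="lb_uptake" fbc:upperFluxBound="zero">
        <listOfReactants><speciesReference species="GLU" stoichiometry="1" constant="true"/></listOfReactants>
      </reaction>
      <reaction id="CAT_GLC" reversible="false" fast="false" fbc:lowerFluxBound="zero" fbc:upperFluxBound="ub_default">
        <listOfReactants><speciesReference species="GLC" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts>
          <speciesReference species="PREC" stoichiometry="1" constant="true"/>
          <speciesReference species="ATP" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="CAT_GLU" reversible="false" fast="false" fbc:lowerFluxBound="zero" fbc:upperFluxBound="ub_default">
        <listOfReactants><speciesReference species="GLU" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts>
          <speciesReference species="PREC" stoichiometry="1" constant="true"/>
          <speciesReference species="ATP" stoichiometry="2" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="OVERFLOW" reversible="false" fast="false" fbc:lowerFluxBound="zero" fbc:upperFluxBound="ub_default">
        <listOfReactants><speciesReference species="PREC" stoichiometry="1" constant="true"/></listOfReactants>
        <listOfProducts><speciesReference species="ACE" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
      <reaction id="EX_ace" reversible="false" fast="false" fbc:lowerFluxBound="zero" fbc:upperFluxBound="ub_default">
        <listOfReactants><speciesReference species="ACE" stoichiometry="1" constant="true"/></listOfReactants>
      </reaction>
      <reaction id="BIOMASS" reversible="false" fast="false" fbc:lowerFluxBound="zero" fbc:upperFluxBound="ub_default">
        <listOfReactants>
          <speciesReference species="PREC" stoichiometry="1" constant="true"/>
          <speciesReference species="ATP" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="BIOMASS" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
  </model>
</sbml>
"""


@pytest.fixture()
def sbml_path(tmp_path):
    p = tmp_path / "toy7.xml"
    p.write_text(SBML_7RXN)
    return p
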