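"""Shared fixtures: hand-written SBML files and small network builders."""

from __future__ import annotations

import pytest

from gsmcompare.core import MetabolicNetwork, Metabolite, Reaction
from gsmcompare.gprs import parse_gpr
from gsmcompare.model_io import classify_network, split_compartment

# A hand-written SBML Level 3 + FBC v2 model: 4 metabolites (a_c, b_c,
# c_c, d_e), 3 reactions, 2 genes.  Counts are fixed by construction.
L3_FIXTURE = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="toy3" fbc:strict="true">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
      <compartment id="e" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="M_a_c" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
      <species id="M_b_c" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
      <species id="M_c_c" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
      <species id="M_d_e" compartment="e" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb" value="-1000" constant="true"/>
      <parameter id="zero" value="0" constant="true"/>
      <parameter id="ub" value="1000" constant="true"/>
    </listOfParameters>
    <fbc:listOfGeneProducts>
      <fbc:geneProduct fbc:id="G_g1" fbc:label="g1"/>
      <fbc:geneProduct fbc:id="G_g2" fbc:label="g2"/>
    </fbc:listOfGeneProducts>
    <listOfReactions>
      <reaction id="R_r1" reversible="false" fast="false"
                fbc:lowerFluxBound="zero" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="M_a_c" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_b_c" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:and>
            <fbc:geneProductRef fbc:geneProduct="G_g1"/>
            <fbc:geneProductRef fbc:geneProduct="G_g2"/>
          </fbc:and>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="R_r2" reversible="true" fast="false"
                fbc:lowerFluxBound="lb" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="M_b_c" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_c_c" stoichiometry="2" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:geneProductRef fbc:geneProduct="G_g1"/>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="R_EX_d_e" reversible="true" fast="false"
                fbc:lowerFluxBound="lb" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="M_d_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

# SBML Level 2: gene association in notes, bounds in kinetic-law parameters.
L2_FIXTURE = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="toy2">
    <listOfCompartments>
      <compartment id="c"/>
      <compartment id="b"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="M_x_c" compartment="c" boundaryCondition="false"/>
      <species id="M_y_c" compartment="c" boundaryCondition="false"/>
      <species id="M_x_b" compartment="b" boundaryCondition="true"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R_conv" reversible="false">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>GENE_ASSOCIATION: (g1 or g2)</p>
          </body>
        </notes>
        <listOfReactants>
          <speciesReference species="M_x_c" stoichiometry="1"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_y_c" stoichiometry="1"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <ci> FLUX_VALUE </ci>
          </math>
          <listOfParameters>
            <parameter id="LOWER_BOUND" value="0"/>
            <parameter id="UPPER_BOUND" value="999"/>
            <parameter id="FLUX_VALUE" value="0"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
      <reaction id="R_in" reversible="false">
        <listOfReactants>
          <speciesReference species="M_x_b" stoichiometry="1"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_x_c" stoichiometry="1"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

EMPTY_MODEL = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="void"/>
</sbml>
"""


@pytest.fixture
def l3_path(tmp_path):
    p = tmp_path / "toy3.xml"
    p.write_text(L3_FIXTURE)
    return p


@pytest.fixture
def l2_path(tmp_path):
    p = tmp_path / "toy2.xml"
    p.write_text(L2_FIXTURE)
    return p


@pytest.fixture
def empty_model_path(tmp_path):
    p = tmp_path / "void.xml"
    p.write_text(EMPTY_MODEL)
    return p


def build_network(
    reactions: dict[str, tuple[dict[str, float], float, float, str]],
    net_id: str = "test",
    objective: str | None = None,
) -> MetabolicNetwork:
    """Build a network from {rid: (stoichiometry, lb, ub, gpr_text)}."""
    net = MetabolicNetwork(id=net_id, objective_reaction=objective)
    for rid, (stoich, lb, ub, gpr) in reactions.items():
        for met in stoich:
            if met not in net.metabolites:
                core, comp = split_compartment(met)
                net.add_metabolite(
                    Metabolite(full_id=met, core_id=core, compartment=comp)
                )
        net.add_reaction(
            Reaction(
                id=rid,
                stoichiometry=dict(stoich),
                lower_bound=lb,
                upper_bound=ub,
                gene_rule=parse_gpr(gpr),
            )
        )
    classify_network(net)
    return net


def toy_chain(yield_coeff: float = 1.0) -> MetabolicNetwork:
    """Uptake-limited linear chain: EX_s (cap 10) -> s -> b -> biomass."""
    net = build_network(
        {
            "EX_s_e": ({"s_e": -1.0}, -10.0, 1000.0, ""),
            "T_s": ({"s_e": -1.0, "s_c": 1.0}, 0.0, 1000.0, "g1"),
            "CONV": ({"s_c": -yield_coeff, "b_c": 1.0}, 0.0, 1000.0, "g2"),
            "biomass": ({"b_c": -1.0}, 0.0, 1000.0, ""),
        },
        net_id="chain",
        objective="biomass",
    )
    return net
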