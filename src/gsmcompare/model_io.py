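"""Read, pre-process, classify and write metabolic networks (SBML).

Supports SBML Level 2 (gene associations in ``GENE_ASSOCIATION:`` notes,
bounds in kinetic-law parameters) and Level 3 with the FBC package
(gene-product association trees, bound parameters).  Pre-processing follows
the comparison methodology: boundary species are dropped, duplicate
reactions are merged with their gene rules OR-combined, and empty reactions
removed before equation-level comparison.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import libsbml

from .core import DEFAULT_BOUND, MetabolicNetwork, Metabolite, Reaction, ReactionClass
from .gprs import EMPTY_RULE, GeneRule, gene, or_, and_, parse_gpr

__all__ = [
    "SBMLParseError",
    "read_network",
    "write_network",
    "split_compartment",
    "classify_reaction",
    "classify_network",
    "deduplicate_reactions",
    "remove_empty_reactions",
    "preprocess",
]

# Compartment tokens recognised as identifier suffixes.  Covers the usual
# single-letter conventions ("_c", "_e", ...) and numbered dialect variants
# ("_c0") which normalise to their letter.
COMPARTMENT_TOKENS = frozenset(
    "c e p m x r v n g h l u i j w f s y b".split()
)
DEFAULT_COMPARTMENT = "c"

# Reactions whose id matches this are biomass/objective-type reactions and
# are excluded from reaction-coverage denominators.
BIOMASS_ID_PATTERN = re.compile(r"biomass", re.IGNORECASE)

_SUFFIX_RE = re.compile(r"^(.*)_([A-Za-z])(\d*)$")
_GA_NOTE_RE = re.compile(
    r"GENE[ _]?ASSOCIATION\s*:\s*([^<\n]*)", re.IGNORECASE
)


class SBMLParseError(ValueError):
    pass


def split_compartment(
    full_id: str,
    tokens: frozenset[str] = COMPARTMENT_TOKENS,
    default: str = DEFAULT_COMPARTMENT,
    log: list[str] | None = None,
) -> tuple[str, str]:
    """Split a metabolite identifier into (core_id, compartment token).

    The compartment is the substring after the final underscore when it is a
    known token, optionally followed by digits which are stripped during
    normalisation ("glc__D_c" -> ("glc__D", "c"); "cpd00002_c0" ->
    ("cpd00002", "c")).  Identifiers without a recognisable suffix keep their
    full id as core and get the default compartment, logged once.
    """
    m = _SUFFIX_RE.match(full_id)
    if m and m.group(2).lower() in tokens:
        return m.group(1), m.group(2).lower()
    if log is not None:
        log.append(
            f"no compartment suffix on '{full_id}'; "
            f"assigned default '{default}'"
        )
    return full_id, default


def _strip_sbml_prefix(sid: str) -> str:
    """Remove the conventional writer prefixes M_/R_/G_ from SBML ids."""
    if sid[:2] in ("M_", "R_", "G_"):
        return sid[2:]
    return sid


def _association_to_rule(assoc, fbc_model) -> GeneRule:
    """Convert a libsbml FBC association tree to a canonical GeneRule."""
    if assoc is None:
        return EMPTY_RULE
    if isinstance(assoc, libsbml.GeneProductRef):
        gp = fbc_model.getGeneProduct(assoc.getGeneProduct())
        if gp is not None and gp.isSetLabel() and gp.getLabel():
            return gene(gp.getLabel())
        return gene(_strip_sbml_prefix(assoc.getGeneProduct()))
    children = [
        _association_to_rule(assoc.getAssociation(i), fbc_model)
        for i in range(assoc.getNumAssociations())
    ]
    if isinstance(assoc, libsbml.FbcAnd):
        return and_(*children)
    if isinstance(assoc, libsbml.FbcOr):
        return or_(*children)
    return EMPTY_RULE


def _notes_gene_rule(sbml_rxn) -> GeneRule:
    if not sbml_rxn.isSetNotes():
        return EMPTY_RULE
    notes = sbml_rxn.getNotesString()
    m = _GA_NOTE_RE.search(notes)
    if not m:
        return EMPTY_RULE
    return parse_gpr(m.group(1).strip())


def _reaction_bounds(sbml_rxn, model, log: list[str]) -> tuple[float, float]:
    lb = ub = None
    fbc_rxn = sbml_rxn.getPlugin("fbc")
    if fbc_rxn is not None:
        if fbc_rxn.isSetLowerFluxBound():
            p = model.getParameter(fbc_rxn.getLowerFluxBound())
            if p is not None:
                lb = p.getValue()
        if fbc_rxn.isSetUpperFluxBound():
            p = model.getParameter(fbc_rxn.getUpperFluxBound())
            if p is not None:
                ub = p.getValue()
    if (lb is None or ub is None) and sbml_rxn.isSetKineticLaw():
        kl = sbml_rxn.getKineticLaw()
        for i in range(kl.getNumParameters()):
            p = kl.getParameter(i)
            if p.getId() == "LOWER_BOUND" and lb is None:
                lb = p.getValue()
            elif p.getId() == "UPPER_BOUND" and ub is None:
                ub = p.getValue()
    rev = sbml_rxn.getReversible()
    if lb is None:
        lb = -DEFAULT_BOUND if rev else 0.0
        log.append(
            f"reaction {sbml_rxn.getId()}: no lower bound; defaulted to {lb}"
        )
    if ub is None:
        ub = DEFAULT_BOUND
        log.append(
            f"reaction {sbml_rxn.getId()}: no upper bound; defaulted to {ub}"
        )
    return float(lb), float(ub)


def read_network(
    path: str | Path, log: list[str] | None = None
) -> MetabolicNetwork:
    """Read an SBML Level 2 or Level 3(+FBC) file into a MetabolicNetwork.

    Boundary-condition species (``boundaryCondition="true"`` or compartment
    token ``b``) are excluded from the metabolite set and silently dropped
    from reaction stoichiometries.  ``log``, when given, collects a line for
    every skipped or defaulted element.
    """
    log = log if log is not None else []
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SBMLParseError(
                f"{path}: line {err.getLine()}: {err.getMessage().strip()}"
            )
    model = doc.getModel()
    if model is None:
        raise SBMLParseError(f"{path}: no model element found")

    net = MetabolicNetwork(id=model.getId() or Path(str(path)).stem)
    fbc_model = model.getPlugin("fbc")

    boundary: set[str] = set()
    seen_nosuffix: set[str] = set()
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        full_id = _strip_sbml_prefix(sp.getId())
        sublog: list[str] = []
        core, comp = split_compartment(full_id, log=sublog)
        if sublog and full_id not in seen_nosuffix:
            seen_nosuffix.add(full_id)
            log.extend(sublog)
        comp_id = sp.getCompartment()
        if sp.getBoundaryCondition() or comp == "b" or comp_id == "b":
            boundary.add(sp.getId())
            log.append(f"species {sp.getId()}: boundary species excluded")
            continue
        charge = None
        formula = None
        sp_fbc = sp.getPlugin("fbc")
        if sp_fbc is not None:
            if sp_fbc.isSetCharge():
                charge = sp_fbc.getCharge()
            if sp_fbc.isSetChemicalFormula():
                formula = sp_fbc.getChemicalFormula()
        if charge is None and sp.isSetCharge():
            charge = sp.getCharge()
        net.add_metabolite(
            Metabolite(
                full_id=full_id,
                core_id=core,
                compartment=comp,
                name=sp.getName() or "",
                charge=charge,
                formula=formula,
            )
        )

    sbml_to_full = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        sbml_to_full[sp.getId()] = _strip_sbml_prefix(sp.getId())

    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        rid = _strip_sbml_prefix(rxn.getId())
        stoich: dict[str, float] = {}
        for n, getter, sign in (
            (rxn.getNumReactants(), rxn.getReactant, -1.0),
            (rxn.getNumProducts(), rxn.getProduct, 1.0),
        ):
            for j in range(n):
                ref = getter(j)
                sid = ref.getSpecies()
                if sid in boundary:
                    continue
                full = sbml_to_full[sid]
                coeff = ref.getStoichiometry()
                if coeff != coeff:  # NaN
                    coeff = 1.0
                    log.append(
                        f"reaction {rid}: missing stoichiometry for {sid}; "
                        "defaulted to 1"
                    )
                stoich[full] = stoich.get(full, 0.0) + sign * coeff
        stoich = {m: c for m, c in stoich.items() if c != 0.0}

        lb, ub = _reaction_bounds(rxn, model, log)
        rule = EMPTY_RULE
        fbc_rxn = rxn.getPlugin("fbc")
        if fbc_rxn is not None and fbc_rxn.isSetGeneProductAssociation():
            rule = _association_to_rule(
                fbc_rxn.getGeneProductAssociation().getAssociation(), fbc_model
            )
        if rule.is_empty():
            rule = _notes_gene_rule(rxn)
        net.reactions[rid] = Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=lb,
            upper_bound=ub,
            gene_rule=rule,
            name=rxn.getName() or "",
        )

    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            net.objective_reaction = _strip_sbml_prefix(
                obj.getFluxObjective(0).getReaction()
            )
    classify_network(net)
    net.validate()
    return net


def write_network(net: MetabolicNetwork, path: str | Path) -> None:
    """Write the network as SBML Level 3 Version 1 with FBC version 2."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(net.id)
    fbc_model = model.getPlugin("fbc")
    fbc_model.setStrict(True)

    compartments = sorted({m.compartment for m in net.metabolites.values()})
    for comp in compartments:
        c = model.createCompartment()
        c.setId(comp)
        c.setConstant(True)

    for full_id in sorted(net.metabolites):
        m = net.metabolites[full_id]
        sp = model.createSpecies()
        sp.setId("M_" + m.full_id)
        sp.setCompartment(m.compartment)
        sp.setName(m.name or m.core_id)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp_fbc = sp.getPlugin("fbc")
        if m.charge is not None:
            sp_fbc.setCharge(int(m.charge))
        if m.formula:
            sp_fbc.setChemicalFormula(m.formula)

    for g in sorted(net.genes):
        gp = fbc_model.createGeneProduct()
        gp.setId("G_" + re.sub(r"[^A-Za-z0-9_]", "_", g))
        gp.setLabel(g)

    bound_params: dict[float, str] = {}

    def bound_id(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for rid in sorted(net.reactions):
        r = net.reactions[rid]
        rxn = model.createReaction()
        rxn.setId("R_" + r.id)
        rxn.setName(r.name or r.id)
        rxn.setReversible(r.lower_bound < 0)
        rxn.setFast(False)
        for met, coeff in sorted(r.stoichiometry.items()):
            ref = (
                rxn.createReactant() if coeff < 0 else rxn.createProduct()
            )
            ref.setSpecies("M_" + met)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
        fbc_rxn = rxn.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(bound_id(r.lower_bound))
        fbc_rxn.setUpperFluxBound(bound_id(r.upper_bound))
        if not r.gene_rule.is_empty():
            gpa = fbc_rxn.createGeneProductAssociation()
            infix = re.sub(
                r"[^A-Za-z0-9_()\s]",
                "_",
                r.gene_rule.to_string(),
            )
            gpa.setAssociation(infix, True, False)

    if net.objective_reaction is not None:
        obj = fbc_model.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction("R_" + net.objective_reaction)
        fo.setCoefficient(1.0)
        fbc_model.setActiveObjectiveId("obj")

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise IOError(f"failed to write SBML to {path}")


def equation_key(r: Reaction, ndigits: int = 9) -> tuple:
    """Canonical, direction-sensitive key for a reaction equation."""
    return tuple(
        sorted((m, round(c, ndigits)) for m, c in r.stoichiometry.items())
    )


def classify_reaction(
    r: Reaction,
    net: MetabolicNetwork | None = None,
    biomass_pattern: re.Pattern = BIOMASS_ID_PATTERN,
) -> str:
    """Assign a reaction class.

    Precedence: exchange > demand > sink > biomass > transport > internal.
    Single-metabolite reactions are boundary reactions: exchange when
    reversible, demand when irreversibly consuming, sink when irreversibly
    producing.  Transport moves at least one identical core_id between
    different compartments.
    """
    if len(r.stoichiometry) == 1:
        (met, coeff), = r.stoichiometry.items()
        if r.reversible or r.id.startswith("EX_"):
            return ReactionClass.EXCHANGE
        # effective direction: forward-only consumes reactants, produces
        # products; reverse-only flips that
        forward = r.upper_bound > 0
        consuming = (coeff < 0) if forward else (coeff > 0)
        if consuming:
            return ReactionClass.DEMAND
        return ReactionClass.SINK
    if biomass_pattern.search(r.id):
        return ReactionClass.BIOMASS
    if net is not None:
        by_core: dict[str, set[tuple[str, float]]] = {}
        for met, coeff in r.stoichiometry.items():
            m = net.metabolites.get(met)
            if m is None:
                continue
            by_core.setdefault(m.core_id, set()).add((m.compartment, coeff))
        for entries in by_core.values():
            comps = {c for c, _ in entries}
            signs = {coeff > 0 for _, coeff in entries}
            if len(comps) > 1 and len(signs) > 1:
                return ReactionClass.TRANSPORT
    return ReactionClass.INTERNAL


def classify_network(net: MetabolicNetwork) -> None:
    for r in net.reactions.values():
        r.rclass = classify_reaction(r, net)


def deduplicate_reactions(
    net: MetabolicNetwork,
    mode: str = "by_equation",
    table=None,
) -> tuple[MetabolicNetwork, list[str]]:
    """Merge duplicate reactions, OR-combining their gene rules.

    ``by_equation`` groups reactions with identical stoichiometry maps;
    ``by_mapped_id`` groups reactions sharing a mapped (cross-namespace)
    identifier even when their equations differ, and requires ``table``.
    The lexicographically smallest reaction id survives; the merge log lists
    every removal.  Idempotent on duplicate-free input.
    """
    out = net.copy()
    log: list[str] = []
    groups: dict[tuple, list[str]] = {}
    if mode == "by_equation":
        for rid in sorted(out.reactions):
            r = out.reactions[rid]
            if not r.stoichiometry:
                continue  # empty reactions handled by remove_empty_reactions
            groups.setdefault(equation_key(r), []).append(rid)
    elif mode == "by_mapped_id":
        if table is None:
            raise ValueError("by_mapped_id deduplication requires a MappingTable")
        for rid in sorted(out.reactions):
            syns = table.reaction_synonyms(rid)
            key = tuple(sorted(syns)) if syns else ("##self##", rid)
            groups.setdefault(key, []).append(rid)
    else:
        raise ValueError(f"unknown deduplication mode {mode!r}")

    for key, members in groups.items():
        if len(members) < 2:
            continue
        survivor_id = min(members)
        survivor = out.reactions[survivor_id]
        merged_rule = survivor.gene_rule
        for rid in members:
            if rid == survivor_id:
                continue
            merged_rule = or_(merged_rule, out.reactions[rid].gene_rule)
            log.append(f"removed duplicate reaction {rid}; merged into {survivor_id}")
            del out.reactions[rid]
        survivor.gene_rule = merged_rule
    return out, log


def remove_empty_reactions(
    net: MetabolicNetwork,
) -> tuple[MetabolicNetwork, list[str]]:
    """Remove reactions with no reactants and no products."""
    out = net.copy()
    log = []
    for rid in sorted(out.reactions):
        if not out.reactions[rid].stoichiometry:
            log.append(f"removed empty reaction {rid}")
            del out.reactions[rid]
    return out, log


def preprocess(
    net: MetabolicNetwork, mode: str = "by_equation", table=None
) -> tuple[MetabolicNetwork, list[str]]:
    """Standard comparison pre-step: drop empty reactions, merge duplicates."""
    out, log1 = remove_empty_reactions(net)
    out, log2 = deduplicate_reactions(out, mode=mode, table=table)
    classify_network(out)
    return out, log1 + log2
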