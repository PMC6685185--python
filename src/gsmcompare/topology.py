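"""Structural diagnostics of a single metabolic network.

Three classic reconstruction-quality indicators:

* dead-end metabolites — species that are only produced or only consumed,
  the hallmark of disrupted pathways and missing reactions;
* orphan reactions — reactions without any gene association, excluding
  boundary (exchange/demand/sink) reactions which never carry genes;
* unconnected reactions — reactions sharing no metabolite with any other
  reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import MetabolicNetwork, ReactionClass

__all__ = [
    "TopologyReport",
    "dead_end_metabolites",
    "orphan_reactions",
    "unconnected_reactions",
    "topology_report",
]


@dataclass
class TopologyReport:
    dead_end_metabolites: set[str] = field(default_factory=set)
    orphan_reactions: set[str] = field(default_factory=set)
    unconnected_reactions: set[str] = field(default_factory=set)

    def summary(self) -> dict:
        return {
            "n_dead_end_metabolites": len(self.dead_end_metabolites),
            "n_orphan_reactions": len(self.orphan_reactions),
            "n_unconnected_reactions": len(self.unconnected_reactions),
        }


def dead_end_metabolites(net: MetabolicNetwork) -> set[str]:
    """Metabolites that can only be produced or only consumed.

    A reversible reaction (lb < 0 < ub) counts as both producer and consumer
    of all its participants.  Exchange reactions count as both for their
    metabolite regardless of bounds: the boundary supplies the missing side,
    so an extracellular species served only by its exchange is not a dead
    end.  Demand and sink reactions count per their effective direction.
    Species participating in no reaction are not reported.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    participates: set[str] = set()
    for r in net.reactions.values():
        for met, coeff in r.stoichiometry.items():
            participates.add(met)
            if r.rclass == ReactionClass.EXCHANGE or r.reversible:
                produced.add(met)
                consumed.add(met)
                continue
            forward = r.upper_bound > 0
            makes = (coeff > 0) if forward else (coeff < 0)
            (produced if makes else consumed).add(met)
    return (produced ^ consumed) & participates


def orphan_reactions(net: MetabolicNetwork) -> set[str]:
    """Reactions without gene associations, excluding boundary reactions."""
    return {
        rid
        for rid, r in net.reactions.items()
        if r.gene_rule.is_empty() and r.rclass not in ReactionClass.BOUNDARY
    }


def unconnected_reactions(net: MetabolicNetwork) -> set[str]:
    """Reactions none of whose metabolites occurs in any other reaction."""
    usage: dict[str, int] = {}
    for r in net.reactions.values():
        for met in r.stoichiometry:
            usage[met] = usage.get(met, 0) + 1
    return {
        rid
        for rid, r in net.reactions.items()
        if r.stoichiometry
        and all(usage[m] == 1 for m in r.stoichiometry)
    }


def topology_report(net: MetabolicNetwork) -> TopologyReport:
    return TopologyReport(
        dead_end_metabolites=dead_end_metabolites(net),
        orphan_reactions=orphan_reactions(net),
        unconnected_reactions=unconnected_reactions(net),
    )
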