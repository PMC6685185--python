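"""In-memory containers for metabolic networks.

A :class:`MetabolicNetwork` holds genes, compartmented metabolites and
stoichiometric reactions with flux bounds and gene-reaction rules — the unit
on which all comparisons, diagnostics and flux simulations operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

from .gprs import EMPTY_RULE, GeneRule

__all__ = ["Metabolite", "Reaction", "MetabolicNetwork", "ReactionClass"]

# default bound magnitude used when an SBML file gives none
DEFAULT_BOUND = 1000.0


class ReactionClass:
    INTERNAL = "internal"
    TRANSPORT = "transport"
    EXCHANGE = "exchange"
    DEMAND = "demand"
    SINK = "sink"
    BIOMASS = "biomass"

    ALL = (INTERNAL, TRANSPORT, EXCHANGE, DEMAND, SINK, BIOMASS)
    BOUNDARY = (EXCHANGE, DEMAND, SINK)


@dataclass
class Metabolite:
    """A compartmented species.  ``full_id = core_id + '_' + compartment``."""

    full_id: str
    core_id: str
    compartment: str
    name: str = ""
    charge: int | None = None
    formula: str | None = None


@dataclass
class Reaction:
    """A stoichiometric reaction.

    ``stoichiometry`` maps metabolite full_id to a nonzero signed coefficient
    (negative = consumed, positive = produced).  ``gene_rule`` is a canonical
    AND/OR tree (possibly empty).  ``rclass`` is assigned by
    :func:`gsmcompare.model_io.classify_reaction`.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_rule: GeneRule = EMPTY_RULE
    rclass: str = ReactionClass.INTERNAL
    name: str = ""

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ValueError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def genes(self) -> frozenset[str]:
        return self.gene_rule.genes()

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicNetwork:
    """A genome-scale metabolic network."""

    id: str
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    objective_reaction: str | None = None

    @property
    def genes(self) -> frozenset[str]:
        """Gene set: union of genes over all gene-reaction rules."""
        out: set[str] = set()
        for r in self.reactions.values():
            out |= r.genes()
        return frozenset(out)

    @property
    def gene_set(self) -> frozenset[str]:
        return self.genes

    @property
    def metabolite_ids(self) -> frozenset[str]:
        return frozenset(self.metabolites)

    @property
    def reaction_ids(self) -> frozenset[str]:
        return frozenset(self.reactions)

    def add_metabolite(self, m: Metabolite) -> None:
        if m.full_id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {m.full_id}")
        self.metabolites[m.full_id] = m

    def add_reaction(self, r: Reaction) -> None:
        if r.id in self.reactions:
            raise ValueError(f"duplicate reaction id {r.id}")
        missing = [m for m in r.stoichiometry if m not in self.metabolites]
        if missing:
            raise ValueError(
                f"reaction {r.id} references unknown metabolites {missing}"
            )
        self.reactions[r.id] = r

    def remove_reactions(self, ids: Iterable[str]) -> None:
        for rid in ids:
            self.reactions.pop(rid)

    def copy(self) -> "MetabolicNetwork":
        net = MetabolicNetwork(
            id=self.id, objective_reaction=self.objective_reaction
        )
        net.metabolites = {k: replace(v) for k, v in self.metabolites.items()}
        net.reactions = {k: r.copy() for k, r in self.reactions.items()}
        return net

    def validate(self) -> None:
        """Check referential integrity; raises on violation."""
        for r in self.reactions.values():
            for m in r.stoichiometry:
                if m not in self.metabolites:
                    raise ValueError(
                        f"reaction {r.id} references unknown metabolite {m}"
                    )
        if (
            self.objective_reaction is not None
            and self.objective_reaction not in self.reactions
        ):
            raise ValueError(
                f"objective reaction {self.objective_reaction} not in network"
            )
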