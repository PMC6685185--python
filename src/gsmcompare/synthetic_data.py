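"""Synthetic reference/draft model pairs with planted, fully known divergence.

The generator emits a growth-capable reference network and derives a draft
from it by applying the kinds of divergence observed between automatic
draft reconstructions and manually curated models: incomplete gene recall
plus spurious extra genes, reaction dropout, proton-stoichiometry
perturbations (mimicking charge-state differences), direction reversals,
duplicate reactions, and metabolite/reaction renaming into an alternate
namespace.  Every change is recorded in a :class:`SyntheticTruth`, the
ground-truth oracle against which the comparison pipeline is scored.

The reference network is built around a deterministic growth core — nutrient
exchanges, transporters and conversion steps feeding a biomass assembly
reaction — guaranteeing FBA growth on the bundled medium, padded with
randomly generated mass-balanced side reactions.  Mass balance is enforced
by integer pseudo-formula bookkeeping: each species carries an integer
mass, padding reactions conserve total mass exactly, and a dedicated
proton species (mass 1) absorbs remainders, which also gives the
proton-perturbation machinery realistic targets.
"""

from __future__ import annotations

import random
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path

from .core import MetabolicNetwork, Metabolite, Reaction, ReactionClass
from .gprs import EMPTY_RULE, GeneRule, and_, gene, or_
from .model_io import classify_network
from .namespace_map import MappingTable, ROUTE_XREF
from .performance_eval import Medium, MediumComponent

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "Scenario",
    "generate_reference",
    "derive_draft",
    "generate_mapping",
    "generate_scenario",
    "reference_medium",
    "reference_phenotypes",
]

PROTON_CORE = "h"
# essential nutrients: each feeds exactly one biomass precursor
N_ESSENTIAL = 4
# one precursor is fed redundantly by two interchangeable nutrients
REDUNDANT_PAIR = ("nutra", "nutrb")

FATE_EXACT = "kept_exact"
FATE_PROTON = "kept_proton_perturbed"
FATE_REVERSED = "kept_reversed"
FATE_DROPPED = "dropped"
FATE_DUPLICATED = "duplicated"


@dataclass
class GeneratorConfig:
    """Knobs of one synthetic scenario; same seed, same outputs, bit for bit."""

    seed: int = 0
    n_reactions: int = 200
    n_metabolites: int = 150
    n_genes: int = 120
    orphan_fraction: float = 0.10
    exchange_fraction: float = 0.08
    gene_recall: float = 0.80
    extra_gene_fraction: float = 0.10
    reaction_dropout: float = 0.20
    proton_perturb_rate: float = 0.05
    reversal_rate: float = 0.03
    duplicate_rate: float = 0.05
    rename_rate: float = 0.30
    mapping_completeness: float = 1.0
    # when 2+, only metabolites occurring in at least this many reactions
    # are eligible for renaming (needed for synonym-recovery studies)
    rename_min_occurrence: int = 1

    def validate(self) -> None:
        for name in (
            "orphan_fraction", "exchange_fraction", "gene_recall",
            "extra_gene_fraction", "reaction_dropout", "proton_perturb_rate",
            "reversal_rate", "duplicate_rate", "rename_rate",
            "mapping_completeness",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_reactions", "n_metabolites", "n_genes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticTruth:
    """Planted divergence between a reference and its derived draft."""

    seed: int
    shared_genes: frozenset[str] = frozenset()
    extra_genes: frozenset[str] = frozenset()
    missed_genes: frozenset[str] = frozenset()
    reaction_fates: dict[str, str] = field(default_factory=dict)
    duplicate_ids: dict[str, str] = field(default_factory=dict)
    metabolite_renames: dict[str, str] = field(default_factory=dict)
    reaction_renames: dict[str, str] = field(default_factory=dict)
    withheld_metabolites: frozenset[str] = frozenset()
    withheld_reactions: frozenset[str] = frozenset()

    def fate_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for fate in self.reaction_fates.values():
            out[fate] = out.get(fate, 0) + 1
        return out

    def write_tsv(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        lines = ["# ref_reaction\tfate"]
        for rid in sorted(self.reaction_fates):
            lines.append(f"{rid}\t{self.reaction_fates[rid]}")
        (directory / "reaction_fates.tsv").write_text("\n".join(lines) + "\n")
        lines = ["# draft_core\tref_core\twithheld"]
        for d in sorted(self.metabolite_renames):
            w = "yes" if d in self.withheld_metabolites else "no"
            lines.append(f"{d}\t{self.metabolite_renames[d]}\t{w}")
        (directory / "metabolite_renames.tsv").write_text("\n".join(lines) + "\n")
        lines = ["# gene\tstatus"]
        for g in sorted(self.shared_genes):
            lines.append(f"{g}\tshared")
        for g in sorted(self.extra_genes):
            lines.append(f"{g}\textra")
        for g in sorted(self.missed_genes):
            lines.append(f"{g}\tmissed")
        (directory / "genes.tsv").write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------------ helpers

def _essential_nutrients() -> list[str]:
    return [f"nut{i}" for i in range(1, N_ESSENTIAL + 1)]


def reference_medium(name: str = "basal") -> Medium:
    """The bundled basal medium: every nutrient available at uptake 10."""
    comps = [
        MediumComponent(n, f"EX_{n}_e", 10.0)
        for n in _essential_nutrients() + list(REDUNDANT_PAIR)
    ]
    return Medium(name=name, components=comps)


def reference_phenotypes() -> dict[str, bool]:
    """In-vivo growth phenotype for each single-omission experiment.

    Essential nutrients abolish growth when omitted; either member of the
    redundant pair can be omitted without losing growth.
    """
    pheno = {n: False for n in _essential_nutrients()}
    pheno.update({n: True for n in REDUNDANT_PAIR})
    return pheno


def _rule_from_genes(genes: list[str], pattern: int) -> GeneRule:
    if pattern == 0 or len(genes) == 1:
        return gene(genes[0])
    if pattern == 1:
        return or_(gene(genes[0]), gene(genes[1]))
    if pattern == 2:
        return and_(gene(genes[0]), gene(genes[1]))
    if len(genes) >= 3:
        return or_(and_(gene(genes[0]), gene(genes[1])), gene(genes[2]))
    return and_(gene(genes[0]), gene(genes[1]))


# --------------------------------------------------------------- reference

def generate_reference(cfg: GeneratorConfig) -> MetabolicNetwork:
    """Generate a growth-capable reference network.

    The network contains a deterministic growth core (nutrient exchanges,
    transporters, conversion steps, a mass-balanced biomass assembly plus
    biomass drain, and a proton exchange) padded with seeded random
    mass-balanced reactions up to exactly ``cfg.n_reactions`` reactions and
    ``cfg.n_metabolites`` metabolites.  Raises on infeasible configurations.
    """
    cfg.validate()
    rng = random.Random(cfg.seed)
    net = MetabolicNetwork(id=f"ref_seed{cfg.seed}")
    masses: dict[str, int] = {}

    def add_met(core: str, comp: str, mass: int) -> str:
        full = f"{core}_{comp}"
        net.add_metabolite(
            Metabolite(full_id=full, core_id=core, compartment=comp)
        )
        masses[full] = mass
        return full

    # --- growth core -----------------------------------------------------
    core_rxns: list[Reaction] = []
    nutrients = _essential_nutrients()
    precursor_mass: dict[str, int] = {}
    for i, nut in enumerate(nutrients, start=1):
        mass = 60 + 17 * i
        add_met(nut, "e", mass)
        add_met(nut, "c", mass)
        prec = add_met(f"prec{i}", "c", mass)
        precursor_mass[prec] = mass
        core_rxns.append(Reaction(
            id=f"EX_{nut}_e", stoichiometry={f"{nut}_e": -1.0},
            lower_bound=-1000.0, upper_bound=1000.0,
        ))
        core_rxns.append(Reaction(
            id=f"T_{nut}", stoichiometry={f"{nut}_e": -1.0, f"{nut}_c": 1.0},
            lower_bound=0.0, upper_bound=1000.0,
        ))
        core_rxns.append(Reaction(
            id=f"C_{nut}", stoichiometry={f"{nut}_c": -1.0, prec: 1.0},
            lower_bound=0.0, upper_bound=1000.0,
        ))
    # redundant pair: both nutrients convert to the same fifth precursor
    red_mass = 95
    prec5 = add_met("prec5", "c", red_mass)
    precursor_mass[prec5] = red_mass
    for nut in REDUNDANT_PAIR:
        add_met(nut, "e", red_mass)
        add_met(nut, "c", red_mass)
        core_rxns.append(Reaction(
            id=f"EX_{nut}_e", stoichiometry={f"{nut}_e": -1.0},
            lower_bound=-1000.0, upper_bound=1000.0,
        ))
        core_rxns.append(Reaction(
            id=f"T_{nut}", stoichiometry={f"{nut}_e": -1.0, f"{nut}_c": 1.0},
            lower_bound=0.0, upper_bound=1000.0,
        ))
        core_rxns.append(Reaction(
            id=f"C_{nut}", stoichiometry={f"{nut}_c": -1.0, prec5: 1.0},
            lower_bound=0.0, upper_bound=1000.0,
        ))
    h_c = add_met(PROTON_CORE, "c", 1)
    h_e = add_met(PROTON_CORE, "e", 1)
    core_rxns.append(Reaction(
        id="EX_h_e", stoichiometry={h_e: -1.0},
        lower_bound=-1000.0, upper_bound=1000.0,
    ))
    core_rxns.append(Reaction(
        id="T_h", stoichiometry={h_c: -1.0, h_e: 1.0},
        lower_bound=-1000.0, upper_bound=1000.0,
    ))
    bm_mass = sum(precursor_mass.values())
    bm = add_met("bm", "c", bm_mass)
    core_rxns.append(Reaction(
        id="biomass",
        stoichiometry={**{p: -1.0 for p in precursor_mass}, bm: 1.0},
        lower_bound=0.0, upper_bound=1000.0,
    ))
    core_rxns.append(Reaction(
        id="DM_biomass",
        stoichiometry={bm: -1.0}, lower_bound=0.0, upper_bound=1000.0,
    ))

    n_core = len(core_rxns)           # 22 with the default core
    n_core_mets = len(net.metabolites)

    # --- exchange budget --------------------------------------------------
    n_core_ex = sum(1 for r in core_rxns if len(r.stoichiometry) == 1
                    and r.lower_bound < 0 < r.upper_bound)
    n_ex_total = max(n_core_ex, round(cfg.exchange_fraction * cfg.n_reactions))
    n_extra_ex = n_ex_total - n_core_ex

    n_internal = cfg.n_reactions - n_core - 2 * n_extra_ex
    n_new_mets = cfg.n_metabolites - n_core_mets - 2 * n_extra_ex
    if n_internal < 0:
        raise ValueError(
            f"n_reactions={cfg.n_reactions} too small for the growth core "
            f"plus {n_extra_ex} extra exchanges"
        )
    if n_new_mets < 0:
        raise ValueError(
            f"n_metabolites={cfg.n_metabolites} too small: the growth core "
            f"and exchanged byproducts already need "
            f"{n_core_mets + 2 * n_extra_ex}"
        )
    if n_new_mets > n_internal:
        raise ValueError(
            f"cannot introduce {n_new_mets} new metabolites with only "
            f"{n_internal} internal padding reactions"
        )

    # metabolites whose production by padding would break planted
    # nutrient essentiality
    protected = {f"{n}_c" for n in nutrients + list(REDUNDANT_PAIR)}
    protected |= set(precursor_mass) | {bm}
    protected |= {f"{n}_e" for n in nutrients + list(REDUNDANT_PAIR)}

    pool: list[str] = sorted(
        m for m in net.metabolites
        if net.metabolites[m].compartment == "c" and m != h_c
    )

    extra_rxns: list[Reaction] = []
    for k in range(n_extra_ex):
        mass = rng.randrange(40, 200)
        byp_c = add_met(f"byp{k}", "c", mass)
        byp_e = add_met(f"byp{k}", "e", mass)
        extra_rxns.append(Reaction(
            id=f"EX_byp{k}_e", stoichiometry={byp_e: -1.0},
            lower_bound=-1000.0, upper_bound=1000.0,
        ))
        extra_rxns.append(Reaction(
            id=f"T_byp{k}", stoichiometry={byp_c: -1.0, byp_e: 1.0},
            lower_bound=-1000.0, upper_bound=1000.0,
        ))
        pool.append(byp_c)

    # --- mass-balanced random padding ------------------------------------
    # Reference equations are kept unique even modulo direction and proton
    # stoichiometry, so that every planted perturbation has exactly one
    # possible match and greedy assignment cannot be ambiguous.
    equation_keys: set[tuple] = set()

    def register(stoich: dict[str, float]) -> bool:
        variants = [stoich, {m: -c for m, c in stoich.items()}]
        stripped = {m: c for m, c in stoich.items() if m not in (h_c, h_e)}
        if stripped and len(stripped) < len(stoich):
            variants.append(stripped)
            variants.append({m: -c for m, c in stripped.items()})
        keys = [tuple(sorted(v.items())) for v in variants]
        if any(k in equation_keys for k in keys):
            return False
        equation_keys.update(keys)
        return True

    for r in core_rxns + extra_rxns:
        register(r.stoichiometry)

    def product_pool() -> list[tuple[int, str]]:
        cands = [
            (masses[m], m) for m in pool if m not in protected
        ]
        cands.sort()
        return cands

    pad_rxns: list[Reaction] = []
    n_created = 0

    def make_products(total: int, exclude: set[str]) -> dict[str, float] | None:
        """Greedy mass decomposition of ``total`` into pool species + protons."""
        cands = product_pool()
        out: dict[str, float] = {}
        remaining = total
        for _ in range(2):
            idx = bisect_right(cands, (remaining, chr(0x10FFFF))) - 1
            while idx >= 0 and (cands[idx][1] in exclude or cands[idx][1] in out):
                idx -= 1
            if idx < 0:
                break
            mass, met = cands[idx]
            out[met] = 1.0
            remaining -= mass
            if remaining <= 6:
                break
        if not out or remaining < 0 or remaining > 6:
            return None
        if remaining > 0:
            out[h_c] = float(remaining)
        return out

    attempts = 0
    while len(pad_rxns) < n_internal:
        attempts += 1
        if attempts > 200 * n_internal + 1000:
            raise ValueError(
                "padding generation failed to converge; configuration "
                "is too tight (raise n_metabolites or lower n_reactions)"
            )
        reversible = rng.random() < 0.3
        reactant_pool = [
            m for m in pool if not (reversible and m in protected)
        ]
        n_react = rng.choice((1, 2))
        if len(reactant_pool) < n_react:
            continue
        reactants = rng.sample(sorted(reactant_pool), n_react)
        total = sum(masses[m] for m in reactants)

        if n_created < n_new_mets:
            # creation reaction: reactants -> one brand-new species (+ protons)
            p = rng.choice((0, 1, 2))
            if total - p <= 0:
                continue
            new_core = f"m{n_created:04d}"
            stoich = {m: -1.0 for m in reactants}
            new_full = f"{new_core}_c"
            stoich[new_full] = 1.0
            if p:
                stoich[h_c] = stoich.get(h_c, 0.0) + float(p)
            # register before the metabolite exists so a retry cannot leak it
            probe = dict(stoich)
            if not register(probe):
                continue
            add_met(new_core, "c", total - p)
            pool.append(new_full)
            n_created += 1
        else:
            products = make_products(total, exclude=set(reactants))
            if products is None:
                continue
            stoich = {m: -1.0 for m in reactants}
            for m, c in products.items():
                stoich[m] = stoich.get(m, 0.0) + c
            stoich = {m: c for m, c in stoich.items() if c != 0.0}
            if len(stoich) < 2 or not register(stoich):
                continue
        rid = f"RP{len(pad_rxns):04d}"
        pad_rxns.append(Reaction(
            id=rid,
            stoichiometry=stoich,
            lower_bound=-1000.0 if reversible else 0.0,
            upper_bound=1000.0,
        ))

    all_rxns = core_rxns + extra_rxns + pad_rxns
    for r in all_rxns:
        net.add_reaction(r)
    net.objective_reaction = "biomass"
    classify_network(net)

    # --- gene rules -------------------------------------------------------
    gene_ids = [f"g{i:04d}" for i in range(1, cfg.n_genes + 1)]
    rule_bearing = sorted(
        rid for rid, r in net.reactions.items()
        if r.rclass not in ReactionClass.BOUNDARY
    )
    n_orphan = min(round(cfg.orphan_fraction * cfg.n_reactions),
                   len(rule_bearing))
    orphans = set(rng.sample(rule_bearing, n_orphan))
    slots = [rid for rid in rule_bearing if rid not in orphans]
    # deal genes out so that every gene is used when there are enough slots
    deck: list[str] = []
    while len(deck) < 3 * len(slots) + cfg.n_genes:
        block = list(gene_ids)
        rng.shuffle(block)
        deck.extend(block)
    pos = 0
    for rid in slots:
        pattern = rng.choices((0, 1, 2, 3), weights=(50, 25, 15, 10))[0]
        need = {0: 1, 1: 2, 2: 2, 3: 3}[pattern]
        picked: list[str] = []
        while len(picked) < need:
            g = deck[pos]
            pos += 1
            if g not in picked:
                picked.append(g)
        net.reactions[rid].gene_rule = _rule_from_genes(picked, pattern)
    net.validate()
    return net


# ------------------------------------------------------------------- draft

def _prune_rule(rule: GeneRule, keep: set[str]) -> GeneRule:
    if rule.is_empty():
        return EMPTY_RULE
    if rule.op == "gene":
        return rule if rule.name in keep else EMPTY_RULE
    children = [_prune_rule(c, keep) for c in rule.children]
    children = [c for c in children if not c.is_empty()]
    if not children:
        return EMPTY_RULE
    return and_(*children) if rule.op == "and" else or_(*children)


def derive_draft(
    ref: MetabolicNetwork, cfg: GeneratorConfig
) -> tuple[MetabolicNetwork, SyntheticTruth]:
    """Derive a perturbed draft from the reference, recording all changes."""
    rng = random.Random(cfg.seed + 10_007)
    truth = SyntheticTruth(seed=cfg.seed)

    # --- gene subsampling -------------------------------------------------
    ref_genes = sorted(ref.genes)
    n_keep = round(cfg.gene_recall * len(ref_genes))
    kept_genes = set(rng.sample(ref_genes, n_keep))
    n_extra = round(cfg.extra_gene_fraction * len(ref_genes))
    extra_genes = [f"xg{i:04d}" for i in range(1, n_extra + 1)]

    # --- reaction fates ---------------------------------------------------
    ref_rids = sorted(ref.reactions)
    undroppable = {"biomass", "DM_biomass", ref.objective_reaction}
    droppable = [rid for rid in ref_rids if rid not in undroppable]
    n_drop = min(round(cfg.reaction_dropout * len(ref_rids)), len(droppable))
    dropped = set(rng.sample(droppable, n_drop))
    kept = [rid for rid in ref_rids if rid not in dropped]

    # reactions made entirely of protons (the proton exchange/transport)
    # are excluded: stripping protons from them leaves nothing to match
    proton_eligible = sorted(
        rid for rid in kept
        if any(
            ref.metabolites[m].core_id == PROTON_CORE
            for m in ref.reactions[rid].stoichiometry
        )
        and any(
            ref.metabolites[m].core_id != PROTON_CORE
            for m in ref.reactions[rid].stoichiometry
        )
    )
    n_pp = min(round(cfg.proton_perturb_rate * len(proton_eligible)),
               len(proton_eligible))
    perturbed = set(rng.sample(proton_eligible, n_pp))

    reversal_eligible = sorted(
        rid for rid in kept
        if rid not in perturbed
        and len(ref.reactions[rid].stoichiometry) >= 2
        and ref.reactions[rid].rclass
        not in (ReactionClass.BIOMASS, ReactionClass.EXCHANGE)
    )
    n_rev = min(round(cfg.reversal_rate * len(kept)), len(reversal_eligible))
    reversed_ = set(rng.sample(reversal_eligible, n_rev))

    exact_pool = sorted(set(kept) - perturbed - reversed_)
    n_dup = min(round(cfg.duplicate_rate * len(kept)), len(exact_pool))
    duplicated = set(rng.sample(exact_pool, n_dup))

    for rid in ref_rids:
        if rid in dropped:
            truth.reaction_fates[rid] = FATE_DROPPED
        elif rid in perturbed:
            truth.reaction_fates[rid] = FATE_PROTON
        elif rid in reversed_:
            truth.reaction_fates[rid] = FATE_REVERSED
        elif rid in duplicated:
            truth.reaction_fates[rid] = FATE_DUPLICATED
        else:
            truth.reaction_fates[rid] = FATE_EXACT

    # --- metabolite renaming ---------------------------------------------
    occurrence: dict[str, int] = {}
    for rid in kept:
        for m in ref.reactions[rid].stoichiometry:
            core = ref.metabolites[m].core_id
            occurrence[core] = occurrence.get(core, 0) + 1
    rename_pool = sorted(
        core for core, n in occurrence.items()
        if core != PROTON_CORE and n >= cfg.rename_min_occurrence
    )
    n_ren = min(round(cfg.rename_rate * len(rename_pool)), len(rename_pool))
    renamed_cores = rng.sample(rename_pool, n_ren)
    rename_map = {
        core: f"synX_{i:04d}" for i, core in enumerate(sorted(renamed_cores))
    }
    truth.metabolite_renames = {v: k for k, v in rename_map.items()}

    # --- reaction-id renaming --------------------------------------------
    renameable = sorted(set(kept) - undroppable)
    n_rxn_ren = min(round(cfg.rename_rate * len(kept)), len(renameable))
    rxn_renamed = rng.sample(renameable, n_rxn_ren)
    rxn_rename_map = {
        rid: f"synr_{i:04d}" for i, rid in enumerate(sorted(rxn_renamed))
    }
    truth.reaction_renames = {v: k for k, v in rxn_rename_map.items()}

    # --- assemble the draft -----------------------------------------------
    draft = MetabolicNetwork(id=f"draft_seed{cfg.seed}")

    def draft_met(ref_full: str) -> str:
        m = ref.metabolites[ref_full]
        core = rename_map.get(m.core_id, m.core_id)
        full = f"{core}_{m.compartment}"
        if full not in draft.metabolites:
            draft.add_metabolite(Metabolite(
                full_id=full, core_id=core, compartment=m.compartment,
                name=m.name,
            ))
        return full

    proton_fulls = {
        m for m in ref.metabolites
        if ref.metabolites[m].core_id == PROTON_CORE
    }

    def build_stoich(rid: str) -> dict[str, float]:
        r = ref.reactions[rid]
        stoich = {draft_met(m): c for m, c in r.stoichiometry.items()}
        if rid in perturbed:
            targets = [draft_met(m) for m in r.stoichiometry if m in proton_fulls]
            t = sorted(targets)[0]
            # magnitude +1, mimicking a charge-state difference
            stoich[t] += 1.0 if stoich[t] > 0 else -1.0
        if rid in reversed_:
            stoich = {m: -c for m, c in stoich.items()}
        return stoich

    for rid in kept:
        r = ref.reactions[rid]
        new_id = rxn_rename_map.get(rid, rid)
        rule = _prune_rule(r.gene_rule, kept_genes)
        lb, ub = r.lower_bound, r.upper_bound
        if rid in reversed_:
            lb, ub = -r.upper_bound, -r.lower_bound
        draft.add_reaction(Reaction(
            id=new_id,
            stoichiometry=build_stoich(rid),
            lower_bound=lb,
            upper_bound=ub,
            gene_rule=rule,
        ))

    for rid in sorted(duplicated):
        dup_id = f"dup_{rxn_rename_map.get(rid, rid)}"
        dup_gene = rng.choice(sorted(kept_genes)) if kept_genes else None
        draft.add_reaction(Reaction(
            id=dup_id,
            stoichiometry=build_stoich(rid),
            lower_bound=ref.reactions[rid].lower_bound,
            upper_bound=ref.reactions[rid].upper_bound,
            gene_rule=gene(dup_gene) if dup_gene else EMPTY_RULE,
        ))
        truth.duplicate_ids[dup_id] = rid

    # guarantee every sampled kept gene and every extra gene appears in a rule
    rule_hosts = sorted(
        rid for rid, r in draft.reactions.items()
        if not r.gene_rule.is_empty()
    )
    if not rule_hosts:
        rule_hosts = sorted(draft.reactions)
    present = draft.genes
    for g in sorted(kept_genes - present) + extra_genes:
        host = draft.reactions[rng.choice(rule_hosts)]
        host.gene_rule = or_(host.gene_rule, gene(g))

    obj = rxn_rename_map.get(ref.objective_reaction, ref.objective_reaction)
    if obj in draft.reactions:
        draft.objective_reaction = obj
    classify_network(draft)
    draft.validate()

    truth.shared_genes = frozenset(draft.genes & ref.genes)
    truth.extra_genes = frozenset(draft.genes - ref.genes)
    truth.missed_genes = frozenset(ref.genes - draft.genes)
    return draft, truth


# ----------------------------------------------------------------- mapping

def generate_mapping(
    truth: SyntheticTruth, completeness: float, seed: int | None = None
) -> MappingTable:
    """Emit the rename tables as a mapping table, withholding a fraction.

    A seeded random fraction ``completeness`` of the planted rename entries
    is retained; the withheld entries are recorded on ``truth`` so synonym
    discovery can be scored against them.
    """
    rng = random.Random((seed if seed is not None else truth.seed) + 77_003)
    table = MappingTable()

    met_sources = sorted(truth.metabolite_renames)
    n_keep = round(completeness * len(met_sources))
    kept = set(rng.sample(met_sources, n_keep))
    for src in met_sources:
        if src in kept:
            table.add_metabolite_synonym(
                src, truth.metabolite_renames[src], ROUTE_XREF
            )
    truth.withheld_metabolites = frozenset(set(met_sources) - kept)

    rxn_sources = sorted(truth.reaction_renames)
    n_keep_r = round(completeness * len(rxn_sources))
    kept_r = set(rng.sample(rxn_sources, n_keep_r))
    for src in rxn_sources:
        if src in kept_r:
            table.add_reaction_synonym(
                src, truth.reaction_renames[src], ROUTE_XREF
            )
    truth.withheld_reactions = frozenset(set(rxn_sources) - kept_r)
    return table


@dataclass
class Scenario:
    """A complete synthetic study: model pair, truth, mapping and medium."""

    cfg: GeneratorConfig
    reference: MetabolicNetwork
    draft: MetabolicNetwork
    truth: SyntheticTruth
    mapping: MappingTable
    medium: Medium
    phenotypes: dict[str, bool]
    omission_compounds: list[str]


def generate_scenario(cfg: GeneratorConfig) -> Scenario:
    """Generate reference, draft, truth and mapping for one configuration."""
    ref = generate_reference(cfg)
    draft, truth = derive_draft(ref, cfg)
    mapping = generate_mapping(truth, cfg.mapping_completeness)
    return Scenario(
        cfg=cfg,
        reference=ref,
        draft=draft,
        truth=truth,
        mapping=mapping,
        medium=reference_medium(),
        phenotypes=reference_phenotypes(),
        omission_compounds=_essential_nutrients() + list(REDUNDANT_PAIR),
    )
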