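"""Draft-versus-reference network comparison.

Compares a draft reconstruction against a manually curated reference at the
gene, metabolite and reaction level.  Two set-similarity summaries are
produced for each element class: the Jaccard distance

    JD = 1 - |S_i intersect S_ref| / |S_i union S_ref|

and the ratio between covered and additional elements

    R = |S_i intersect S_ref| / |S_i - S_ref|

together with coverage and additional-element percentages relative to the
reference.  Reaction sets are compared by two complementary routes: mapped
identifiers (case-sensitive string comparison after cross-namespace
translation) and reaction equations (stoichiometry comparison with
tolerance for proton-stoichiometry differences and for equations written in
the opposite direction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .core import MetabolicNetwork, Reaction, ReactionClass
from .model_io import preprocess, split_compartment
from .namespace_map import MappingTable, map_metabolite, map_reaction_id

__all__ = [
    "PROTON_CORE_IDS",
    "ComparisonReport",
    "ReactionMatch",
    "jaccard",
    "ratio",
    "match_equations",
    "compare_genes",
    "compare_metabolite_sets",
    "compare_reaction_sets",
]

# Core ids treated as protons in any compartment; configurable per call.
PROTON_CORE_IDS = frozenset({"h", "H", "cpd00067", "PROTON"})

# relative tolerance for comparing raw stoichiometric coefficients
STOICH_RTOL = 1e-6

CAT_IDENTIFIER = "identifier"
CAT_EXACT = "equation_exact"
CAT_PROTON = "proton_partial"
CAT_REVERSED = "reversed"
CAT_NONE = "none"


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """Jaccard distance between two sets; NaN when both are empty."""
    union = len(a | b)
    if union == 0:
        return math.nan
    return 1.0 - len(a & b) / union


def ratio(draft: frozenset | set, ref: frozenset | set) -> float:
    """Covered-to-additional ratio |draft∩ref| / |draft−ref|.

    Returns +inf when the draft adds nothing but covers something, and NaN
    when both intersection and difference are empty.
    """
    inter = len(draft & ref)
    diff = len(draft - ref)
    if diff == 0:
        return math.inf if inter > 0 else math.nan
    return inter / diff


@dataclass
class ReactionMatch:
    draft_id: str
    ref_id: str | None
    category: str


@dataclass
class ComparisonReport:
    """Outcome of one element-class comparison."""

    kind: str
    n_draft: int
    n_ref: int
    n_ref_denominator: int  # reference size after exclusions (biomass etc.)
    covered: set[str] = field(default_factory=set)     # matched ref elements
    additional: set[str] = field(default_factory=set)  # unmatched draft elements
    missed: set[str] = field(default_factory=set)      # unmatched ref elements
    coverage_pct: float = math.nan
    additional_pct: float = math.nan
    jd: float = math.nan
    r: float = math.nan
    n_proton_partial: int = 0
    matches: list[ReactionMatch] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "kind": self.kind,
            "n_draft": self.n_draft,
            "n_ref": self.n_ref,
            "n_covered": len(self.covered),
            "n_additional": len(self.additional),
            "n_missed": len(self.missed),
            "n_proton_partial": self.n_proton_partial,
            "coverage_pct": round(self.coverage_pct, 1)
            if math.isfinite(self.coverage_pct) else None,
            "additional_pct": round(self.additional_pct, 1)
            if math.isfinite(self.additional_pct) else None,
            "jaccard_distance": self.jd if not math.isnan(self.jd) else None,
            "ratio": self.r
            if math.isfinite(self.r)
            else ("inf" if self.r == math.inf else None),
        }


def _set_report(kind: str, draft_set: frozenset, ref_set: frozenset) -> ComparisonReport:
    rep = ComparisonReport(
        kind=kind,
        n_draft=len(draft_set),
        n_ref=len(ref_set),
        n_ref_denominator=len(ref_set),
        covered=set(draft_set & ref_set),
        additional=set(draft_set - ref_set),
        missed=set(ref_set - draft_set),
    )
    if ref_set:
        rep.coverage_pct = 100.0 * len(rep.covered) / len(ref_set)
        rep.additional_pct = 100.0 * len(rep.additional) / len(ref_set)
    else:
        rep.warnings.append(f"empty reference {kind} set: metrics undefined")
    rep.jd = jaccard(draft_set, ref_set)
    rep.r = ratio(draft_set, ref_set)
    return rep


def compare_genes(
    draft: MetabolicNetwork, ref: MetabolicNetwork
) -> ComparisonReport:
    """Compare gene sets by case-sensitive identifier comparison."""
    return _set_report("genes", draft.genes, ref.genes)


def compare_metabolite_sets(
    draft: MetabolicNetwork, ref: MetabolicNetwork, table: MappingTable
) -> ComparisonReport:
    """Compare metabolite sets on compartmented ids after translation.

    Every draft metabolite is passed through the namespace mapping; a draft
    metabolite is covered when some synonym, re-concatenated with its
    compartment token, is a member of the reference metabolite set.
    """
    translated: set[str] = set()
    unmatched: set[str] = set()
    for full_id in sorted(draft.metabolites):
        m = map_metabolite(full_id, table, ref)
        if m.target is not None:
            translated.add(m.target)
        else:
            unmatched.add(full_id)
    ref_set = ref.metabolite_ids
    rep = ComparisonReport(
        kind="metabolites",
        n_draft=len(draft.metabolites),
        n_ref=len(ref_set),
        n_ref_denominator=len(ref_set),
        covered=set(translated),
        additional=unmatched,
        missed=set(ref_set - translated),
    )
    if ref_set:
        rep.coverage_pct = 100.0 * len(rep.covered) / len(ref_set)
        rep.additional_pct = 100.0 * len(rep.additional) / len(ref_set)
    else:
        rep.warnings.append("empty reference metabolite set: metrics undefined")
    # JD/R on translated draft ids so shared elements coincide
    draft_as_ref = translated | unmatched
    rep.jd = jaccard(draft_as_ref, ref_set)
    rep.r = ratio(draft_as_ref, ref_set)
    return rep


# --------------------------------------------------------------- equations

def _close(a: float, b: float) -> bool:
    return math.isclose(a, b, rel_tol=STOICH_RTOL, abs_tol=0.0)


def _stoich_equal(s1: dict[str, float], s2: dict[str, float]) -> bool:
    if s1.keys() != s2.keys():
        return False
    return all(_close(s1[m], s2[m]) for m in s1)


def _strip_protons(
    stoich: dict[str, float], proton_cores: frozenset[str]
) -> dict[str, float]:
    out = {}
    for met, coeff in stoich.items():
        core, _comp = split_compartment(met)
        if core in proton_cores:
            continue
        out[met] = coeff
    return out


def translate_stoichiometry(
    r: Reaction, met_map: dict[str, str | None]
) -> dict[str, float] | None:
    """Translate a draft reaction's metabolites into the reference namespace.

    ``met_map`` maps each draft metabolite full_id to its reference
    counterpart or None.  Any untranslated metabolite blocks equation-level
    matching, so None is returned for the whole reaction.
    """
    out: dict[str, float] = {}
    for met, coeff in r.stoichiometry.items():
        target = met_map.get(met)
        if target is None:
            return None
        out[target] = out.get(target, 0.0) + coeff
    return {m: c for m, c in out.items() if c != 0.0}


def match_equations(
    draft_stoich: dict[str, float] | None,
    ref_stoich: dict[str, float],
    proton_cores: frozenset[str] = PROTON_CORE_IDS,
) -> str:
    """Categorise the relationship between two translated equations.

    Returns ``equation_exact`` when the stoichiometries are identical within
    tolerance, ``reversed`` when identical after negating one side,
    ``proton_partial`` when identical (directly or reversed) once all proton
    species are deleted from both, and ``none`` otherwise.  A draft equation
    blocked by untranslated metabolites (None) never matches.
    """
    if draft_stoich is None:
        return CAT_NONE
    if _stoich_equal(draft_stoich, ref_stoich):
        return CAT_EXACT
    negated = {m: -c for m, c in draft_stoich.items()}
    if _stoich_equal(negated, ref_stoich):
        return CAT_REVERSED
    d = _strip_protons(draft_stoich, proton_cores)
    r = _strip_protons(ref_stoich, proton_cores)
    if d and r:
        if _stoich_equal(d, r) or _stoich_equal({m: -c for m, c in d.items()}, r):
            return CAT_PROTON
    return CAT_NONE


def _stoich_key(stoich: dict[str, float], ndigits: int = 9) -> tuple:
    return tuple(sorted((m, round(c, ndigits)) for m, c in stoich.items()))


def build_met_map(
    draft: MetabolicNetwork, ref: MetabolicNetwork, table: MappingTable
) -> dict[str, str | None]:
    """Translate every draft metabolite id into the reference namespace."""
    return {
        full_id: map_metabolite(full_id, table, ref).target
        for full_id in draft.metabolites
    }


def compare_reaction_sets(
    draft: MetabolicNetwork,
    ref: MetabolicNetwork,
    table: MappingTable,
    method: str = "by_equation",
    exclude_exchange: bool = False,
    proton_cores: frozenset[str] = PROTON_CORE_IDS,
    preprocessed: bool = False,
) -> ComparisonReport:
    """Compare reaction sets by mapped identifiers or by reaction equations.

    ``by_id`` deduplicates both networks on mapped identifiers and compares
    translated reaction ids case-sensitively.  ``by_equation`` removes empty
    reactions, deduplicates on identical equations, and then matches
    equations draft-by-reference with greedy one-to-one assignment in
    category priority exact > reversed > proton_partial; proton-partial
    matches are tallied separately and excluded from the JD/R intersection.

    The coverage and additional percentages use the corrected reference
    size: total reference reactions minus biomass-class reactions (and
    minus exchange-class when ``exclude_exchange``).
    """
    if not preprocessed:
        mode = "by_mapped_id" if method == "by_id" else "by_equation"
        draft, _ = preprocess(draft, mode=mode, table=table if method == "by_id" else None)
        ref, _ = preprocess(ref, mode=mode, table=table if method == "by_id" else None)

    def included(r: Reaction) -> bool:
        return not (exclude_exchange and r.rclass == ReactionClass.EXCHANGE)

    draft_rxns = {rid: r for rid, r in draft.reactions.items() if included(r)}
    ref_rxns = {rid: r for rid, r in ref.reactions.items() if included(r)}

    matches: list[ReactionMatch] = []
    assigned_ref: set[str] = set()

    if method == "by_id":
        for rid in sorted(draft_rxns):
            mapped = map_reaction_id(rid, table, ref)
            if mapped is not None and mapped in ref_rxns and mapped not in assigned_ref:
                matches.append(ReactionMatch(rid, mapped, CAT_IDENTIFIER))
                assigned_ref.add(mapped)
            else:
                matches.append(ReactionMatch(rid, None, CAT_NONE))
    elif method == "by_equation":
        met_map = build_met_map(draft, ref, table)
        translated = {
            rid: translate_stoichiometry(r, met_map)
            for rid, r in draft_rxns.items()
        }
        exact_index: dict[tuple, list[str]] = {}
        stripped_index: dict[tuple, list[str]] = {}
        for rid in sorted(ref_rxns):
            s = ref_rxns[rid].stoichiometry
            exact_index.setdefault(_stoich_key(s), []).append(rid)
            stripped = _strip_protons(s, proton_cores)
            if stripped:
                stripped_index.setdefault(_stoich_key(stripped), []).append(rid)

        assignment: dict[str, tuple[str, str]] = {}

        def try_pass(category: str) -> None:
            for rid in sorted(draft_rxns):
                if rid in assignment:
                    continue
                s = translated[rid]
                if s is None:
                    continue
                candidates: list[str] = []
                if category == CAT_EXACT:
                    candidates = exact_index.get(_stoich_key(s), [])
                elif category == CAT_REVERSED:
                    neg = {m: -c for m, c in s.items()}
                    candidates = exact_index.get(_stoich_key(neg), [])
                elif category == CAT_PROTON:
                    stripped = _strip_protons(s, proton_cores)
                    if not stripped:
                        continue
                    neg = {m: -c for m, c in stripped.items()}
                    candidates = sorted(
                        set(stripped_index.get(_stoich_key(stripped), []))
                        | set(stripped_index.get(_stoich_key(neg), []))
                    )
                for ref_id in candidates:
                    if ref_id in assigned_ref:
                        continue
                    # a candidate from the stripped index must not be an
                    # exact/reversed match (those were claimed earlier) but
                    # must genuinely differ only in protons
                    if category == CAT_PROTON:
                        if match_equations(
                            s, ref_rxns[ref_id].stoichiometry, proton_cores
                        ) != CAT_PROTON:
                            continue
                    assignment[rid] = (ref_id, category)
                    assigned_ref.add(ref_id)
                    break

        try_pass(CAT_EXACT)
        try_pass(CAT_REVERSED)
        try_pass(CAT_PROTON)
        for rid in sorted(draft_rxns):
            if rid in assignment:
                ref_id, category = assignment[rid]
                matches.append(ReactionMatch(rid, ref_id, category))
            else:
                matches.append(ReactionMatch(rid, None, CAT_NONE))
    else:
        raise ValueError(f"unknown comparison method {method!r}")

    strict = {CAT_IDENTIFIER, CAT_EXACT, CAT_REVERSED}
    covered = {m.ref_id for m in matches if m.category in strict}
    proton_matched_ref = {m.ref_id for m in matches if m.category == CAT_PROTON}
    additional = {m.draft_id for m in matches if m.category == CAT_NONE}
    missed = set(ref_rxns) - covered - proton_matched_ref

    denominator_excluded = {
        rid for rid, r in ref_rxns.items() if r.rclass == ReactionClass.BIOMASS
    }
    n_denom = len(ref_rxns) - len(denominator_excluded)

    rep = ComparisonReport(
        kind="reactions",
        n_draft=len(draft_rxns),
        n_ref=len(ref_rxns),
        n_ref_denominator=n_denom,
        covered=covered,
        additional=additional,
        missed=missed,
        n_proton_partial=len(proton_matched_ref),
        matches=matches,
    )
    if not ref_rxns:
        rep.warnings.append("empty reference reaction set: metrics undefined")
        return rep
    n_inter = len(covered)
    if n_denom > 0:
        rep.coverage_pct = 100.0 * len(covered - denominator_excluded) / n_denom
        rep.additional_pct = 100.0 * len(additional) / n_denom
    union = len(draft_rxns) + len(ref_rxns) - n_inter
    rep.jd = 1.0 - n_inter / union if union else math.nan
    n_diff = len(draft_rxns) - n_inter
    rep.r = (
        n_inter / n_diff if n_diff > 0 else (math.inf if n_inter else math.nan)
    )
    return rep
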