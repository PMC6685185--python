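"""Semi-automatic discovery of metabolite synonyms from near-matching equations.

Cross-reference tables are never complete: a draft reaction may fail to
match its reference counterpart only because one metabolite identifier has
no known translation.  This module inspects unmatched draft/reference
reaction pairs whose translated equations agree everywhere except in at
most ``max_unmatched`` metabolite positions (with equal stoichiometric
coefficients and compartments at the mismatched positions, protons
stripped first) and proposes the mismatched core-id pairs as synonym
candidates.  Candidates supported by at least two independent reaction
pairs and free of competing partners are auto-accepted into the mapping
table with provenance ``discovered``; the rest are emitted for human
review.  Iterating accept-and-repropose reaches a fixed point, because
each round either accepts a new synonym (strictly growing the table) or
stops.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from .core import MetabolicNetwork
from .model_io import split_compartment
from .namespace_map import MappingTable, ROUTE_DISCOVERED
from .network_compare import (
    CAT_NONE,
    PROTON_CORE_IDS,
    _close,
    _strip_protons,
    compare_reaction_sets,
)

__all__ = ["SynonymCandidate", "propose_synonyms", "discover_synonyms"]

AUTO_ACCEPT_SUPPORT = 2


@dataclass
class SynonymCandidate:
    draft_core: str
    ref_core: str
    support: int
    conflicts: int
    anchored: bool = True  # at least one witness pair shares a position
    status: str = "proposed"  # proposed | accepted | rejected

    @property
    def auto_acceptable(self) -> bool:
        return (
            self.support >= AUTO_ACCEPT_SUPPORT
            and self.anchored
            and self.conflicts == 0
        )


def _partial_translate(
    stoich: dict[str, float], met_map: dict[str, str | None]
) -> dict[str, float]:
    """Translate what can be translated; untranslated ids pass through."""
    out: dict[str, float] = {}
    for met, coeff in stoich.items():
        target = met_map.get(met) or met
        out[target] = out.get(target, 0.0) + coeff
    return {m: c for m, c in out.items() if c != 0.0}


def _mismatch_core_pairs(
    d: dict[str, float],
    r: dict[str, float],
    max_unmatched: int,
) -> tuple[list[tuple[str, str]], bool] | None:
    """Pair up the metabolite positions where two equations disagree.

    The equations must agree on every shared position; the leftover
    positions must pair one-to-one with equal coefficients and identical
    compartments, and the pairing must be unambiguous (a position with two
    possible partners rejects the whole pair).  Position pairs are then
    collapsed to (draft_core, ref_core) pairs — the same unknown core seen
    in two compartments (a transporter) is one mismatched metabolite, not
    two — and at most ``max_unmatched`` distinct core pairs are allowed.
    Returns ``(core_pairs, anchored)`` where ``anchored`` records whether
    the pair of equations shares at least one agreeing metabolite position
    (an anchor: evidence beyond a bare coefficient pattern), or None when
    no consistent pairing exists.
    """
    shared = d.keys() & r.keys()
    for met in shared:
        if not _close(d[met], r[met]):
            return None
    left_d = sorted(m for m in d if m not in shared)
    left_r = sorted(m for m in r if m not in shared)
    if len(left_d) != len(left_r) or not left_d:
        return None
    core_pairs: dict[str, str] = {}
    used_r: set[str] = set()
    for dm in left_d:
        d_core, d_comp = split_compartment(dm)
        cands = [
            rm for rm in left_r
            if rm not in used_r
            and split_compartment(rm)[1] == d_comp
            and _close(d[dm], r[rm])
        ]
        if len(cands) != 1:
            return None
        rm = cands[0]
        used_r.add(rm)
        r_core, _ = split_compartment(rm)
        if core_pairs.get(d_core, r_core) != r_core:
            return None  # inconsistent: one draft core, two ref partners
        core_pairs[d_core] = r_core
    pairs = [(dc, rc) for dc, rc in sorted(core_pairs.items()) if dc != rc]
    if not pairs or len(core_pairs) > max_unmatched:
        return None
    return pairs, bool(shared)


def propose_synonyms(
    draft: MetabolicNetwork,
    ref: MetabolicNetwork,
    table: MappingTable,
    max_unmatched: int = 1,
    proton_cores: frozenset[str] = PROTON_CORE_IDS,
) -> list[SynonymCandidate]:
    """Propose metabolite synonym candidates from unmatched reaction pairs."""
    from .network_compare import build_met_map

    report = compare_reaction_sets(
        draft, ref, table, method="by_equation", proton_cores=proton_cores
    )
    unmatched_draft = sorted(
        m.draft_id for m in report.matches if m.category == CAT_NONE
    )
    unmatched_ref = sorted(report.missed)
    met_map = build_met_map(draft, ref, table)

    proposals: dict[tuple[str, str], set[tuple[str, str]]] = {}
    ref_stripped = {
        rid: _strip_protons(ref.reactions[rid].stoichiometry, proton_cores)
        for rid in unmatched_ref
        if rid in ref.reactions
    }
    for d_rid in unmatched_draft:
        if d_rid not in draft.reactions:
            continue
        d_raw = _partial_translate(draft.reactions[d_rid].stoichiometry, met_map)
        d_stoich = _strip_protons(d_raw, proton_cores)
        if not d_stoich:
            continue
        d_neg = {m: -c for m, c in d_stoich.items()}
        d_sizes = len(d_stoich)
        for r_rid, r_stoich in ref_stripped.items():
            if not r_stoich or len(r_stoich) != d_sizes:
                continue
            hit = _mismatch_core_pairs(d_stoich, r_stoich, max_unmatched)
            if hit is None:
                hit = _mismatch_core_pairs(d_neg, r_stoich, max_unmatched)
            if hit is None:
                continue
            pairs, anchored = hit
            for d_core, r_core in pairs:
                proposals.setdefault((d_core, r_core), set()).add(
                    (d_rid, r_rid, anchored)
                )

    # A credible candidate needs enough total support to be auto-acceptable
    # AND at least one anchored witness: bare coefficient patterns (a lone
    # exchange, a generic transporter) are interchangeable between unrelated
    # species and carry no identifying evidence on their own.  Conflicts are
    # counted among credible candidates only, so a one-off spurious pairing
    # cannot block a well-supported synonym.
    credible = {
        pair for pair, wit in proposals.items()
        if len(wit) >= AUTO_ACCEPT_SUPPORT
        and any(anchored for _, _, anchored in wit)
    }
    by_draft: dict[str, set[str]] = {}
    by_ref: dict[str, set[str]] = {}
    for d_core, r_core in credible:
        by_draft.setdefault(d_core, set()).add(r_core)
        by_ref.setdefault(r_core, set()).add(d_core)

    candidates = []
    for (d_core, r_core), witnesses in sorted(proposals.items()):
        conflicts = len(by_draft.get(d_core, set()) - {r_core}) + len(
            by_ref.get(r_core, set()) - {d_core}
        )
        candidates.append(
            SynonymCandidate(
                draft_core=d_core,
                ref_core=r_core,
                support=len(witnesses),
                conflicts=conflicts,
                anchored=any(anchored for _, _, anchored in witnesses),
            )
        )
    return candidates


def discover_synonyms(
    draft: MetabolicNetwork,
    ref: MetabolicNetwork,
    table: MappingTable,
    max_unmatched: int = 1,
    max_rounds: int = 20,
    proton_cores: frozenset[str] = PROTON_CORE_IDS,
) -> tuple[list[SynonymCandidate], list[SynonymCandidate]]:
    """Iterate propose -> auto-accept until fixed point.

    Auto-accepted candidates are appended to ``table`` with provenance
    ``discovered``.  Returns (accepted, remaining-for-review).
    """
    accepted: list[SynonymCandidate] = []
    remaining: list[SynonymCandidate] = []
    for _ in range(max_rounds):
        candidates = propose_synonyms(
            draft, ref, table, max_unmatched, proton_cores
        )
        new = [c for c in candidates if c.auto_acceptable]
        remaining = [c for c in candidates if not c.auto_acceptable]
        if not new:
            break
        for c in new:
            c.status = "accepted"
            table.add_metabolite_synonym(
                c.draft_core, c.ref_core, ROUTE_DISCOVERED
            )
            accepted.append(c)
    return accepted, remaining


def write_candidates(
    candidates: list[SynonymCandidate], path: str | Path
) -> None:
    """Write a review TSV: draft id, ref id, support, conflicts, status."""
    lines = ["# draft_core\tref_core\tsupport\tconflicts\tstatus"]
    for c in candidates:
        lines.append(
            f"{c.draft_core}\t{c.ref_core}\t{c.support}\t{c.conflicts}\t{c.status}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
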