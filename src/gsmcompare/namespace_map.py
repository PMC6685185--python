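"""Cross-namespace identifier translation.

Draft reconstructions built from different databases (KEGG-, MetaCyc- or
SEED-style namespaces) label the same metabolite or reaction with different
identifiers.  A :class:`MappingTable` holds synonym sets loaded from
cross-reference TSV files (MetaNetX-style) layered with a custom dictionary;
lookups are case-sensitive and membership in the reference network decides
whether a candidate translation counts as a match.

TSV layout (tab-separated, ``#`` comments)::

    source_id<TAB>target_id<TAB>provenance

Provenance is free text (e.g. ``cross-reference``, ``custom``,
``discovered``); rows missing it default to ``cross-reference``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .core import MetabolicNetwork
from .model_io import split_compartment

__all__ = ["MappingTable", "MetaboliteMatch", "load_mapping"]

ROUTE_IDENTITY = "identity"
ROUTE_XREF = "cross-reference"
ROUTE_CUSTOM = "custom"
ROUTE_DISCOVERED = "discovered"


@dataclass
class MetaboliteMatch:
    source: str
    target: str | None
    route: str | None
    multiple: bool = False  # more than one synonym was a reference member


@dataclass
class MappingTable:
    """Synonym sets for metabolite core ids and reaction ids."""

    metabolite_syn: dict[str, set[str]] = field(default_factory=dict)
    reaction_syn: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str, str], str] = field(default_factory=dict)
    load_log: list[str] = field(default_factory=list)

    def add_metabolite_synonym(
        self, source: str, target: str, provenance: str = ROUTE_XREF
    ) -> None:
        self.metabolite_syn.setdefault(source, set()).add(target)
        self.provenance[("met", source, target)] = provenance

    def add_reaction_synonym(
        self, source: str, target: str, provenance: str = ROUTE_XREF
    ) -> None:
        self.reaction_syn.setdefault(source, set()).add(target)
        self.provenance[("rxn", source, target)] = provenance

    def metabolite_synonyms(self, core_id: str) -> frozenset[str]:
        return frozenset(self.metabolite_syn.get(core_id, ()))

    def reaction_synonyms(self, rid: str) -> frozenset[str]:
        return frozenset(self.reaction_syn.get(rid, ()))

    def n_entries(self) -> tuple[int, int]:
        return (
            sum(len(v) for v in self.metabolite_syn.values()),
            sum(len(v) for v in self.reaction_syn.values()),
        )

    # ------------------------------------------------------------------ I/O
    def _load_file(self, path: str | Path, kind: str) -> None:
        path = Path(path)
        n_rows = 0
        text = path.read_text()
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                self.load_log.append(
                    f"{path.name}:{lineno}: malformed row skipped"
                )
                continue
            source = parts[0].strip()
            target = parts[1].strip()
            prov = parts[2].strip() if len(parts) > 2 and parts[2].strip() else ROUTE_XREF
            # tolerate a "namespace:id" source prefix
            if ":" in source:
                source = source.split(":", 1)[1]
            if kind == "met":
                self.add_metabolite_synonym(source, target, prov)
            else:
                self.add_reaction_synonym(source, target, prov)
            n_rows += 1
        if n_rows == 0:
            self.load_log.append(f"{path.name}: no usable rows (empty table)")

    @classmethod
    def load(
        cls,
        metabolite_files: Iterable[str | Path] = (),
        reaction_files: Iterable[str | Path] = (),
    ) -> "MappingTable":
        table = cls()
        for p in metabolite_files:
            table._load_file(p, "met")
        for p in reaction_files:
            table._load_file(p, "rxn")
        return table

    def write(self, metabolite_path: str | Path | None = None,
              reaction_path: str | Path | None = None) -> None:
        if metabolite_path is not None:
            lines = ["# source\ttarget\tprovenance"]
            for src in sorted(self.metabolite_syn):
                for tgt in sorted(self.metabolite_syn[src]):
                    prov = self.provenance.get(("met", src, tgt), ROUTE_XREF)
                    lines.append(f"{src}\t{tgt}\t{prov}")
            Path(metabolite_path).write_text("\n".join(lines) + "\n")
        if reaction_path is not None:
            lines = ["# source\ttarget\tprovenance"]
            for src in sorted(self.reaction_syn):
                for tgt in sorted(self.reaction_syn[src]):
                    prov = self.provenance.get(("rxn", src, tgt), ROUTE_XREF)
                    lines.append(f"{src}\t{tgt}\t{prov}")
            Path(reaction_path).write_text("\n".join(lines) + "\n")


def load_mapping(
    metabolite_files: Iterable[str | Path] = (),
    reaction_files: Iterable[str | Path] = (),
) -> MappingTable:
    """Load one or more synonym TSV files into a MappingTable."""
    return MappingTable.load(metabolite_files, reaction_files)


def map_metabolite(
    full_id: str, table: MappingTable, ref: MetabolicNetwork
) -> MetaboliteMatch:
    """Translate a compartmented metabolite id into the reference namespace.

    The compartment character is stripped, synonyms of the core id looked
    up, each synonym re-concatenated with the original compartment token and
    membership-checked against the reference metabolite set.  The identity
    id is tried first; among multiple member synonyms the lexicographically
    smallest wins and the match is flagged.  Cross-compartment matches are
    never attempted.
    """
    if full_id in ref.metabolites:
        return MetaboliteMatch(full_id, full_id, ROUTE_IDENTITY)
    core, comp = split_compartment(full_id)
    hits = []
    for syn in sorted(table.metabolite_synonyms(core)):
        candidate = f"{syn}_{comp}"
        if candidate in ref.metabolites:
            prov = table.provenance.get(("met", core, syn), ROUTE_XREF)
            hits.append((candidate, prov))
    if not hits:
        return MetaboliteMatch(full_id, None, None)
    target, prov = hits[0]
    return MetaboliteMatch(full_id, target, prov, multiple=len(hits) > 1)


def map_reaction_id(
    rid: str, table: MappingTable, ref: MetabolicNetwork
) -> str | None:
    """Translate a reaction id into the reference namespace, or None.

    Identity first, then the synonym set in sorted order, membership-checked
    against the reference reaction ids (case-sensitive).
    """
    if rid in ref.reactions:
        return rid
    for syn in sorted(table.reaction_synonyms(rid)):
        if syn in ref.reactions:
            return syn
    return None
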