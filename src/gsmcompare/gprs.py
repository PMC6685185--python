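"""Boolean gene-reaction rules (GPRs).

A gene-reaction rule is a boolean expression over gene identifiers stating
which gene products enable a reaction, e.g. ``(g1 and g2) or g3``.  Rules are
stored as canonical AND/OR trees: nested same-operator nodes are flattened,
duplicate operands removed, and operands sorted, so that two rules describing
the same boolean function in a different written order compare equal and
OR-merges performed during reaction deduplication are order-independent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

__all__ = ["GeneRule", "gene", "and_", "or_", "parse_gpr", "EMPTY_RULE"]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


@dataclass(frozen=True)
class GeneRule:
    """Canonical node of a GPR tree.

    ``op`` is ``"gene"`` for a leaf (``name`` set), or ``"and"``/``"or"``
    with at least two children.  The empty rule (no gene requirement) is
    represented by ``EMPTY_RULE`` (op ``"empty"``).
    """

    op: str
    name: str = ""
    children: tuple["GeneRule", ...] = field(default=())

    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> frozenset[str]:
        if self.op == "empty":
            return frozenset()
        if self.op == "gene":
            return frozenset((self.name,))
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def _key(self) -> str:
        return self.to_string()

    def to_string(self) -> str:
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.name
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op in ("and", "or"):
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


EMPTY_RULE = GeneRule("empty")


def gene(name: str) -> GeneRule:
    return GeneRule("gene", name=name)


def _combine(op: str, operands: Iterator[GeneRule] | list[GeneRule]) -> GeneRule:
    """Build a canonical n-ary AND/OR node: flatten, dedupe, sort."""
    flat: list[GeneRule] = []
    for o in operands:
        if o.is_empty():
            continue
        if o.op == op:
            flat.extend(o.children)
        else:
            flat.append(o)
    uniq = {c._key(): c for c in flat}
    ordered = [uniq[k] for k in sorted(uniq)]
    if not ordered:
        return EMPTY_RULE
    if len(ordered) == 1:
        return ordered[0]
    return GeneRule(op, children=tuple(ordered))


def and_(*operands: GeneRule) -> GeneRule:
    return _combine("and", list(operands))


def or_(*operands: GeneRule) -> GeneRule:
    return _combine("or", list(operands))


class GPRSyntaxError(ValueError):
    pass


def parse_gpr(text: str) -> GeneRule:
    """Parse boolean GPR text into a canonical rule tree.

    Accepts ``and``/``or`` in any case (also ``AND``/``OR``), arbitrary
    parenthesisation, and bare gene identifiers.  Empty or whitespace-only
    text yields the empty rule.
    """
    tokens = _TOKEN_RE.findall(text or "")
    if not tokens:
        return EMPTY_RULE
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        t = tokens[pos]
        pos += 1
        return t

    def parse_or() -> GeneRule:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return or_(*terms)

    def parse_and() -> GeneRule:
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        return and_(*terms)

    def parse_atom() -> GeneRule:
        t = peek()
        if t is None:
            raise GPRSyntaxError("unexpected end of gene rule")
        if t == "(":
            take()
            inner = parse_or()
            if peek() != ")":
                raise GPRSyntaxError("unbalanced parenthesis in gene rule")
            take()
            return inner
        if t == ")":
            raise GPRSyntaxError("unexpected ')' in gene rule")
        if t.lower() in ("and", "or"):
            raise GPRSyntaxError(f"operator {t!r} without left operand")
        return gene(take())

    rule = parse_or()
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in gene rule: {tokens[pos:]}")
    return rule
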