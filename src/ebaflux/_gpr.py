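"""Gene-protein-reaction (GPR) boolean expressions.

A GPR is a boolean formula over gene identifiers built with ``and``, ``or``
and parentheses.  ``and`` groups subunits of a complex, ``or`` groups
isozymes.  The numeric evaluation used for flux-bound gating maps ``and`` to
``min`` and ``or`` to ``max`` over per-gene activity ratios (an ``or -> sum``
variant is available for pooled isozyme capacity).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping


class GPRSyntaxError(ValueError):
    """Raised when a GPR string does not conform to the and/or grammar."""


@dataclass(frozen=True)
class GPRNode:
    """Node of a parsed GPR tree.

    ``op`` is one of ``"and"``, ``"or"`` or ``"gene"``.  Leaves carry the
    gene id in ``gene``; internal nodes carry ``children``.
    """

    op: str
    gene: str | None = None
    children: tuple["GPRNode", ...] = field(default_factory=tuple)

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, values: Mapping[str, float], default: float = 1.0,
                 or_mode: str = "max") -> float:
        """Evaluate the tree over per-gene numeric values.

        AND -> min of children; OR -> ``max`` (default) or ``sum`` of
        children; a leaf returns its gene's value (``default`` if absent).
        """
        if self.op == "gene":
            return float(values.get(self.gene, default))  # type: ignore[arg-type]
        vals = [c.evaluate(values, default, or_mode) for c in self.children]
        if self.op == "and":
            return min(vals)
        if or_mode == "sum":
            return sum(vals)
        return max(vals)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            if c.op != "gene":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> GPRNode | None:
    """Parse a GPR string into a :class:`GPRNode` tree.

    Returns ``None`` for an empty/blank rule (reaction with no genes).
    ``or`` binds looser than ``and``; parentheses override.  Gene ids are
    any whitespace/paren-free tokens other than the (case-insensitive)
    keywords ``and`` / ``or``.
    """
    if text is None or not text.strip():
        return None
    tokens = _TOKEN_RE.findall(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRNode:
        parts = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            advance()
            parts.append(parse_and())
        if len(parts) == 1:
            return parts[0]
        return GPRNode("or", children=tuple(parts))

    def parse_and() -> GPRNode:
        parts = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            advance()
            parts.append(parse_atom())
        if len(parts) == 1:
            return parts[0]
        return GPRNode("and", children=tuple(parts))

    def parse_atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of GPR: {text!r}")
        if tok == "(":
            advance()
            node = parse_or()
            if peek() != ")":
                raise GPRSyntaxError(f"unbalanced parenthesis in GPR: {text!r}")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in GPR: {text!r}")
        advance()
        return GPRNode("gene", gene=tok)

    tree = parse_or()
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in GPR: {text!r}")
    return tree
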