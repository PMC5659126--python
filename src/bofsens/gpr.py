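"""Gene-protein-reaction (GPR) boolean rules.

A GPR expression links a reaction to the genes whose products catalyse it:
``AND`` joins subunits of a complex (all required), ``OR`` joins isoenzymes
(any suffices).  An empty expression means the reaction has no gene
association and is always considered catalytically active.

The text grammar follows the COBRA community convention: infix ``and`` /
``or`` (case-insensitive) with parentheses, ``and`` binding tighter than
``or``.  Gene identifiers are any run of characters other than whitespace
and parentheses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Tuple

__all__ = ["GPRExpression", "parse_gpr", "GPRParseError"]


class GPRParseError(ValueError):
    """Raised when a GPR string does not conform to the grammar."""


@dataclass(frozen=True)
class GPRExpression:
    """Boolean tree over gene identifiers.

    ``kind`` is one of ``"empty"``, ``"gene"``, ``"and"``, ``"or"``.
    Leaves carry ``gene``; internal nodes carry ``children`` (>= 2).
    """

    kind: str = "empty"
    gene: str | None = None
    children: Tuple["GPRExpression", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind not in ("empty", "gene", "and", "or"):
            raise ValueError(f"unknown GPR node kind: {self.kind!r}")
        if self.kind == "gene" and not self.gene:
            raise ValueError("gene leaf requires a gene id")
        if self.kind in ("and", "or") and len(self.children) < 2:
            raise ValueError(f"{self.kind!r} node requires >= 2 children")

    @property
    def is_empty(self) -> bool:
        return self.kind == "empty"

    def genes(self) -> FrozenSet[str]:
        """All gene ids appearing in the tree."""
        if self.kind == "gene":
            return frozenset((self.gene,))
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)

    def is_active(self, deleted: Iterable[str] = ()) -> bool:
        """Evaluate the rule with the given genes knocked out.

        AND is active iff all children are; OR iff any child is; a leaf
        iff its gene is not deleted; the empty rule is always active.
        """
        deleted = frozenset(deleted)
        return self._eval(deleted)

    def _eval(self, deleted: frozenset) -> bool:
        if self.kind == "empty":
            return True
        if self.kind == "gene":
            return self.gene not in deleted
        if self.kind == "and":
            return all(c._eval(deleted) for c in self.children)
        return any(c._eval(deleted) for c in self.children)

    def to_string(self) -> str:
        if self.kind == "empty":
            return ""
        if self.kind == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.kind} "
        parts = []
        for child in self.children:
            text = child.to_string()
            # parenthesise an 'or' under an 'and' to preserve precedence
            if self.kind == "and" and child.kind == "or":
                text = f"({text})"
            parts.append(text)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


EMPTY_GPR = GPRExpression()


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append(ch)
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            tokens.append(text[i:j])
            i = j
    return tokens


def parse_gpr(text: str | None) -> GPRExpression:
    """Parse a GPR rule string into a boolean tree.

    ``None``, the empty string, and bare whitespace all give the empty
    (always-active) expression.
    """
    if text is None or not text.strip():
        return EMPTY_GPR
    tokens = _tokenize(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRExpression:
        children = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            advance()
            children.append(parse_and())
        if len(children) == 1:
            return children[0]
        return GPRExpression(kind="or", children=tuple(children))

    def parse_and() -> GPRExpression:
        children = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            advance()
            children.append(parse_atom())
        if len(children) == 1:
            return children[0]
        return GPRExpression(kind="and", children=tuple(children))

    def parse_atom() -> GPRExpression:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR rule: {text!r}")
        if tok == "(":
            advance()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parenthesis in {text!r}")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRParseError(f"unexpected token {tok!r} in {text!r}")
        advance()
        return GPRExpression(kind="gene", gene=tok)

    expr = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens after GPR rule: {text!r}")
    return expr
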