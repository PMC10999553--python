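"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule links a reaction to the genes whose products catalyse it:
``and`` joins subunits of a complex (all required), ``or`` joins isozymes
(any suffices). Rules are parsed into an explicit expression tree so the
same object can drive gene-deletion screens (boolean evaluation) and
expression mapping (min/sum aggregation) without re-parsing text.

Grammar (case-insensitive keywords, ``and`` binds tighter than ``or``)::

    expr    := term ("or" term)*
    term    := factor ("and" factor)*
    factor  := GENE | "(" expr ")"
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "GPRExpression",
    "GPRLeaf",
    "GPRNode",
    "GPRParseError",
    "parse_gpr",
    "evaluate_gpr",
]


class GPRParseError(ValueError):
    """Malformed GPR text; carries the character position of the defect."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class GPRLeaf:
    gene: str

    def genes(self) -> frozenset[str]:
        return frozenset({self.gene})

    def evaluate(self, deleted: frozenset[str] | set[str]) -> bool:
        return self.gene not in deleted

    def to_string(self) -> str:
        return self.gene


@dataclass(frozen=True)
class GPRNode:
    op: str  # "and" | "or"
    children: tuple = ()

    def genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for child in self.children:
            out |= child.genes()
        return out

    def evaluate(self, deleted: frozenset[str] | set[str]) -> bool:
        if self.op == "and":
            return all(c.evaluate(deleted) for c in self.children)
        return any(c.evaluate(deleted) for c in self.children)

    def to_string(self) -> str:
        parts = []
        for child in self.children:
            text = child.to_string()
            # parenthesise a looser-binding OR nested under AND
            if self.op == "and" and isinstance(child, GPRNode) and child.op == "or":
                text = f"({text})"
            parts.append(text)
        return f" {self.op} ".join(parts)


@dataclass(frozen=True)
class GPRExpression:
    """Boolean tree over gene ids; ``root is None`` means no gene association."""

    root: GPRLeaf | GPRNode | None = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset[str]:
        return frozenset() if self.root is None else self.root.genes()

    def evaluate(self, deleted: Iterable[str] = ()) -> bool:
        """True iff the reaction stays catalysed after deleting ``deleted``.

        An empty rule has no gene dependency and always evaluates True.
        """
        if self.root is None:
            return True
        return self.root.evaluate(frozenset(deleted))

    def to_string(self) -> str:
        return "" if self.root is None else self.root.to_string()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


# ---------------------------------------------------------------------------
# Tokeniser / recursive-descent parser
# ---------------------------------------------------------------------------

_KEYWORDS = {"and", "or"}


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            yield ("paren", ch, i)
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in _KEYWORDS:
            yield ("op", low, i)
        elif low == "&&" or word == "&":
            yield ("op", "and", i)
        elif low == "||" or word == "|":
            yield ("op", "or", i)
        else:
            yield ("gene", word, i)
        i = j


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is not None:
            self.pos += 1
        return tok

    def parse(self) -> GPRLeaf | GPRNode:
        node = self.expr()
        tok = self.peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def expr(self):
        terms = [self.term()]
        while True:
            tok = self.peek()
            if tok and tok[0] == "op" and tok[1] == "or":
                self.next()
                terms.append(self.term())
            else:
                break
        if len(terms) == 1:
            return terms[0]
        return GPRNode("or", tuple(terms))

    def term(self):
        factors = [self.factor()]
        while True:
            tok = self.peek()
            if tok and tok[0] == "op" and tok[1] == "and":
                self.next()
                factors.append(self.factor())
            else:
                break
        if len(factors) == 1:
            return factors[0]
        return GPRNode("and", tuple(factors))

    def factor(self):
        tok = self.next()
        if tok is None:
            raise GPRParseError("dangling operator: expected gene or '('", len(self.text))
        kind, value, pos = tok
        if kind == "gene":
            return GPRLeaf(value)
        if kind == "paren" and value == "(":
            node = self.expr()
            closing = self.next()
            if closing is None or closing[1] != ")":
                raise GPRParseError("unbalanced parentheses: missing ')'", pos)
            return node
        raise GPRParseError(f"unexpected token {value!r}", pos)


def parse_gpr(text: str) -> GPRExpression:
    """Parse a GPR rule string into an expression tree.

    ``and`` binds tighter than ``or`` (so ``g1 or g2 and g3`` reads as
    ``g1 or (g2 and g3)``); keywords are case-insensitive; an empty or
    all-whitespace string yields the empty expression.

    Raises
    ------
    GPRParseError
        On unbalanced parentheses or dangling operators, naming the
        character position.
    """
    if text is None or not text.strip():
        return GPRExpression(None)
    return GPRExpression(_Parser(text).parse())


def evaluate_gpr(gpr: GPRExpression, deleted: Iterable[str] = ()) -> bool:
    """Is the reaction still active after deleting the given genes?"""
    return gpr.evaluate(deleted)
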