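"""Boolean gene-protein-reaction (GPR) rules.

A GPR rule is a boolean expression over gene identifiers in which AND
encodes an enzyme complex (all subunits required) and OR encodes
isozymes (any one gene product suffices).  Rules are stored as small
expression trees (:class:`GeneRef`, :class:`And`, :class:`Or`) so that
structure survives serialisation round trips and can be rewritten during
template-based reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Tuple


class GPRSyntaxError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class GPRNode:
    """Base class for GPR expression-tree nodes."""

    def genes(self) -> FrozenSet[str]:
        raise NotImplementedError

    def evaluate(self, present: Iterable[str]) -> bool:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError


@dataclass(frozen=True)
class GeneRef(GPRNode):
    gene: str

    def genes(self) -> FrozenSet[str]:
        return frozenset({self.gene})

    def evaluate(self, present) -> bool:
        return self.gene in set(present)

    def to_string(self) -> str:
        return self.gene


@dataclass(frozen=True)
class And(GPRNode):
    children: Tuple[GPRNode, ...]

    def __post_init__(self):
        if not self.children:
            raise GPRSyntaxError("empty AND node")

    def genes(self) -> FrozenSet[str]:
        return frozenset().union(*(c.genes() for c in self.children))

    def evaluate(self, present) -> bool:
        present = set(present)
        return all(c.evaluate(present) for c in self.children)

    def to_string(self) -> str:
        return " and ".join(
            f"({c.to_string()})" if isinstance(c, Or) else c.to_string()
            for c in self.children
        )


@dataclass(frozen=True)
class Or(GPRNode):
    children: Tuple[GPRNode, ...]

    def __post_init__(self):
        if not self.children:
            raise GPRSyntaxError("empty OR node")

    def genes(self) -> FrozenSet[str]:
        return frozenset().union(*(c.genes() for c in self.children))

    def evaluate(self, present) -> bool:
        present = set(present)
        return any(c.evaluate(present) for c in self.children)

    def to_string(self) -> str:
        return " or ".join(c.to_string() for c in self.children)


def _tokenize(text: str):
    tokens = []
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


def parse_gpr(text: str) -> GPRNode:
    """Parse a GPR string like ``"(g1 and g2) or g3"`` into a tree.

    ``and``/``or`` (case-insensitive, also ``&&``/``||``) are the only
    operators; ``and`` binds tighter than ``or``.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise GPRSyntaxError("empty GPR string")
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def is_op(tok, name):
        return tok is not None and (
            tok.lower() == name or tok == {"and": "&&", "or": "||"}[name]
        )

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while is_op(peek(), "or"):
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and():
        nonlocal pos
        factors = [parse_atom()]
        while is_op(peek(), "and"):
            pos += 1
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_atom():
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GPRSyntaxError("unexpected end of GPR expression")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise GPRSyntaxError("unbalanced parenthesis in GPR")
            pos += 1
            return node
        if tok == ")" or is_op(tok, "and") or is_op(tok, "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in GPR")
        pos += 1
        return GeneRef(tok)

    node = parse_or()
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in GPR near {tokens[pos]!r}")
    return node


def simplify(node: GPRNode) -> GPRNode:
    """Flatten nested same-type nodes, drop duplicate children, collapse
    single-child AND/OR nodes."""
    if isinstance(node, GeneRef):
        return node
    kind = type(node)
    flat = []
    for child in node.children:
        child = simplify(child)
        if isinstance(child, kind):
            flat.extend(child.children)
        else:
            flat.append(child)
    seen, unique = set(), []
    for child in flat:
        if child not in seen:
            seen.add(child)
            unique.append(child)
    if len(unique) == 1:
        return unique[0]
    return kind(tuple(unique))


def gpr_equal(a: GPRNode | None, b: GPRNode | None) -> bool:
    """Structural equality up to child order and simplification."""
    if a is None or b is None:
        return a is b

    def canon(n: GPRNode):
        n = simplify(n)

        def key(m):
            if isinstance(m, GeneRef):
                return ("g", m.gene)
            tag = "and" if isinstance(m, And) else "or"
            return (tag, tuple(sorted(key(c) for c in m.children)))

        return key(n)

    return canon(a) == canon(b)
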