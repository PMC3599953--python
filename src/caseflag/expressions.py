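"""Boolean flag expressions: the rows of the validity tables.

A flag combination such as ``(lumpectomy OR mastectomy) AND diagnosis`` is
represented as a small AND/OR tree over named flags and parsed from the
string form used in configuration files.  Grammar::

    expr   := term (OR term)*
    term   := factor (AND factor)*
    factor := IDENT | '(' expr ')'

AND binds tighter than OR; keywords are case-insensitive.  Identifiers are
``[A-Za-z_][A-Za-z0-9_]*``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Union

FlagExpression = Union["Leaf", "And", "Or"]


@dataclass(frozen=True)
class Leaf:
    flag_name: str


@dataclass(frozen=True)
class And:
    children: tuple[FlagExpression, ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ExpressionError("AND over an empty child set is not allowed")


@dataclass(frozen=True)
class Or:
    children: tuple[FlagExpression, ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise ExpressionError("OR over an empty child set is not allowed")


class ExpressionError(ValueError):
    """Syntax error or reference to an unknown flag."""


def leaves(expr: FlagExpression) -> set[str]:
    """Names of every flag referenced in the expression."""
    if isinstance(expr, Leaf):
        return {expr.flag_name}
    out: set[str] = set()
    for child in expr.children:
        out |= leaves(child)
    return out


def evaluate_expression(expr: FlagExpression, flags_present: Iterable[str] | Mapping[str, bool],
                        known_flags: Iterable[str] | None = None) -> bool:
    """Evaluate the expression over per-flag boolean indicators.

    ``flags_present`` is either the set of flag names that are true, or a
    mapping flag name -> bool.  If ``known_flags`` is given, every leaf must
    be a member, otherwise any leaf name is accepted.
    """
    if isinstance(flags_present, Mapping):
        present = {name for name, val in flags_present.items() if val}
        known = set(flags_present) if known_flags is None else set(known_flags)
    else:
        present = set(flags_present)
        known = None if known_flags is None else set(known_flags)

    if known is not None:
        unknown = leaves(expr) - known
        if unknown:
            raise ExpressionError(f"unknown flag in expression: {sorted(unknown)}")

    def rec(node: FlagExpression) -> bool:
        if isinstance(node, Leaf):
            return node.flag_name in present
        if isinstance(node, And):
            return all(rec(c) for c in node.children)
        return any(rec(c) for c in node.children)

    return rec(expr)


_TOKEN_RE = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<ident>[A-Za-z_][A-Za-z0-9_]*))")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None or match.end() == match.start():
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ExpressionError(f"syntax error at position {pos}: unexpected {text[pos]!r}")
        pos = match.end()
        if match.group("lpar"):
            tokens.append(("lpar", "(", match.start()))
        elif match.group("rpar"):
            tokens.append(("rpar", ")", match.start()))
        else:
            word = match.group("ident")
            upper = word.upper()
            if upper in ("AND", "OR"):
                tokens.append((upper.lower(), upper, match.start()))
            else:
                tokens.append(("ident", word, match.start()))
    return tokens


def parse_expression(text: str) -> FlagExpression:
    """Parse an expression string into a :class:`FlagExpression` tree."""
    tokens = _tokenize(text)
    if not tokens:
        raise ExpressionError("empty expression")
    pos = 0

    def peek() -> str | None:
        return tokens[pos][0] if pos < len(tokens) else None

    def expr() -> FlagExpression:
        nonlocal pos
        terms = [term()]
        while peek() == "or":
            pos += 1
            terms.append(term())
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def term() -> FlagExpression:
        nonlocal pos
        factors = [factor()]
        while peek() == "and":
            pos += 1
            factors.append(factor())
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def factor() -> FlagExpression:
        nonlocal pos
        if pos >= len(tokens):
            raise ExpressionError(f"syntax error at position {len(text)}: unexpected end of expression")
        kind, value, where = tokens[pos]
        if kind == "ident":
            pos += 1
            return Leaf(value)
        if kind == "lpar":
            pos += 1
            inner = expr()
            if peek() != "rpar":
                raise ExpressionError(f"syntax error: unclosed parenthesis opened at position {where}")
            pos += 1
            return inner
        raise ExpressionError(f"syntax error at position {where}: unexpected {value!r}")

    tree = expr()
    if pos != len(tokens):
        kind, value, where = tokens[pos]
        raise ExpressionError(f"syntax error at position {where}: unexpected {value!r}")
    return tree


def to_string(expr: FlagExpression) -> str:
    """Render a tree back to the canonical (fully parenthesized) string form."""
    if isinstance(expr, Leaf):
        return expr.flag_name
    joiner = " AND " if isinstance(expr, And) else " OR "
    parts = []
    for child in expr.children:
        text = to_string(child)
        if not isinstance(child, Leaf):
            text = f"({text})"
        parts.append(text)
    return joiner.join(parts)


def satisfying_leaves(expr: FlagExpression) -> set[str]:
    """A minimal-ish set of flags whose presence makes the expression true.

    Chooses every child of an AND and the first child of an OR.  Used by the
    synthetic generator to emit a compound event process for a combination
    row.
    """
    if isinstance(expr, Leaf):
        return {expr.flag_name}
    if isinstance(expr, And):
        out: set[str] = set()
        for child in expr.children:
            out |= satisfying_leaves(child)
        return out
    return satisfying_leaves(expr.children[0])
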