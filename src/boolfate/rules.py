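"""Boolean rule expressions.

Rules are written in the conventional logic-model syntax used by tools such as
BoolNet and CellNOptR: node names combined with ``&`` (AND), ``|`` (OR),
``!`` (NOT), parentheses, and the constants ``0``/``1``.  A parsed rule is an
immutable expression tree that can be evaluated on a single state (a mapping
node -> 0/1) or, for batch simulation, compiled once into a vectorized numpy
function operating on a ``(n_states, n_nodes)`` uint8 matrix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

__all__ = ["Rule", "RuleSyntaxError", "parse_rule"]


class RuleSyntaxError(ValueError):
    """Raised when a rule expression cannot be parsed."""


_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_./-]*)"
                       r"|(?P<const>[01])"
                       r"|(?P<op>[&|!()]))")

# expression tree: ("var", name) | ("const", 0/1) | ("not", t) |
#                  ("and", [t...]) | ("or", [t...])


def _tokenize(text: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise RuleSyntaxError(f"bad token at {text[pos:]!r} in rule {text!r}")
        tokens.append(m.group(m.lastgroup))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], source: str):
        self.tokens = tokens
        self.pos = 0
        self.source = source

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError(f"unexpected end of rule {self.source!r}")
        self.pos += 1
        return tok

    def parse(self):
        tree = self.parse_or()
        if self.peek() is not None:
            raise RuleSyntaxError(
                f"trailing tokens {self.tokens[self.pos:]} in rule {self.source!r}")
        return tree

    def parse_or(self):
        terms = [self.parse_and()]
        while self.peek() == "|":
            self.take()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and(self):
        terms = [self.parse_unary()]
        while self.peek() == "&":
            self.take()
            terms.append(self.parse_unary())
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_unary(self):
        tok = self.take()
        if tok == "!":
            return ("not", self.parse_unary())
        if tok == "(":
            inner = self.parse_or()
            if self.take() != ")":
                raise RuleSyntaxError(f"unbalanced parentheses in {self.source!r}")
            return inner
        if tok in ("0", "1"):
            return ("const", int(tok))
        if tok in ("&", "|", ")"):
            raise RuleSyntaxError(f"misplaced {tok!r} in rule {self.source!r}")
        return ("var", tok)


def _walk_vars(tree, negated: bool, acc: dict[str, set[int]]):
    kind = tree[0]
    if kind == "var":
        acc.setdefault(tree[1], set()).add(-1 if negated else +1)
    elif kind == "not":
        _walk_vars(tree[1], not negated, acc)
    elif kind in ("and", "or"):
        for t in tree[1]:
            _walk_vars(t, negated, acc)


def _emit(tree, ref: Callable[[str], str]) -> str:
    kind = tree[0]
    if kind == "var":
        return ref(tree[1])
    if kind == "const":
        return str(tree[1])
    if kind == "not":
        return f"(1 ^ {_emit(tree[1], ref)})"
    joiner = " & " if kind == "and" else " | "
    return "(" + joiner.join(_emit(t, ref) for t in tree[1]) + ")"


def _to_string(tree, parent: str | None = None) -> str:
    kind = tree[0]
    if kind == "var":
        return tree[1]
    if kind == "const":
        return str(tree[1])
    if kind == "not":
        return "!" + _to_string(tree[1], "not")
    op = "&" if kind == "and" else "|"
    body = f" {op} ".join(_to_string(t, kind) for t in tree[1])
    needs_paren = parent is not None and not (parent == kind)
    return f"({body})" if needs_paren else body


@dataclass(frozen=True)
class Rule:
    """A parsed Boolean update rule."""

    source: str
    tree: tuple

    @property
    def parents(self) -> tuple[str, ...]:
        acc: dict[str, set[int]] = {}
        _walk_vars(self.tree, False, acc)
        return tuple(sorted(acc))

    def parent_signs(self) -> dict[str, int]:
        """Sign of each parent's influence: +1 activating, -1 inhibiting.

        A parent occurring both positively and negatively reports -1 (the
        inhibitory role dominates for SIF export purposes).
        """
        acc: dict[str, set[int]] = {}
        _walk_vars(self.tree, False, acc)
        return {n: (-1 if -1 in s else +1) for n, s in acc.items()}

    def evaluate(self, state: Mapping[str, int]) -> int:
        return _eval_tree(self.tree, state)

    def compile_columns(self, index: Mapping[str, int]) -> Callable[[np.ndarray], np.ndarray]:
        """Compile to a function of a (n_states, n_nodes) uint8 matrix."""
        if self.tree[0] == "const":
            value = self.tree[1]

            def const_fn(X, _v=value):
                return np.full(X.shape[0], _v, dtype=np.uint8)

            return const_fn
        expr = _emit(self.tree, lambda name: f"X[:, {index[name]}]")
        code = compile(expr, "<rule>", "eval")

        def fn(X, _code=code):
            return eval(_code, {"X": X})  # noqa: S307 - expression built from validated AST

        return fn

    def substitute(self, name: str, value: int) -> "Rule":
        """Return a rule with ``name`` replaced by a constant (edge removal)."""
        tree = _substitute(self.tree, name, value)
        tree = _simplify(tree)
        return Rule(source=_to_string(tree), tree=tree)

    def __str__(self) -> str:
        return _to_string(self.tree)


def _eval_tree(tree, state) -> int:
    kind = tree[0]
    if kind == "var":
        return int(state[tree[1]])
    if kind == "const":
        return tree[1]
    if kind == "not":
        return 1 - _eval_tree(tree[1], state)
    if kind == "and":
        return int(all(_eval_tree(t, state) for t in tree[1]))
    return int(any(_eval_tree(t, state) for t in tree[1]))


def _substitute(tree, name, value):
    kind = tree[0]
    if kind == "var":
        return ("const", value) if tree[1] == name else tree
    if kind == "const":
        return tree
    if kind == "not":
        return ("not", _substitute(tree[1], name, value))
    return (kind, [_substitute(t, name, value) for t in tree[1]])


def _simplify(tree):
    kind = tree[0]
    if kind in ("var", "const"):
        return tree
    if kind == "not":
        inner = _simplify(tree[1])
        if inner[0] == "const":
            return ("const", 1 - inner[1])
        return ("not", inner)
    terms = [_simplify(t) for t in tree[1]]
    absorbing = 0 if kind == "and" else 1
    identity = 1 - absorbing
    kept = []
    for t in terms:
        if t[0] == "const":
            if t[1] == absorbing:
                return ("const", absorbing)
            continue  # identity element
        kept.append(t)
    if not kept:
        return ("const", identity)
    if len(kept) == 1:
        return kept[0]
    return (kind, kept)


def parse_rule(text: str) -> Rule:
    """Parse a Boolean expression such as ``"A & !B | C"``."""
    tokens = _tokenize(text)
    if not tokens:
        raise RuleSyntaxError("empty rule expression")
    tree = _Parser(tokens, text).parse()
    return Rule(source=text.strip(), tree=tree)
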