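"""Tiny boolean-expression language for combining per-method signal flags.

Grammar (case-insensitive identifiers)::

    expr   := term ('|' term)*
    term   := factor ('&' factor)*
    factor := '!' factor | '(' expr ')' | ident

Identifiers are the five method names: ror, prr, mhra, bcpnn, ebgm.
``parse_rule`` returns a callable mapping a {method: bool-array} dict to a
boolean array, so rules evaluate vectorized over a whole screen.
"""

from __future__ import annotations

import re
from typing import Callable, Mapping

import numpy as np

from .errors import RuleError
from .stats import METHODS

_TOKEN_RE = re.compile(r"\s*(?:([a-zA-Z_]+)|([&|!()]))")


def _tokenize(expr: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            tail = expr[pos:].strip()
            if not tail:
                break
            raise RuleError(f"bad character in rule at {tail[:10]!r}")
        tokens.append(m.group(1).lower() if m.group(1) else m.group(2))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expr(self):
        node = self.term()
        while self.peek() == "|":
            self.take()
            rhs = self.term()
            node = ("or", node, rhs)
        return node

    def term(self):
        node = self.factor()
        while self.peek() == "&":
            self.take()
            rhs = self.factor()
            node = ("and", node, rhs)
        return node

    def factor(self):
        tok = self.take()
        if tok == "!":
            return ("not", self.factor())
        if tok == "(":
            node = self.expr()
            if self.take() != ")":
                raise RuleError("unbalanced parentheses in rule")
            return node
        if tok in METHODS:
            return ("var", tok)
        raise RuleError(f"unknown token {tok!r}; methods are {', '.join(METHODS)}")


def _evaluate(node, flags: Mapping[str, np.ndarray]):
    kind = node[0]
    if kind == "var":
        return np.asarray(flags[node[1]], dtype=bool)
    if kind == "not":
        return ~_evaluate(node[1], flags)
    if kind == "and":
        return _evaluate(node[1], flags) & _evaluate(node[2], flags)
    return _evaluate(node[1], flags) | _evaluate(node[2], flags)


def parse_rule(expr: str) -> Callable[[Mapping[str, np.ndarray]], np.ndarray]:
    """Compile a rule like ``"ror & prr"`` into a vectorized predicate."""
    tokens = _tokenize(expr)
    if not tokens:
        raise RuleError("empty rule expression")
    parser = _Parser(tokens)
    tree = parser.expr()
    if parser.peek() is not None:
        raise RuleError(f"trailing tokens in rule: {parser.tokens[parser.pos:]}")

    def predicate(flags: Mapping[str, np.ndarray]) -> np.ndarray:
        return _evaluate(tree, flags)

    predicate.expression = expr  # type: ignore[attr-defined]
    return predicate
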