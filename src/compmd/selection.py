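"""A small atom-selection grammar.

Terms: ``chain <id>``, ``resid <n>`` / ``resid <a>-<b>``, ``resname <code>``,
``name <atom>``, ``heavy``, ``calpha`` (alias ``ca``), ``all``.  Terms combine
with ``and`` / ``or`` / ``not`` and parentheses.  Keywords are
case-insensitive; atom/residue/chain values are matched case-sensitively as
printed in the source file.  Results are 0-based topology indices in
topology order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .errors import SelectionError

__all__ = ["select_atoms"]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_KEYWORDS = {"and", "or", "not", "chain", "resid", "resname", "name",
             "heavy", "calpha", "ca", "all"}


@dataclass
class _Token:
    text: str
    position: int


def _tokenize(expr: str) -> list[_Token]:
    tokens = [_Token(m.group(0), m.start()) for m in _TOKEN_RE.finditer(expr)]
    if not tokens:
        raise SelectionError("empty selection expression", 0)
    return tokens


class _Parser:
    """Recursive descent over: or_expr > and_expr > unary > primary."""

    def __init__(self, expr: str, traj):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0
        self.topology = traj.topology

    def parse(self) -> np.ndarray:
        mask = self._or_expr()
        if self.pos != len(self.tokens):
            tok = self.tokens[self.pos]
            raise SelectionError(f"unexpected token {tok.text!r}", tok.position)
        return mask

    def _peek(self) -> _Token | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self, expect: str | None = None) -> _Token:
        tok = self._peek()
        if tok is None:
            raise SelectionError(
                f"unexpected end of expression"
                + (f", expected {expect}" if expect else ""),
                len(self.expr),
            )
        self.pos += 1
        return tok

    def _or_expr(self) -> np.ndarray:
        mask = self._and_expr()
        while (tok := self._peek()) is not None and tok.text.lower() == "or":
            self.pos += 1
            mask = mask | self._and_expr()
        return mask

    def _and_expr(self) -> np.ndarray:
        mask = self._unary()
        while (tok := self._peek()) is not None and tok.text.lower() == "and":
            self.pos += 1
            mask = mask & self._unary()
        return mask

    def _unary(self) -> np.ndarray:
        tok = self._peek()
        if tok is not None and tok.text.lower() == "not":
            self.pos += 1
            return ~self._unary()
        return self._primary()

    def _primary(self) -> np.ndarray:
        tok = self._next("a selection term")
        word = tok.text.lower()
        if tok.text == "(":
            mask = self._or_expr()
            closing = self._next("')'")
            if closing.text != ")":
                raise SelectionError("expected ')'", closing.position)
            return mask
        if word == "all":
            return np.ones(len(self.topology), dtype=bool)
        if word == "heavy":
            return np.array([a.is_heavy for a in self.topology])
        if word in ("calpha", "ca"):
            return np.array(
                [a.name == "CA" and a.element == "C" for a in self.topology])
        if word == "chain":
            value = self._value(tok)
            return np.array([a.chain == value for a in self.topology])
        if word == "name":
            value = self._value(tok)
            return np.array([a.name == value for a in self.topology])
        if word == "resname":
            value = self._value(tok)
            return np.array(
                [a.residue_name == value for a in self.topology])
        if word == "resid":
            value_tok = self._next("a residue index or range")
            lo, hi = self._parse_range(value_tok)
            return np.array(
                [lo <= a.residue_index <= hi for a in self.topology])
        raise SelectionError(f"unknown selection term {tok.text!r}",
                             tok.position)

    def _value(self, keyword_tok: _Token) -> str:
        tok = self._next(f"a value after {keyword_tok.text!r}")
        if tok.text in ("(", ")") or tok.text.lower() in ("and", "or", "not"):
            raise SelectionError(
                f"expected a value after {keyword_tok.text!r}", tok.position)
        return tok.text

    def _parse_range(self, tok: _Token) -> tuple[int, int]:
        m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", tok.text)
        if m is None:
            raise SelectionError(
                f"invalid residue index/range {tok.text!r}", tok.position)
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if hi < lo:
            raise SelectionError(
                f"empty residue range {tok.text!r}", tok.position)
        return lo, hi


def select_atoms(traj, expr: str) -> np.ndarray:
    """Evaluate a selection expression to sorted 0-based atom indices.

    Deterministic and order-preserving: indices come back in topology order;
    a term matching nothing yields an empty set, not an error.
    """
    mask = _Parser(expr, traj).parse()
    return np.flatnonzero(mask)
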