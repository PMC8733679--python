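"""Atom selection mini-language.

Grammar (case-insensitive keywords, whitespace-separated tokens)::

    expr     := or_expr
    or_expr  := and_expr ( "or" and_expr )*
    and_expr := unary ( "and" unary )*
    unary    := "not" unary | "(" expr ")" | term
    term     := "chain"   ID+
              | "resid"   RANGE+     (RANGE = N | N:M | N-M, inclusive)
              | "resname" NAME+
              | "name"    NAME+
              | "element" NAME+
              | "all"

Multiple values after a keyword are a union, e.g. ``resid 246 261 262``.
String matching is case-insensitive.  The result is deterministic and sorted
by atom index, so boolean operators act exactly as set algebra on atom sets.
"""

from __future__ import annotations

import re

import numpy as np

from .core import AtomGroup, Structure

__all__ = ["select", "evaluate"]

_KEYWORDS = {"chain", "resid", "resname", "name", "element", "all",
             "and", "or", "not", "(", ")"}

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_RANGE_RE = re.compile(r"^(-?\d+)(?:[:\-](-?\d+))?$")


class SelectionError(ValueError):
    pass


def _tokenize(expr: str) -> list[str]:
    return _TOKEN_RE.findall(expr)


class _Parser:
    def __init__(self, structure: Structure, tokens: list[str]):
        self.s = structure
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionError(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while (self.peek() or "").lower() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.unary()
        while (self.peek() or "").lower() == "and":
            self.next()
            mask = mask & self.unary()
        return mask

    def unary(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionError("unexpected end of selection expression")
        if tok.lower() == "not":
            self.next()
            return ~self.unary()
        if tok == "(":
            self.next()
            mask = self.or_expr()
            if self.next() != ")":
                raise SelectionError("missing closing parenthesis")
            return mask
        return self.term()

    def _values(self) -> list[str]:
        vals = []
        while True:
            tok = self.peek()
            if tok is None or tok.lower() in _KEYWORDS:
                break
            vals.append(self.next())
        if not vals:
            raise SelectionError("keyword expects at least one value")
        return vals

    def term(self) -> np.ndarray:
        kw = self.next().lower()
        n = self.s.n_atoms
        if kw == "all":
            return np.ones(n, dtype=bool)
        if kw == "resid":
            mask = np.zeros(n, dtype=bool)
            resids = self.s.resids
            for v in self._values():
                m = _RANGE_RE.match(v)
                if not m:
                    raise SelectionError(f"bad resid value {v!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                mask |= (resids >= lo) & (resids <= hi)
            return mask
        fields = {
            "chain": self.s.chain_ids,
            "resname": self.s.resnames,
            "name": self.s.names,
            "element": self.s.elements,
        }
        if kw not in fields:
            raise SelectionError(f"unknown keyword {kw!r}")
        col = np.asarray([str(x).upper() for x in fields[kw]], dtype=object)
        wanted = {v.upper() for v in self._values()}
        return np.isin(col, list(wanted))


def evaluate(structure: Structure, expr: str) -> np.ndarray:
    """Evaluate a selection expression to a boolean mask over atoms."""
    tokens = _tokenize(expr)
    if not tokens:
        raise SelectionError("empty selection expression")
    return _Parser(structure, tokens).parse()


def select(structure: Structure, expr: str, allow_empty: bool = False,
           label: str | None = None) -> AtomGroup:
    """Resolve a selection expression to an AtomGroup.

    Raises on an empty result unless ``allow_empty`` is set.
    """
    mask = evaluate(structure, expr)
    idx = np.nonzero(mask)[0]
    if idx.size == 0 and not allow_empty:
        raise SelectionError(f"selection {expr!r} matched no atoms")
    return AtomGroup(structure, idx, label if label is not None else expr)
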