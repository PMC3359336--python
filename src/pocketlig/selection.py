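"""A small atom-selection language.

Grammar (case-insensitive keywords, whitespace-tokenized)::

    expr      := term ("or" term)*
    term      := factor ("and" factor)*
    factor    := "not" factor | "(" expr ")" | predicate
    predicate := "hetero"
               | ("chain" | "resname" | "resnum" | "name" | "element") value+
    value     := bare word, or for resnum an integer or inclusive range "a:b"

Examples: ``chain A and resnum 473 and name OH``, ``resname HOH WAT``,
``not hetero``, ``resnum 466:477``.
"""

from __future__ import annotations

import numpy as np

from .structure import AtomSet, Structure

__all__ = ["SelectionError", "select_atoms"]

_KEYWORDS = {"and", "or", "not", "(", ")", "chain", "resname", "resnum",
             "name", "element", "hetero"}
_FIELDS = {"chain", "resname", "resnum", "name", "element"}


class SelectionError(ValueError):
    """Selection expression does not conform to the grammar."""


def _tokenize(expr: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(expr):
        c = expr[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < len(expr) and not expr[j].isspace() and expr[j] not in "()":
            j += 1
        tokens.append((expr[i:j], i))
        i = j
    return tokens


class _Parser:
    def __init__(self, expr: str, structure: Structure):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.pos = 0
        self.st = structure

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        if self.pos >= len(self.tokens):
            raise SelectionError(f"unexpected end of expression: {self.expr!r}")
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def fail(self, msg: str) -> None:
        at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.expr)
        raise SelectionError(f"{msg} at position {at} in {self.expr!r}")

    def parse(self) -> np.ndarray:
        mask = self.expr_rule()
        if self.pos != len(self.tokens):
            self.fail(f"unexpected token {self.peek()!r}")
        return mask

    def expr_rule(self) -> np.ndarray:
        mask = self.term_rule()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.term_rule()
        return mask

    def term_rule(self) -> np.ndarray:
        mask = self.factor_rule()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.factor_rule()
        return mask

    def factor_rule(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            self.fail("expected a predicate")
        low = tok.lower()
        if low == "not":
            self.next()
            return ~self.factor_rule()
        if tok == "(":
            self.next()
            mask = self.expr_rule()
            if self.peek() != ")":
                self.fail("expected ')'")
            self.next()
            return mask
        if low == "hetero":
            self.next()
            return np.array([a.is_hetero for a in self.st.atoms])
        if low in _FIELDS:
            self.next()
            return self.predicate_rule(low)
        self.fail(f"unknown keyword {tok!r}")

    def predicate_rule(self, field: str) -> np.ndarray:
        values: list[str] = []
        while True:
            tok = self.peek()
            if tok is None or tok.lower() in _KEYWORDS or tok in "()":
                break
            values.append(self.next()[0])
        if not values:
            self.fail(f"'{field}' requires at least one value")
        if field == "resnum":
            mask = np.zeros(self.st.n_atoms, dtype=bool)
            nums = np.array([a.residue_number for a in self.st.atoms])
            for v in values:
                if ":" in v:
                    lo_s, _, hi_s = v.partition(":")
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        raise SelectionError(f"bad resnum range {v!r} in {self.expr!r}") from None
                    mask |= (nums >= lo) & (nums <= hi)
                else:
                    try:
                        mask |= nums == int(v)
                    except ValueError:
                        raise SelectionError(f"bad resnum {v!r} in {self.expr!r}") from None
            return mask
        wanted = {v.upper() for v in values}
        getter = {
            "chain": lambda a: a.chain_id.upper(),
            "resname": lambda a: a.residue_name.upper(),
            "name": lambda a: a.name.upper(),
            "element": lambda a: a.element.upper(),
        }[field]
        return np.array([getter(a) in wanted for a in self.st.atoms])


def select_atoms(structure: Structure, expr: str) -> AtomSet:
    """Evaluate a selection expression; result ordered by atom serial."""
    mask = _Parser(expr, structure).parse()
    idx = np.flatnonzero(mask)
    serials = np.array([structure.atoms[i].serial for i in idx])
    return AtomSet(structure, idx[np.argsort(serials, kind="stable")])
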