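"""Gene-protein-reaction (GPR) rule parsing and evaluation.

A GPR rule is a boolean expression over gene identifiers stating which
gene products catalyse a reaction: subunits of a complex are joined with
``and``, isoenzymes with ``or``.  Grammar (keywords case-insensitive,
``and`` binds tighter than ``or``)::

    expr   := term ('or' term)*
    term   := factor ('and' factor)*
    factor := GENE | '(' expr ')'

For quantitative evaluation the boolean algebra is mapped onto gene
activities (non-negative numbers): an AND node takes the minimum of its
children (a complex is limited by its scarcest subunit) and an OR node the
sum (isoenzymes add capacity).  Evaluation broadcasts over numpy arrays,
so a rule can be evaluated for many Monte-Carlo draws at once.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

__all__ = ["Gene", "And", "Or", "GPRNode", "parse_gpr", "GPRParseError"]

Activity = Union[float, np.ndarray]


class GPRParseError(ValueError):
    """Malformed GPR string; carries the character position of the defect."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} at position {position}")
        self.position = position


@dataclass(frozen=True)
class Gene:
    gene_id: str

    def evaluate(self, activity: Mapping[str, Activity]) -> Activity:
        try:
            return activity[self.gene_id]
        except KeyError:
            raise KeyError(f"no activity for gene {self.gene_id!r}") from None

    def gene_ids(self) -> set[str]:
        return {self.gene_id}

    def to_string(self) -> str:
        return self.gene_id


@dataclass(frozen=True)
class And:
    children: tuple["GPRNode", ...]

    def evaluate(self, activity: Mapping[str, Activity]) -> Activity:
        vals = [c.evaluate(activity) for c in self.children]
        out = vals[0]
        for v in vals[1:]:
            out = np.minimum(out, v)
        return out

    def gene_ids(self) -> set[str]:
        return set().union(*(c.gene_ids() for c in self.children))

    def to_string(self) -> str:
        parts = [
            f"({c.to_string()})" if isinstance(c, Or) else c.to_string() for c in self.children
        ]
        return " and ".join(parts)


@dataclass(frozen=True)
class Or:
    children: tuple["GPRNode", ...]

    def evaluate(self, activity: Mapping[str, Activity]) -> Activity:
        vals = [c.evaluate(activity) for c in self.children]
        out = vals[0]
        for v in vals[1:]:
            out = out + v
        return out

    def gene_ids(self) -> set[str]:
        return set().union(*(c.gene_ids() for c in self.children))

    def to_string(self) -> str:
        return " or ".join(c.to_string() for c in self.children)


GPRNode = Union[Gene, And, Or]

_TOKEN_RE = re.compile(r"\s*(?:(\()|(\))|([^\s()]+))")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            break
        start = m.start(m.lastindex)
        if m.group(1):
            tokens.append(("LPAREN", "(", start))
        elif m.group(2):
            tokens.append(("RPAREN", ")", start))
        else:
            word = m.group(3)
            low = word.casefold()
            if low == "and":
                tokens.append(("AND", word, start))
            elif low == "or":
                tokens.append(("OR", word, start))
            else:
                tokens.append(("GENE", word, start))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> tuple[str, str, int] | None:
        tok = self._peek()
        if tok is not None:
            self.i += 1
        return tok

    def _end_pos(self) -> int:
        return len(self.text)

    def parse(self) -> GPRNode:
        if not self.tokens:
            raise GPRParseError("empty GPR rule", 0)
        node = self.expr()
        tok = self._peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def expr(self) -> GPRNode:
        terms = [self.term()]
        while (tok := self._peek()) is not None and tok[0] == "OR":
            self._next()
            terms.append(self.term())
        if len(terms) == 1:
            return terms[0]
        # flatten associative nests so print/parse round-trips to the same tree
        flat: list[GPRNode] = []
        for t in terms:
            flat.extend(t.children if isinstance(t, Or) else (t,))
        return Or(tuple(flat))

    def term(self) -> GPRNode:
        factors = [self.factor()]
        while (tok := self._peek()) is not None and tok[0] == "AND":
            self._next()
            factors.append(self.factor())
        if len(factors) == 1:
            return factors[0]
        flat: list[GPRNode] = []
        for f in factors:
            flat.extend(f.children if isinstance(f, And) else (f,))
        return And(tuple(flat))

    def factor(self) -> GPRNode:
        tok = self._next()
        if tok is None:
            raise GPRParseError("dangling operator: expected gene or '('", self._end_pos())
        kind, value, pos = tok
        if kind == "GENE":
            return Gene(value)
        if kind == "LPAREN":
            node = self.expr()
            closing = self._next()
            if closing is None or closing[0] != "RPAREN":
                raise GPRParseError("unbalanced parentheses", closing[2] if closing else self._end_pos())
            return node
        raise GPRParseError(f"expected gene or '(', found {value!r}", pos)


def parse_gpr(rule: str) -> GPRNode:
    """Parse a GPR rule string into its tree; ``and`` binds tighter than ``or``."""
    return _Parser(rule).parse()
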