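"""Configurable read filters expressed in a small boolean DSL.

Only reads passing the configured filter contribute to the filtered
pileups, so that mutation calls are triggered by high-quality reads only.
Filters are boolean combinations of comparisons on numeric read
attributes (single-read mapping quality, aligned length, mismatch count)
and flag atoms (duplicate, proper_pair, second_in_pair), combined with
``and`` / ``or`` / ``not`` and parentheses.

Grammar (whitespace-insensitive)::

    expr    := or_expr
    or_expr := and_expr ("or" and_expr)*
    and_expr:= unary ("and" unary)*
    unary   := "not" unary | atom
    atom    := "(" expr ")" | FLAG | FIELD OP NUMBER
    FIELD   := mapq_single | align_len | mismatches
    FLAG    := duplicate | proper_pair | second_in_pair
    OP      := < | <= | > | >= | == | !=

Two platform presets are provided.  For SOLiD v4 exome data: at least
35 bp aligned length (or second of a properly mapped pair), single
mapping quality above 15, at most 2 mismatches, and not a PCR duplicate.
For Illumina paired-end data: single mapping quality above 10, at most
3 mismatches, and not a duplicate.
"""

from __future__ import annotations

import operator
import re
from dataclasses import dataclass
from typing import Callable

from .reads import ReadRecord

__all__ = [
    "FilterSpec",
    "FilterSyntaxError",
    "parse_filter_spec",
    "passes_filter",
    "PRESETS",
    "SOLID_PRESET",
    "ILLUMINA_PRESET",
]

_NUMERIC_FIELDS = ("mapq_single", "align_len", "mismatches")
_FLAG_FIELDS = {
    "duplicate": "is_duplicate",
    "proper_pair": "is_proper_pair",
    "second_in_pair": "is_second_in_pair",
}
_OPS: dict[str, Callable[[int, int], bool]] = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
    "==": operator.eq,
    "!=": operator.ne,
}


class FilterSyntaxError(ValueError):
    """Raised for malformed filter expressions; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class FilterSpec:
    """A compiled filter: the source expression plus an evaluable predicate."""

    expression: str
    _predicate: Callable[[ReadRecord], bool]

    def __call__(self, read: ReadRecord) -> bool:
        return self._predicate(read)


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<op><=|>=|==|!=|<|>)"
    r"|(?P<num>-?\d+)|(?P<word>[A-Za-z_][A-Za-z_0-9]*))"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    i = 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if m is None or m.end() == i:
            # skip pure whitespace tail
            if text[i:].strip() == "":
                break
            raise FilterSyntaxError(f"unexpected character {text[i]!r}", i)
        kind = m.lastgroup
        tokens.append((kind, m.group(kind), m.start(kind)))
        i = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is None:
            raise FilterSyntaxError("unexpected end of expression", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> Callable[[ReadRecord], bool]:
        node = self.or_expr()
        tok = self.peek()
        if tok is not None:
            raise FilterSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def or_expr(self):
        left = self.and_expr()
        while True:
            tok = self.peek()
            if tok and tok[0] == "word" and tok[1] == "or":
                self.next()
                right = self.and_expr()
                left = (lambda a, b: lambda r: a(r) or b(r))(left, right)
            else:
                return left

    def and_expr(self):
        left = self.unary()
        while True:
            tok = self.peek()
            if tok and tok[0] == "word" and tok[1] == "and":
                self.next()
                right = self.unary()
                left = (lambda a, b: lambda r: a(r) and b(r))(left, right)
            else:
                return left

    def unary(self):
        tok = self.peek()
        if tok and tok[0] == "word" and tok[1] == "not":
            self.next()
            inner = self.unary()
            return lambda r: not inner(r)
        return self.atom()

    def atom(self):
        tok = self.next()
        kind, value, at = tok
        if kind == "lpar":
            inner = self.or_expr()
            closing = self.next()
            if closing[0] != "rpar":
                raise FilterSyntaxError(f"expected ')', got {closing[1]!r}", closing[2])
            return inner
        if kind != "word":
            raise FilterSyntaxError(f"expected field or flag, got {value!r}", at)
        if value in _FLAG_FIELDS:
            attr = _FLAG_FIELDS[value]
            return lambda r, a=attr: getattr(r, a)
        if value in _NUMERIC_FIELDS:
            op_tok = self.next()
            if op_tok[0] != "op":
                raise FilterSyntaxError(
                    f"expected comparison operator after {value!r}, got {op_tok[1]!r}",
                    op_tok[2],
                )
            num_tok = self.next()
            if num_tok[0] != "num":
                raise FilterSyntaxError(
                    f"expected integer literal, got {num_tok[1]!r}", num_tok[2]
                )
            fn = _OPS[op_tok[1]]
            lit = int(num_tok[1])
            return lambda r, f=value, fn=fn, lit=lit: fn(getattr(r, f), lit)
        raise FilterSyntaxError(f"unknown field name {value!r}", at)


def parse_filter_spec(dsl_text: str) -> FilterSpec:
    """Compile a filter expression into an evaluable :class:`FilterSpec`.

    Raises :class:`FilterSyntaxError` naming the offending token position
    for grammar errors and unknown field names.
    """
    if not dsl_text or not dsl_text.strip():
        raise FilterSyntaxError("empty filter expression", 0)
    predicate = _Parser(dsl_text).parse()
    return FilterSpec(expression=dsl_text, _predicate=predicate)


def passes_filter(read: ReadRecord, spec: FilterSpec) -> bool:
    """Evaluate ``spec`` on ``read``."""
    return spec(read)


SOLID_PRESET = parse_filter_spec(
    "(align_len >= 35 or (second_in_pair and proper_pair))"
    " and mapq_single > 15 and mismatches <= 2 and not duplicate"
)
ILLUMINA_PRESET = parse_filter_spec(
    "mapq_single > 10 and mismatches <= 3 and not duplicate"
)

PRESETS: dict[str, FilterSpec] = {
    "solid": SOLID_PRESET,
    "illumina": ILLUMINA_PRESET,
}
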