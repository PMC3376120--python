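"""A small expression language for row filters, e.g. ``"filtervar<2"``.

Filter strings combine variable names, numeric literals, arithmetic
(``+ - * /``), comparisons (``< <= > >= = ~=``, with ``==``/``!=`` accepted
as synonyms) and logical connectives (``& | ~`` or the case-insensitive
words ``AND OR NOT``), with parentheses for grouping.  Precedence, loosest
to tightest::

    OR  <  AND  <  NOT  <  comparison  <  + -  <  * /  <  unary -

Comparisons on a missing value evaluate to false, so a filter never keeps a
row it cannot judge.  ``=`` is exact numeric equality; prefer inequalities
for continuous variables.

Strings, dates and user functions are out of scope.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Union

import numpy as np

from .dataio import SurvivalDataset

__all__ = [
    "FilterSyntaxError",
    "FilterNameError",
    "FilterTypeError",
    "EmptyFilterResultError",
    "FilterExpr",
    "Var",
    "Number",
    "BinOp",
    "Compare",
    "Logical",
    "Not",
    "Neg",
    "parse_filter",
    "evaluate_filter",
    "apply_filter",
    "unparse",
]


class FilterSyntaxError(ValueError):
    """Raised for malformed filter strings; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


class FilterNameError(KeyError):
    """A filter references a variable absent from the dataset."""


class FilterTypeError(TypeError):
    """Numeric and boolean subexpressions were mixed incorrectly."""


class EmptyFilterResultError(ValueError):
    """The filter removed every row; analysis must not proceed."""


# --- AST -------------------------------------------------------------------

@dataclass(frozen=True)
class Var:
    name: str


@dataclass(frozen=True)
class Number:
    value: float


@dataclass(frozen=True)
class Neg:
    operand: "FilterExpr"


@dataclass(frozen=True)
class BinOp:
    """Arithmetic node; ``op`` is one of ``+ - * /``."""
    op: str
    left: "FilterExpr"
    right: "FilterExpr"


@dataclass(frozen=True)
class Compare:
    """Comparison node; ``op`` is one of ``< <= > >= = ~=``."""
    op: str
    left: "FilterExpr"
    right: "FilterExpr"


@dataclass(frozen=True)
class Logical:
    """``AND``/``OR`` over boolean children."""
    op: str
    left: "FilterExpr"
    right: "FilterExpr"


@dataclass(frozen=True)
class Not:
    operand: "FilterExpr"


FilterExpr = Union[Var, Number, Neg, BinOp, Compare, Logical, Not]


# --- Lexer -----------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>(\d+\.\d*|\.\d+|\d+)([eE][+-]?\d+)?)
  | (?P<name>[A-Za-z_][A-Za-z0-9_.]*)
  | (?P<op><=|>=|==|!=|~=|[<>=]|[-+*/()&|~])
    """,
    re.VERBOSE,
)

_WORD_OPS = {"and": "&", "or": "|", "not": "~"}
_CMP_SYNONYMS = {"==": "=", "!=": "~="}


@dataclass(frozen=True)
class _Token:
    kind: str  # 'number' | 'name' | 'op' | 'end'
    text: str
    offset: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise FilterSyntaxError(f"unknown token {text[pos]!r}", pos)
        if m.lastgroup != "ws":
            kind = m.lastgroup
            tok = m.group()
            if kind == "name" and tok.lower() in _WORD_OPS:
                kind, tok = "op", _WORD_OPS[tok.lower()]
            elif kind == "op":
                tok = _CMP_SYNONYMS.get(tok, tok)
            tokens.append(_Token(kind, tok, m.start()))
        pos = m.end()
    tokens.append(_Token("end", "", len(text)))
    return tokens


# --- Parser ----------------------------------------------------------------

class _Parser:
    """Recursive descent over the precedence ladder in the module docstring."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def _advance(self) -> _Token:
        tok = self.cur
        self.i += 1
        return tok

    def _accept_op(self, *ops: str) -> _Token | None:
        if self.cur.kind == "op" and self.cur.text in ops:
            return self._advance()
        return None

    def parse(self) -> FilterExpr:
        expr = self.or_expr()
        if self.cur.kind != "end":
            raise FilterSyntaxError(f"unexpected {self.cur.text!r}", self.cur.offset)
        return expr

    def or_expr(self) -> FilterExpr:
        node = self.and_expr()
        while self._accept_op("|"):
            node = Logical("OR", node, self.and_expr())
        return node

    def and_expr(self) -> FilterExpr:
        node = self.not_expr()
        while self._accept_op("&"):
            node = Logical("AND", node, self.not_expr())
        return node

    def not_expr(self) -> FilterExpr:
        if self._accept_op("~"):
            return Not(self.not_expr())
        return self.comparison()

    def comparison(self) -> FilterExpr:
        node = self.arith()
        tok = self._accept_op("<", "<=", ">", ">=", "=", "~=")
        if tok is not None:
            node = Compare(tok.text, node, self.arith())
        return node

    def arith(self) -> FilterExpr:
        node = self.term()
        while True:
            tok = self._accept_op("+", "-")
            if tok is None:
                return node
            node = BinOp(tok.text, node, self.term())

    def term(self) -> FilterExpr:
        node = self.factor()
        while True:
            tok = self._accept_op("*", "/")
            if tok is None:
                return node
            node = BinOp(tok.text, node, self.factor())

    def factor(self) -> FilterExpr:
        tok = self.cur
        if tok.kind == "number":
            self._advance()
            return Number(float(tok.text))
        if tok.kind == "name":
            self._advance()
            return Var(tok.text)
        if self._accept_op("-"):
            return Neg(self.factor())
        if self._accept_op("("):
            node = self.or_expr()
            if not self._accept_op(")"):
                raise FilterSyntaxError("expected ')'", self.cur.offset)
            return node
        if tok.kind == "end":
            raise FilterSyntaxError("unexpected end of filter string", tok.offset)
        raise FilterSyntaxError(f"unexpected {tok.text!r}", tok.offset)


def parse_filter(text: str) -> FilterExpr:
    """Parse ``text`` into a filter AST.

    Raises :class:`FilterSyntaxError` with a character offset for dangling
    operators, unbalanced parentheses and unknown tokens.
    """
    if not text or not text.strip():
        raise FilterSyntaxError("empty filter string", 0)
    return _Parser(text).parse()


# --- Evaluation ------------------------------------------------------------

def _eval_numeric(node: FilterExpr, ds: SurvivalDataset) -> np.ndarray:
    if isinstance(node, Number):
        return np.full(ds.n_rows, node.value)
    if isinstance(node, Var):
        if node.name not in ds.variable_names:
            raise FilterNameError(
                f"unknown variable {node.name!r}; available: "
                f"{', '.join(ds.variable_names)}"
            )
        return ds.column(node.name)
    if isinstance(node, Neg):
        return -_eval_numeric(node.operand, ds)
    if isinstance(node, BinOp):
        left = _eval_numeric(node.left, ds)
        right = _eval_numeric(node.right, ds)
        if node.op == "+":
            return left + right
        if node.op == "-":
            return left - right
        if node.op == "*":
            return left * right
        with np.errstate(divide="ignore", invalid="ignore"):
            return left / right
    raise FilterTypeError(f"expected a numeric expression, got {unparse(node)!r}")


def _eval_bool(node: FilterExpr, ds: SurvivalDataset) -> np.ndarray:
    if isinstance(node, Compare):
        left = _eval_numeric(node.left, ds)
        right = _eval_numeric(node.right, ds)
        ok = np.isfinite(left) & np.isfinite(right)  # missing compares false
        with np.errstate(invalid="ignore"):
            if node.op == "<":
                res = left < right
            elif node.op == "<=":
                res = left <= right
            elif node.op == ">":
                res = left > right
            elif node.op == ">=":
                res = left >= right
            elif node.op == "=":
                res = left == right
            else:  # "~="
                res = left != right
        return res & ok
    if isinstance(node, Logical):
        left = _eval_bool(node.left, ds)
        right = _eval_bool(node.right, ds)
        return (left & right) if node.op == "AND" else (left | right)
    if isinstance(node, Not):
        return ~_eval_bool(node.operand, ds)
    raise FilterTypeError(
        f"filter must be a boolean expression, got numeric {unparse(node)!r}; "
        "add a comparison (e.g. 'x > 0')"
    )


def evaluate_filter(expr: FilterExpr, ds: SurvivalDataset) -> np.ndarray:
    """Evaluate ``expr`` row-wise; True marks rows to keep."""
    return _eval_bool(expr, ds).astype(bool)


def apply_filter(ds: SurvivalDataset, expr: FilterExpr) -> tuple[SurvivalDataset, int]:
    """Subset ``ds`` to the rows where ``expr`` holds, preserving order.

    Returns the filtered dataset and the number of removed rows.  An empty
    result raises :class:`EmptyFilterResultError` — downstream analysis of
    zero subjects is never meaningful.
    """
    mask = evaluate_filter(expr, ds)
    if not mask.any():
        raise EmptyFilterResultError(
            f"filter {unparse(expr)!r} removed all {ds.n_rows} rows"
        )
    return ds.subset(mask), int((~mask).sum())


# --- Pretty printing -------------------------------------------------------

def unparse(node: FilterExpr) -> str:
    """Render an AST back to filter syntax (fully parenthesized).

    ``parse_filter(unparse(e))`` is structurally equal to ``e``.
    """
    if isinstance(node, Number):
        v = node.value
        return str(int(v)) if float(v).is_integer() else repr(v)
    if isinstance(node, Var):
        return node.name
    if isinstance(node, Neg):
        return f"(-{unparse(node.operand)})"
    if isinstance(node, BinOp):
        return f"({unparse(node.left)} {node.op} {unparse(node.right)})"
    if isinstance(node, Compare):
        return f"({unparse(node.left)} {node.op} {unparse(node.right)})"
    if isinstance(node, Logical):
        sym = "&" if node.op == "AND" else "|"
        return f"({unparse(node.left)} {sym} {unparse(node.right)})"
    if isinstance(node, Not):
        return f"(~{unparse(node.operand)})"
    raise TypeError(f"not a filter node: {node!r}")
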