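"""Update-rule expression language.

Update functions in the model mix Boolean logic with integer arithmetic:
logic clauses (``And``, ``Or``, ``Not``) and level comparisons
(``node >= k``) operate on truth values, while ``+``, ``-`` and ``*``
operate on raw node levels.  A multi-level node is *true* in a logical
context iff its level is strictly positive, and a logical sub-expression
used arithmetically contributes 0 or 1.  The value a rule assigns to its
target node is clamped, once, to the target's declared level range.

Operator precedence, loosest to tightest::

    Or  <  And  <  + -  <  *  <  Not  <  comparisons

so ``A + B And C`` parses as ``(A + B) And C`` and ``Not X = 2`` negates
the comparison ``X = 2``.  Parentheses override as usual.

Two evaluation paths are provided: :func:`evaluate` walks the AST (the
reference semantics) and :func:`compile_rule` emits an equivalent Python
closure used by the simulation engine for speed.  The test suite checks
the two against each other on randomized expressions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterator, Mapping, Sequence

__all__ = [
    "RuleExpr", "Ref", "Num", "NotOp", "AndOp", "OrOp", "BinOp", "Cmp",
    "RuleSyntaxError", "UndeclaredNodeError",
    "parse_rule", "unparse", "evaluate", "compile_rule", "referenced_nodes",
]


class RuleSyntaxError(ValueError):
    """Malformed rule text; carries the character position of the fault."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class UndeclaredNodeError(ValueError):
    """A rule references a node name absent from the model."""

    def __init__(self, name: str):
        super().__init__(f"rule references undeclared node {name!r}")
        self.name = name


# ---------------------------------------------------------------------------
# AST
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ref:
    name: str


@dataclass(frozen=True)
class Num:
    value: float


@dataclass(frozen=True)
class NotOp:
    operand: "RuleExpr"


@dataclass(frozen=True)
class AndOp:
    operands: tuple["RuleExpr", ...]


@dataclass(frozen=True)
class OrOp:
    operands: tuple["RuleExpr", ...]


@dataclass(frozen=True)
class BinOp:
    op: str  # '+', '-', '*'
    left: "RuleExpr"
    right: "RuleExpr"


@dataclass(frozen=True)
class Cmp:
    """Threshold clause comparing a node level against a constant."""

    ref: Ref
    op: str  # '=', '!=', '>=', '<=', '>', '<'
    value: float


RuleExpr = Ref | Num | NotOp | AndOp | OrOp | BinOp | Cmp

_LOGICAL = (NotOp, AndOp, OrOp, Cmp)


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<number>\d+(?:\.\d+)?)
  | (?P<name>[A-Za-z_][A-Za-z0-9_]*)
  | (?P<op>>=|<=|!=|[-+*=><()])
    """,
    re.VERBOSE,
)

_KEYWORDS = {"and": "And", "or": "Or", "not": "Not"}


@dataclass(frozen=True)
class _Token:
    kind: str  # 'number' | 'name' | 'op' | 'kw'
    text: str
    pos: int


def _tokenize(text: str) -> Iterator[_Token]:
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise RuleSyntaxError(f"unexpected character {text[pos]!r}", pos)
        if m.lastgroup != "ws":
            tok = m.group()
            kind = m.lastgroup
            if kind == "name" and tok.lower() in _KEYWORDS:
                yield _Token("kw", _KEYWORDS[tok.lower()], pos)
            else:
                yield _Token(kind, tok, pos)
        pos = m.end()
    yield _Token("op", "<END>", len(text))


# ---------------------------------------------------------------------------
# Parser (recursive descent, one token of lookahead)
# ---------------------------------------------------------------------------

class _Parser:
    def __init__(self, text: str, declared: frozenset[str] | None):
        self.tokens = list(_tokenize(text))
        self.i = 0
        self.declared = declared

    @property
    def cur(self) -> _Token:
        return self.tokens[self.i]

    def advance(self) -> _Token:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, text: str) -> None:
        if self.cur.text != text:
            raise RuleSyntaxError(
                f"expected {text!r}, found {self.cur.text!r}", self.cur.pos)
        self.advance()

    def parse(self) -> RuleExpr:
        expr = self.or_expr()
        if self.cur.text != "<END>":
            raise RuleSyntaxError(
                f"unexpected token {self.cur.text!r}", self.cur.pos)
        return expr

    def or_expr(self) -> RuleExpr:
        parts = [self.and_expr()]
        while self.cur.kind == "kw" and self.cur.text == "Or":
            self.advance()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else OrOp(tuple(parts))

    def and_expr(self) -> RuleExpr:
        parts = [self.add_expr()]
        while self.cur.kind == "kw" and self.cur.text == "And":
            self.advance()
            parts.append(self.add_expr())
        return parts[0] if len(parts) == 1 else AndOp(tuple(parts))

    def add_expr(self) -> RuleExpr:
        expr = self.mul_expr()
        while self.cur.text in ("+", "-"):
            op = self.advance().text
            expr = BinOp(op, expr, self.mul_expr())
        return expr

    def mul_expr(self) -> RuleExpr:
        expr = self.unary()
        while self.cur.text == "*":
            self.advance()
            expr = BinOp("*", expr, self.unary())
        return expr

    def unary(self) -> RuleExpr:
        if self.cur.kind == "kw" and self.cur.text == "Not":
            self.advance()
            return NotOp(self.unary())
        return self.atom()

    def _number(self) -> float:
        sign = 1.0
        if self.cur.text == "-":
            self.advance()
            sign = -1.0
        if self.cur.kind != "number":
            raise RuleSyntaxError(
                f"expected a number, found {self.cur.text!r}", self.cur.pos)
        raw = self.advance().text
        val = float(raw)
        return sign * (int(val) if val.is_integer() else val)

    def atom(self) -> RuleExpr:
        tok = self.cur
        if tok.kind == "number" or tok.text == "-":
            return Num(self._number())
        if tok.text == "(":
            self.advance()
            expr = self.or_expr()
            self.expect(")")
            return expr
        if tok.kind == "name":
            self.advance()
            if self.declared is not None and tok.text not in self.declared:
                raise UndeclaredNodeError(tok.text)
            ref = Ref(tok.text)
            if self.cur.text in ("=", "!=", ">=", "<=", ">", "<"):
                op = self.advance().text
                return Cmp(ref, op, self._number())
            return ref
        raise RuleSyntaxError(f"unexpected token {tok.text!r}", tok.pos)


def parse_rule(text: str, declared: Sequence[str] | frozenset[str] | None = None) -> RuleExpr:
    """Parse a rule string into an AST.

    Parameters
    ----------
    text
        The rule expression, e.g. ``"phot1 And phot1_1433"``.
    declared
        Node names allowed to appear in the rule.  ``None`` skips the
        check (useful for standalone parsing).

    Raises
    ------
    RuleSyntaxError
        On malformed input, with the character position.
    UndeclaredNodeError
        When a referenced name is not declared.
    """
    frozen = None if declared is None else frozenset(declared)
    return _Parser(text, frozen).parse()


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

# precedence rank used to decide where parentheses are required
_PREC = {"Or": 0, "And": 1, "+": 2, "-": 2, "*": 3, "Not": 4, "atom": 5}


def _prec(expr: RuleExpr) -> int:
    if isinstance(expr, OrOp):
        return _PREC["Or"]
    if isinstance(expr, AndOp):
        return _PREC["And"]
    if isinstance(expr, BinOp):
        return _PREC[expr.op]
    if isinstance(expr, NotOp):
        return _PREC["Not"]
    return _PREC["atom"]


def unparse(expr: RuleExpr) -> str:
    """Render an AST back to canonical rule text; parse(unparse(e)) == e."""

    def wrap(sub: RuleExpr, minimum: int) -> str:
        text = unparse(sub)
        return f"({text})" if _prec(sub) < minimum else text

    if isinstance(expr, Ref):
        return expr.name
    if isinstance(expr, Num):
        v = expr.value
        text = str(int(v)) if float(v).is_integer() else str(v)
        return f"({text})" if v < 0 else text
    if isinstance(expr, Cmp):
        return f"({expr.ref.name} {expr.op} {_fmt_num(expr.value)})"
    if isinstance(expr, NotOp):
        return f"Not {wrap(expr.operand, _PREC['Not'])}"
    if isinstance(expr, AndOp):
        return " And ".join(wrap(p, _PREC["And"] + 1) if isinstance(p, AndOp)
                            else wrap(p, _PREC["And"]) for p in expr.operands)
    if isinstance(expr, OrOp):
        return " Or ".join(wrap(p, _PREC["Or"] + 1) if isinstance(p, OrOp)
                           else wrap(p, _PREC["Or"]) for p in expr.operands)
    if isinstance(expr, BinOp):
        left = wrap(expr.left, _PREC[expr.op])
        # binary ops are left-associative: the right operand needs a higher rank
        right = wrap(expr.right, _PREC[expr.op] + 1)
        return f"{left} {expr.op} {right}"
    raise TypeError(f"not a rule expression: {expr!r}")


def _fmt_num(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


def referenced_nodes(expr: RuleExpr) -> frozenset[str]:
    """All node names appearing in the expression."""
    out: set[str] = set()

    def walk(e: RuleExpr) -> None:
        if isinstance(e, Ref):
            out.add(e.name)
        elif isinstance(e, Cmp):
            out.add(e.ref.name)
        elif isinstance(e, NotOp):
            walk(e.operand)
        elif isinstance(e, (AndOp, OrOp)):
            for p in e.operands:
                walk(p)
        elif isinstance(e, BinOp):
            walk(e.left)
            walk(e.right)

    walk(expr)
    return frozenset(out)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

_CMP_FUNCS = {
    "=": lambda a, b: a == b,
    "!=": lambda a, b: a != b,
    ">=": lambda a, b: a >= b,
    "<=": lambda a, b: a <= b,
    ">": lambda a, b: a > b,
    "<": lambda a, b: a < b,
}


def _eval_raw(expr: RuleExpr, state: Mapping[str, float]) -> float:
    """Numeric value of a sub-expression; logical results are 0/1."""
    if isinstance(expr, Ref):
        return state[expr.name]
    if isinstance(expr, Num):
        return expr.value
    if isinstance(expr, Cmp):
        return 1 if _CMP_FUNCS[expr.op](state[expr.ref.name], expr.value) else 0
    if isinstance(expr, NotOp):
        return 0 if _truth(expr.operand, state) else 1
    if isinstance(expr, AndOp):
        return 1 if all(_truth(p, state) for p in expr.operands) else 0
    if isinstance(expr, OrOp):
        return 1 if any(_truth(p, state) for p in expr.operands) else 0
    if isinstance(expr, BinOp):
        a, b = _eval_raw(expr.left, state), _eval_raw(expr.right, state)
        if expr.op == "+":
            return a + b
        if expr.op == "-":
            return a - b
        return a * b
    raise TypeError(f"not a rule expression: {expr!r}")


def _truth(expr: RuleExpr, state: Mapping[str, float]) -> bool:
    # logical context: an arithmetic value is true iff strictly positive
    return _eval_raw(expr, state) > 0


def evaluate(expr: RuleExpr, state: Mapping[str, float],
             min_level: float | None = None,
             max_level: float | None = None) -> float:
    """Evaluate a rule, clamping the final value to the target's range.

    The clamp is applied once, to the completed value; intermediate
    sub-expressions are unrestricted.
    """
    value = _eval_raw(expr, state)
    if min_level is not None and value < min_level:
        value = min_level
    if max_level is not None and value > max_level:
        value = max_level
    return value


# ---------------------------------------------------------------------------
# Compilation (positional state vector -> Python closure)
# ---------------------------------------------------------------------------

def _codegen(expr: RuleExpr, index: Mapping[str, int]) -> str:
    """Python source for the numeric value of ``expr`` over state list ``s``."""
    if isinstance(expr, Ref):
        return f"s[{index[expr.name]}]"
    if isinstance(expr, Num):
        return f"({expr.value!r})"
    if isinstance(expr, Cmp):
        py = {"=": "=="}.get(expr.op, expr.op)
        return f"(s[{index[expr.ref.name]}] {py} {expr.value!r})"
    if isinstance(expr, NotOp):
        return f"(not {_truthgen(expr.operand, index)})"
    if isinstance(expr, AndOp):
        return "(" + " and ".join(_truthgen(p, index) for p in expr.operands) + ")"
    if isinstance(expr, OrOp):
        return "(" + " or ".join(_truthgen(p, index) for p in expr.operands) + ")"
    if isinstance(expr, BinOp):
        return f"({_codegen(expr.left, index)} {expr.op} {_codegen(expr.right, index)})"
    raise TypeError(f"not a rule expression: {expr!r}")


def _truthgen(expr: RuleExpr, index: Mapping[str, int]) -> str:
    if isinstance(expr, _LOGICAL):
        return _codegen(expr, index)  # already 0/1-valued (bool)
    return f"({_codegen(expr, index)} > 0)"


def compile_rule(expr: RuleExpr, index: Mapping[str, int],
                 min_level: float, max_level: float) -> Callable[[Sequence[float]], float]:
    """Compile an AST into ``f(state_vector) -> clamped level``.

    ``index`` maps node names to positions in the state vector.  The
    returned closure is semantically identical to :func:`evaluate` and is
    what the simulation engine calls in its inner loop.
    """
    src = f"lambda s: max({min_level!r}, min({max_level!r}, {_codegen(expr, index)}))"
    namespace = {"__builtins__": {"max": max, "min": min}, "inf": float("inf")}
    return eval(src, namespace)  # noqa: S307
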