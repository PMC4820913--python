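"""A small infix expression grammar.

Used to re-parse the right-hand sides printed into exported Octave/Matlab
and XPP files so their numerical behaviour can be checked against the
in-memory ODE system.  The grammar is written independently of the infix
printer: it is a conventional precedence-climbing parser over the target
languages' shared operator set.

Grammar (loosely)::

    expr    := or
    or      := and ( "|" and )*
    and     := cmp ( "&" cmp )*
    cmp     := add ( ("=="|"!="|"<="|">="|"<"|">") add )?
    add     := mul ( ("+"|"-") mul )*
    mul     := unary ( ("*"|"/") unary )*
    unary   := ("-"|"~")* pow
    pow     := atom ( "^" unary )?          # right-associative
    atom    := NUMBER | NAME | NAME "(" args ")" | "(" expr ")"

``NAME "(" INT ")"`` where NAME is not a known function is read as an
indexed symbol such as ``x(3)``; it becomes a symbol literally named
``x(3)``, matching the binding keys exporters document.
"""

from __future__ import annotations

import re

from .errors import MathError
from .mathexpr import MathNode, num, op, sym

__all__ = ["parse_infix"]

_FUNCTIONS = {
    "exp": "exp",
    "log": "ln",      # octave/matlab/xpp log is the natural logarithm
    "ln": "ln",
    "log10": "log10",
    "sqrt": "sqrt",
    "abs": "abs",
    "floor": "floor",
    "ceil": "ceiling",
    "ceiling": "ceiling",
    "sin": "sin",
    "cos": "cos",
    "tan": "tan",
}

_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<number>\d+\.\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?"
    r"|\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<sign>==|!=|<=|>=|<|>|[-+*/^(),&|~])"
    r")"
)


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise MathError(f"cannot tokenize {text[pos:pos + 20]!r}")
        tokens.append(m.group(m.lastgroup))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self, expected: str | None = None) -> str:
        tok = self.peek()
        if tok is None:
            raise MathError("unexpected end of expression")
        if expected is not None and tok != expected:
            raise MathError(f"expected {expected!r}, got {tok!r}")
        self.i += 1
        return tok

    # precedence levels, loosest first
    def expr(self) -> MathNode:
        return self.or_()

    def or_(self) -> MathNode:
        node = self.and_()
        while self.peek() == "|":
            self.take()
            node = op("or", node, self.and_())
        return node

    def and_(self) -> MathNode:
        node = self.cmp()
        while self.peek() == "&":
            self.take()
            node = op("and", node, self.cmp())
        return node

    def cmp(self) -> MathNode:
        node = self.add()
        tok = self.peek()
        rel = {"==": "eq", "!=": "neq", "<": "lt",
               "<=": "leq", ">": "gt", ">=": "geq"}
        if tok in rel:
            self.take()
            node = op(rel[tok], node, self.add())
        return node

    def add(self) -> MathNode:
        node = self.mul()
        while self.peek() in ("+", "-"):
            sign = self.take()
            rhs = self.mul()
            node = op("plus", node, rhs) if sign == "+" else op("minus", node, rhs)
        return node

    def mul(self) -> MathNode:
        node = self.unary()
        while self.peek() in ("*", "/"):
            sign = self.take()
            rhs = self.unary()
            node = op("times", node, rhs) if sign == "*" else op("divide", node, rhs)
        return node

    def unary(self) -> MathNode:
        if self.peek() == "-":
            self.take()
            return op("minus", self.unary())
        if self.peek() == "~":
            self.take()
            return op("not", self.unary())
        return self.pow()

    def pow(self) -> MathNode:
        node = self.atom()
        if self.peek() == "^":
            self.take()
            return op("power", node, self.unary())
        return node

    def atom(self) -> MathNode:
        tok = self.take()
        if tok == "(":
            node = self.expr()
            self.take(")")
            return node
        if re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", tok):
            if self.peek() == "(":
                self.take("(")
                if tok in _FUNCTIONS:
                    arg = self.expr()
                    self.take(")")
                    return op(_FUNCTIONS[tok], arg)
                # indexed symbol like x(3)
                index = self.take()
                if not re.fullmatch(r"\d+", index):
                    raise MathError(
                        f"{tok!r} is not a known function and {index!r} "
                        "is not an integer index"
                    )
                self.take(")")
                return sym(f"{tok}({index})")
            return sym(tok)
        try:
            return num(float(tok))
        except ValueError:
            raise MathError(f"unexpected token {tok!r}") from None


def parse_infix(text: str) -> MathNode:
    """Parse an infix expression in the exported-dialect grammar."""
    parser = _Parser(_tokenize(text))
    node = parser.expr()
    if parser.peek() is not None:
        raise MathError(
            f"trailing tokens after expression: {parser.tokens[parser.i:]!r}"
        )
    return node
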