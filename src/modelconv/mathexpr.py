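"""Operator-tree representation of kinetic-law mathematics.

Kinetic laws in SBML are content MathML; every exporter in this package
needs them as a tree it can print in a target-language dialect and evaluate
numerically.  :class:`MathNode` is that tree.  The supported operator
subset covers mass-action, Michaelis-Menten and Hill kinetics plus the
relational/piecewise constructs needed for switch-like rate laws:

========== =============================================================
kind       meaning
========== =============================================================
number     literal real; no children
symbol     free identifier (species, parameter, compartment, or ``t``)
operator   plus, minus, times, divide, power and the relational /
           logical operators (relations evaluate to 1.0 / 0.0)
function   exp, ln, log10, sqrt, abs, floor, ceiling, sin, cos, tan
piecewise  alternating (value, condition) children, optional trailing
           otherwise child
========== =============================================================

The MathML csymbol for simulation time maps to the symbol ``t``; the
avogadro csymbol maps to its numeric value.  Natural log is ``ln`` and is
printed as ``log(x)`` in the octave and xpp dialects (both target languages
use ``log`` for the natural logarithm); ``log10`` stays ``log10``.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

from .errors import (
    CycleError,
    DialectError,
    EvaluationError,
    MathError,
    UnsupportedConstructError,
)

__all__ = [
    "MathNode",
    "num",
    "sym",
    "op",
    "free_symbols",
    "parse_mathml",
    "serialize_mathml",
    "to_infix",
    "evaluate",
    "substitute",
    "structurally_equal",
    "format_number",
]

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_URL = "http://www.sbml.org/sbml/symbols/time"
AVOGADRO_URL = "http://www.sbml.org/sbml/symbols/avogadro"
AVOGADRO = 6.02214179e23

ARITHMETIC_OPS = {"plus", "minus", "times", "divide", "power"}
RELATIONAL_OPS = {"eq", "neq", "lt", "leq", "gt", "geq"}
LOGICAL_OPS = {"and", "or", "not"}
OPERATORS = ARITHMETIC_OPS | RELATIONAL_OPS | LOGICAL_OPS
FUNCTIONS = {"exp", "ln", "log10", "sqrt", "abs", "floor", "ceiling",
             "sin", "cos", "tan"}


@dataclass(frozen=True)
class MathNode:
    """Immutable expression-tree node; use :func:`num`/:func:`sym`/:func:`op`."""

    kind: str
    op: str = ""
    value: float = 0.0
    children: tuple = ()
    symbol_name: str = ""

    def __post_init__(self):
        k = self.kind
        n = len(self.children)
        if k in ("number", "symbol"):
            if n:
                raise MathError(f"{k} node must have zero children")
            if k == "symbol" and not self.symbol_name:
                raise MathError("symbol node needs a symbol_name")
        elif k == "operator":
            if self.op not in OPERATORS:
                raise MathError(f"unknown operator {self.op!r}")
            if self.op == "minus" and n not in (1, 2):
                raise MathError("minus takes 1 or 2 children")
            if self.op in ("divide", "power") and n != 2:
                raise MathError(f"{self.op} takes exactly 2 children")
            if self.op in ("plus", "times", "and", "or") and n < 2:
                raise MathError(f"{self.op} takes at least 2 children")
            if self.op in RELATIONAL_OPS and n != 2:
                raise MathError(f"{self.op} takes exactly 2 children")
            if self.op == "not" and n != 1:
                raise MathError("not takes exactly 1 child")
        elif k == "function":
            if self.op not in FUNCTIONS:
                raise MathError(f"unknown function {self.op!r}")
            if n != 1:
                raise MathError(f"function {self.op} takes exactly 1 child")
        elif k == "piecewise":
            if n < 2:
                raise MathError("piecewise needs at least one (value, condition) pair")
        else:
            raise MathError(f"unknown node kind {k!r}")

    # Convenience for building trees in fixtures and tests.
    def __add__(self, other):
        return op("plus", self, _coerce(other))

    def __mul__(self, other):
        return op("times", self, _coerce(other))

    def __sub__(self, other):
        return op("minus", self, _coerce(other))

    def __truediv__(self, other):
        return op("divide", self, _coerce(other))

    def __neg__(self):
        return op("minus", self)


def _coerce(x) -> MathNode:
    if isinstance(x, MathNode):
        return x
    if isinstance(x, (int, float)):
        return num(float(x))
    raise TypeError(f"cannot coerce {x!r} to MathNode")


def num(value: float) -> MathNode:
    return MathNode(kind="number", value=float(value))


def sym(name: str) -> MathNode:
    return MathNode(kind="symbol", symbol_name=name)


def op(operator: str, *children) -> MathNode:
    children = tuple(_coerce(c) for c in children)
    if operator in OPERATORS:
        return MathNode(kind="operator", op=operator, children=children)
    if operator in FUNCTIONS:
        return MathNode(kind="function", op=operator, children=children)
    if operator == "piecewise":
        return MathNode(kind="piecewise", children=children)
    raise MathError(f"unknown operator/function {operator!r}")


def free_symbols(node: MathNode) -> set[str]:
    """The exact set of symbol names occurring in the tree."""
    if node.kind == "symbol":
        return {node.symbol_name}
    out: set[str] = set()
    for child in node.children:
        out |= free_symbols(child)
    return out


def structurally_equal(a: MathNode, b: MathNode) -> bool:
    """Node-by-node equality (dataclass equality, spelled out for intent)."""
    return a == b


# ---------------------------------------------------------------------------
# MathML (content markup) reading and writing
# ---------------------------------------------------------------------------

_MATHML_OP_TAGS = {
    "plus": "plus", "minus": "minus", "times": "times", "divide": "divide",
    "power": "power", "eq": "eq", "neq": "neq", "lt": "lt", "leq": "leq",
    "gt": "gt", "geq": "geq", "and": "and", "or": "or", "not": "not",
}
_MATHML_FN_TAGS = {
    "exp": "exp", "ln": "ln", "abs": "abs", "floor": "floor",
    "ceiling": "ceiling", "sin": "sin", "cos": "cos", "tan": "tan",
}


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def parse_mathml(xml_fragment, function_defs: dict | None = None) -> MathNode:
    """Parse a content-MathML fragment into a :class:`MathNode`.

    ``xml_fragment`` may be a string or an already-parsed Element; a
    ``<math>`` wrapper element is unwrapped.  ``function_defs`` maps a
    function name to ``(arg_names, body)`` and is used to expand SBML
    function-definition applications inline.

    Raises :class:`~modelconv.errors.UnsupportedConstructError` for any
    MathML element outside the supported subset (naming the element).
    """
    if isinstance(xml_fragment, str):
        try:
            element = ET.fromstring(xml_fragment)
        except ET.ParseError as exc:
            raise MathError(f"malformed MathML: {exc}") from exc
    else:
        element = xml_fragment
    if _local(element.tag) == "math":
        children = list(element)
        if len(children) != 1:
            raise MathError("<math> must wrap exactly one expression")
        element = children[0]
    return _parse_element(element, function_defs or {})


def _parse_element(el, fdefs) -> MathNode:
    tag = _local(el.tag)
    if tag == "cn":
        return num(_parse_cn(el))
    if tag == "ci":
        name = (el.text or "").strip()
        if not name:
            raise MathError("<ci> with empty identifier")
        return sym(name)
    if tag == "csymbol":
        url = el.get("definitionURL", "")
        if url == TIME_URL:
            return sym("t")
        if url == AVOGADRO_URL:
            return num(AVOGADRO)
        raise UnsupportedConstructError(f"csymbol with definitionURL {url!r}")
    if tag == "apply":
        return _parse_apply(el, fdefs)
    if tag == "piecewise":
        return _parse_piecewise(el, fdefs)
    if tag in ("true", "false"):
        raise UnsupportedConstructError(f"boolean constant <{tag}>")
    raise UnsupportedConstructError(f"MathML element <{tag}>")


def _parse_cn(el) -> float:
    cn_type = el.get("type", "real")
    if cn_type == "e-notation":
        # <cn type="e-notation"> mantissa <sep/> exponent </cn>
        parts = list(el)
        if len(parts) != 1 or _local(parts[0].tag) != "sep":
            raise MathError("e-notation <cn> must contain a single <sep/>")
        mantissa = (el.text or "").strip()
        exponent = (parts[0].tail or "").strip()
        return float(mantissa) * 10.0 ** float(exponent)
    if cn_type in ("real", "integer", "double"):
        return float((el.text or "").strip())
    raise UnsupportedConstructError(f"<cn> of type {cn_type!r}")


def _parse_apply(el, fdefs) -> MathNode:
    items = list(el)
    if not items:
        raise MathError("empty <apply>")
    head, *args = items
    head_tag = _local(head.tag)

    if head_tag == "ci":  # user-defined function application
        fname = (head.text or "").strip()
        if fname not in fdefs:
            raise UnsupportedConstructError(
                f"application of undefined function {fname!r}"
            )
        params, body = fdefs[fname]
        parsed = [_parse_element(a, fdefs) for a in args]
        if len(parsed) != len(params):
            raise MathError(
                f"function {fname!r} takes {len(params)} arguments, "
                f"got {len(parsed)}"
            )
        return substitute(body, dict(zip(params, parsed)))

    parsed = [_parse_element(a, fdefs) for a in args]

    if head_tag == "log":
        # <log/> without logbase means log10; <logbase><cn>10</cn></logbase>
        # is the only accepted base.
        if parsed and _local(args[0].tag) == "logbase":
            base_children = list(args[0])
            if len(base_children) != 1:
                raise MathError("<logbase> must wrap one element")
            base = _parse_element(base_children[0], fdefs)
            if base.kind != "number" or base.value != 10.0:
                raise UnsupportedConstructError("<log> with non-10 logbase")
            parsed = parsed[1:]
        if len(parsed) != 1:
            raise MathError("<log> takes one argument")
        return op("log10", parsed[0])
    if head_tag == "root":
        if parsed and _local(args[0].tag) == "degree":
            deg_children = list(args[0])
            if len(deg_children) != 1:
                raise MathError("<degree> must wrap one element")
            degree = _parse_element(deg_children[0], fdefs)
            if degree.kind != "number" or degree.value != 2.0:
                raise UnsupportedConstructError("<root> with degree other than 2")
            parsed = parsed[1:]
        if len(parsed) != 1:
            raise MathError("<root> takes one argument")
        return op("sqrt", parsed[0])

    if head_tag in _MATHML_FN_TAGS:
        if len(parsed) != 1:
            raise MathError(f"<{head_tag}> takes one argument")
        return op(_MATHML_FN_TAGS[head_tag], parsed[0])
    if head_tag in _MATHML_OP_TAGS:
        name = _MATHML_OP_TAGS[head_tag]
        # MathML allows unary plus/times; normalize to the child itself.
        if name in ("plus", "times") and len(parsed) == 1:
            return parsed[0]
        return op(name, *parsed)
    raise UnsupportedConstructError(f"MathML operator <{head_tag}>")


def _parse_piecewise(el, fdefs) -> MathNode:
    children: list[MathNode] = []
    saw_otherwise = False
    for item in el:
        tag = _local(item.tag)
        if tag == "piece":
            if saw_otherwise:
                raise MathError("<piece> after <otherwise>")
            parts = list(item)
            if len(parts) != 2:
                raise MathError("<piece> must contain value and condition")
            children.append(_parse_element(parts[0], fdefs))
            children.append(_parse_element(parts[1], fdefs))
        elif tag == "otherwise":
            parts = list(item)
            if len(parts) != 1:
                raise MathError("<otherwise> must contain one element")
            children.append(_parse_element(parts[0], fdefs))
            saw_otherwise = True
        else:
            raise UnsupportedConstructError(f"element <{tag}> inside <piecewise>")
    return MathNode(kind="piecewise", children=tuple(children))


def parse_lambda(el, fdefs=None) -> tuple[list[str], MathNode]:
    """Parse a MathML ``<lambda>`` (inside ``<math>``) into (args, body)."""
    if isinstance(el, str):
        el = ET.fromstring(el)
    if _local(el.tag) == "math":
        children = list(el)
        if len(children) != 1:
            raise MathError("<math> must wrap exactly one expression")
        el = children[0]
    if _local(el.tag) != "lambda":
        raise MathError("expected <lambda>")
    args: list[str] = []
    body = None
    for item in el:
        tag = _local(item.tag)
        if tag == "bvar":
            parts = list(item)
            if len(parts) != 1 or _local(parts[0].tag) != "ci":
                raise MathError("<bvar> must wrap a single <ci>")
            args.append((parts[0].text or "").strip())
        else:
            if body is not None:
                raise MathError("<lambda> with more than one body expression")
            body = _parse_element(item, fdefs or {})
    if body is None:
        raise MathError("<lambda> without a body")
    return args, body


def serialize_mathml(node: MathNode, wrap: bool = True) -> str:
    """Serialize to content MathML; inverse of :func:`parse_mathml`."""
    body = _serialize(node, indent=1 if wrap else 0)
    if not wrap:
        return body
    return f'<math xmlns="{MATHML_NS}">\n{body}\n</math>'


_FN_TO_TAG = {v: k for k, v in _MATHML_FN_TAGS.items()}


def _serialize(node: MathNode, indent: int) -> str:
    pad = "  " * indent
    if node.kind == "number":
        return f"{pad}<cn> {format_number(node.value)} </cn>"
    if node.kind == "symbol":
        if node.symbol_name == "t":
            return (
                f'{pad}<csymbol encoding="text" definitionURL="{TIME_URL}">'
                " t </csymbol>"
            )
        return f"{pad}<ci> {node.symbol_name} </ci>"
    if node.kind == "piecewise":
        lines = [f"{pad}<piecewise>"]
        kids = node.children
        pairs, otherwise = divmod(len(kids), 2)
        for i in range(pairs):
            lines.append(f"{pad}  <piece>")
            lines.append(_serialize(kids[2 * i], indent + 2))
            lines.append(_serialize(kids[2 * i + 1], indent + 2))
            lines.append(f"{pad}  </piece>")
        if otherwise:
            lines.append(f"{pad}  <otherwise>")
            lines.append(_serialize(kids[-1], indent + 2))
            lines.append(f"{pad}  </otherwise>")
        lines.append(f"{pad}</piecewise>")
        return "\n".join(lines)
    # operator or function application
    if node.kind == "function" and node.op == "log10":
        head = "<log/>"
    elif node.kind == "function" and node.op == "sqrt":
        head = "<root/>"
    elif node.kind == "function":
        head = f"<{_FN_TO_TAG[node.op]}/>"
    else:
        head = f"<{node.op}/>"
    lines = [f"{pad}<apply>", f"{pad}  {head}"]
    lines += [_serialize(c, indent + 1) for c in node.children]
    lines.append(f"{pad}</apply>")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Number formatting: shortest decimal that round-trips the binary value
# ---------------------------------------------------------------------------

def format_number(value: float, dialect: str = "generic") -> str:
    """Deterministic shortest round-trip decimal; integers without a point.

    The xpp dialect forces e-notation for magnitudes outside [1e-4, 1e6]
    (XPP's parser dislikes very long exponent-free decimals); Python's repr
    already does this, so the rule only normalizes integral floats there.
    """
    if value != value:  # NaN
        raise MathError("cannot print NaN")
    if value in (math.inf, -math.inf):
        raise MathError("cannot print infinity")
    if value == int(value) and abs(value) < 1e16:
        iv = int(value)
        if dialect == "xpp" and (abs(value) >= 1e6 or (0 < abs(value) < 1e-4)):
            return repr(float(value)).replace("e+", "e")
        return str(iv)
    text = repr(float(value))
    return text.replace("e+", "e") if dialect == "xpp" else text


# ---------------------------------------------------------------------------
# Infix printing
# ---------------------------------------------------------------------------

DIALECTS = ("octave", "matlab", "xpp", "dot_label")

_REL_SIGNS = {"eq": "==", "neq": "!=", "lt": "<", "leq": "<=",
              "gt": ">", "geq": ">="}
# Natural log prints as log() in both octave and xpp (their log is ln).
_FN_NAMES = {"ln": "log", "log10": "log10", "ceiling": "ceil"}
_FN_NAMES_XPP = {"ln": "log", "log10": "log10", "ceiling": "ceil"}


def to_infix(node: MathNode, dialect: str, symbol_map: dict | None = None) -> str:
    """Print the tree in a target-language dialect.

    ``symbol_map`` renames free symbols at print time (used by exporters to
    map SBML ids to indexed state variables like ``x(3)``).  Piecewise and
    the relational/logical operators are printed as indicator arithmetic
    (conditions evaluate to 0/1 in all target languages), so the printed
    expression evaluates identically to :func:`evaluate` under any binding.
    """
    if dialect not in DIALECTS:
        raise DialectError(f"unknown dialect {dialect!r}")
    return _print(node, dialect, symbol_map or {})


def _paren_if_compound(node: MathNode, text: str) -> str:
    # Children that are themselves operator applications or piecewise get
    # parentheses unconditionally; precedence subtleties are never relied on.
    if node.kind in ("number", "symbol", "function"):
        return text
    return f"({text})"


def _print(node: MathNode, dialect: str, smap: dict) -> str:
    if node.kind == "number":
        return format_number(node.value, dialect)
    if node.kind == "symbol":
        return smap.get(node.symbol_name, node.symbol_name)

    def child(i) -> str:
        c = node.children[i]
        return _paren_if_compound(c, _print(c, dialect, smap))

    if node.kind == "function":
        if dialect == "dot_label":
            name = node.op
        else:
            name = _FN_NAMES.get(node.op, node.op)
        return f"{name}({_print(node.children[0], dialect, smap)})"

    if node.kind == "piecewise":
        if dialect == "dot_label":
            raise DialectError("piecewise is not printable as a dot label")
        return _print_piecewise(node, dialect, smap)

    o = node.op
    if o == "plus":
        return " + ".join(child(i) for i in range(len(node.children)))
    if o == "times":
        return " * ".join(child(i) for i in range(len(node.children)))
    if o == "minus":
        if len(node.children) == 1:
            return f"-{child(0)}"
        return f"{child(0)} - {child(1)}"
    if o == "divide":
        return f"{child(0)} / {child(1)}"
    if o == "power":
        return f"{child(0)}^{child(1)}"
    if o in _REL_SIGNS:
        if dialect == "dot_label":
            return f"{child(0)} {_REL_SIGNS[o]} {child(1)}"
        return f"({child(0)} {_REL_SIGNS[o]} {child(1)})"
    if o in ("and", "or", "not"):
        if dialect == "dot_label":
            raise DialectError(f"{o} is not printable as a dot label")
        return _print_logical(node, dialect, smap)
    raise DialectError(f"cannot print operator {o!r}")  # pragma: no cover


def _print_logical(node: MathNode, dialect: str, smap: dict) -> str:
    """Indicator arithmetic over {0,1}-valued operands."""
    def p(c):
        return _paren_if_compound(c, _print(c, dialect, smap))

    if node.op == "not":
        return f"(1 - {p(node.children[0])})"
    if node.op == "and":
        return "(" + " * ".join(p(c) for c in node.children) + ")"
    # or: fold pairwise a + b - a*b
    text = p(node.children[0])
    for c in node.children[1:]:
        q = p(c)
        text = f"({text} + {q} - {text} * {q})"
    return text


def _print_piecewise(node: MathNode, dialect: str, smap: dict) -> str:
    """Nested indicator form: c1*v1 + (1-c1)*(c2*v2 + ... (otherwise))."""
    kids = node.children
    pairs, has_otherwise = divmod(len(kids), 2)

    def p(c):
        return _paren_if_compound(c, _print(c, dialect, smap))

    text = p(kids[-1]) if has_otherwise else "0"
    for i in reversed(range(pairs)):
        value, cond = p(kids[2 * i]), p(kids[2 * i + 1])
        text = f"({cond} * {value} + (1 - {cond}) * ({text}))"
    return text


# ---------------------------------------------------------------------------
# Numeric evaluation
# ---------------------------------------------------------------------------

def evaluate(node: MathNode, bindings: dict[str, float]) -> float:
    """Evaluate with standard real arithmetic; relations give 1.0 / 0.0.

    Division by zero propagates IEEE infinity (NaN for 0/0).  An unbound
    symbol raises :class:`~modelconv.errors.EvaluationError` naming it.
    """
    if node.kind == "number":
        return node.value
    if node.kind == "symbol":
        try:
            return float(bindings[node.symbol_name])
        except KeyError:
            raise EvaluationError(
                f"unbound symbol {node.symbol_name!r}"
            ) from None
    if node.kind == "piecewise":
        kids = node.children
        pairs, has_otherwise = divmod(len(kids), 2)
        for i in range(pairs):
            if evaluate(kids[2 * i + 1], bindings) != 0.0:
                return evaluate(kids[2 * i], bindings)
        return evaluate(kids[-1], bindings) if has_otherwise else 0.0

    vals = [evaluate(c, bindings) for c in node.children]
    o = node.op
    if node.kind == "function":
        return _eval_function(o, vals[0])
    if o == "plus":
        return math.fsum(vals)
    if o == "times":
        out = 1.0
        for v in vals:
            out *= v
        return out
    if o == "minus":
        return -vals[0] if len(vals) == 1 else vals[0] - vals[1]
    if o == "divide":
        a, b = vals
        if b == 0.0:
            if a == 0.0:
                return math.nan
            return math.copysign(math.inf, a) * math.copysign(1.0, b)
        return a / b
    if o == "power":
        base, exponent = vals
        try:
            return math.pow(base, exponent)
        except OverflowError:
            return math.inf
        except ValueError:
            # math.pow raises for 0^negative (IEEE: infinity) and for a
            # negative base with fractional exponent (IEEE: NaN).
            return math.inf if base == 0.0 else math.nan
    if o in _REL_SIGNS:
        a, b = vals
        res = {
            "eq": a == b, "neq": a != b, "lt": a < b,
            "leq": a <= b, "gt": a > b, "geq": a >= b,
        }[o]
        return 1.0 if res else 0.0
    if o == "and":
        return 1.0 if all(v != 0.0 for v in vals) else 0.0
    if o == "or":
        return 1.0 if any(v != 0.0 for v in vals) else 0.0
    if o == "not":
        return 1.0 if vals[0] == 0.0 else 0.0
    raise EvaluationError(f"cannot evaluate operator {o!r}")  # pragma: no cover


def _eval_function(name: str, x: float) -> float:
    try:
        if name == "exp":
            return math.exp(x)
        if name == "ln":
            return math.log(x)
        if name == "log10":
            return math.log10(x)
        if name == "sqrt":
            return math.sqrt(x)
        if name == "abs":
            return abs(x)
        if name == "floor":
            return math.floor(x)
        if name == "ceiling":
            return math.ceil(x)
        if name == "sin":
            return math.sin(x)
        if name == "cos":
            return math.cos(x)
        if name == "tan":
            return math.tan(x)
    except OverflowError:
        return math.inf
    except ValueError:
        return math.nan
    raise EvaluationError(f"unknown function {name!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Substitution
# ---------------------------------------------------------------------------

def substitute(node: MathNode, replacements: dict[str, MathNode]) -> MathNode:
    """Replace symbols by subtrees; chains are resolved to a fixed point.

    After substitution the result contains no symbol from the replacement
    key set: a chain ``a -> b, b -> 3`` applied to ``a`` yields ``3``.  A
    cyclic map (``a -> b, b -> a``) raises
    :class:`~modelconv.errors.CycleError` listing the cycle.
    """
    if not replacements:
        return node
    resolved = _resolve_chains(replacements)
    return _subst(node, resolved)


def _resolve_chains(replacements: dict[str, MathNode]) -> dict[str, MathNode]:
    keys = set(replacements)
    # cycle detection over the dependency graph key -> (free symbols ∩ keys)
    color: dict[str, int] = {}  # 0 visiting, 1 done
    stack: list[str] = []
    resolved: dict[str, MathNode] = {}

    def visit(k: str) -> MathNode:
        if k in resolved:
            return resolved[k]
        if color.get(k) == 0:
            cycle = stack[stack.index(k):] + [k]
            raise CycleError(cycle)
        color[k] = 0
        stack.append(k)
        tree = replacements[k]
        deps = free_symbols(tree) & keys
        if deps:
            tree = _subst(tree, {d: visit(d) for d in deps})
        stack.pop()
        color[k] = 1
        resolved[k] = tree
        return tree

    for k in replacements:
        visit(k)
    return resolved


def _subst(node: MathNode, repl: dict[str, MathNode]) -> MathNode:
    if node.kind == "symbol":
        return repl.get(node.symbol_name, node)
    if not node.children:
        return node
    new_children = tuple(_subst(c, repl) for c in node.children)
    if new_children == node.children:
        return node
    return MathNode(
        kind=node.kind, op=node.op, value=node.value,
        children=new_children, symbol_name=node.symbol_name,
    )
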