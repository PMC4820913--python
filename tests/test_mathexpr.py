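"""Expression-tree behaviour: MathML round trips, dialect printing,
evaluation, and substitution."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modelconv.errors import CycleError, DialectError, EvaluationError, \
    UnsupportedConstructError
from modelconv.infix import parse_infix
from modelconv.mathexpr import (
    MathNode,
    evaluate,
    free_symbols,
    num,
    op,
    parse_mathml,
    serialize_mathml,
    substitute,
    sym,
    to_infix,
)

MM_TREE = op(
    "divide",
    op("times", sym("Vmax"), sym("S")),
    op("plus", sym("Km"), sym("S")),
)


# ---------------------------------------------------------------------------
# MathML parsing
# ---------------------------------------------------------------------------

class TestParseMathml:
    def test_single_operator_structure(self):
        node = parse_mathml(
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            "<apply><times/><ci>k</ci><ci>A</ci></apply></math>"
        )
        assert node == op("times", sym("k"), sym("A"))

    def test_number_literal(self):
        node = parse_mathml(
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            "<cn>2.5</cn></math>"
        )
        assert node == num(2.5)

    def test_e_notation_number(self):
        node = parse_mathml(
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            '<cn type="e-notation">1.5<sep/>3</cn></math>'
        )
        assert node.value == pytest.approx(1500.0)

    def test_michaelis_menten_fragment(self):
        fragment = (
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            "<apply><divide/>"
            "<apply><times/><ci>Vmax</ci><ci>S</ci></apply>"
            "<apply><plus/><ci>Km</ci><ci>S</ci></apply>"
            "</apply></math>"
        )
        assert parse_mathml(fragment) == MM_TREE

    def test_time_csymbol_maps_to_t(self):
        node = parse_mathml(
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            '<csymbol definitionURL="http://www.sbml.org/sbml/symbols/time">'
            "time</csymbol></math>"
        )
        assert node == sym("t")

    @pytest.mark.parametrize(
        "body, construct",
        [
            ("<apply><int/><ci>x</ci></apply>", "int"),
            ("<vector><cn>1</cn></vector>", "vector"),
            ("<apply><factorial/><cn>3</cn></apply>", "factorial"),
        ],
    )
    def test_unsupported_elements_are_named(self, body, construct):
        fragment = (
            f'<math xmlns="http://www.w3.org/1998/Math/MathML">{body}</math>'
        )
        with pytest.raises(UnsupportedConstructError, match=construct):
            parse_mathml(fragment)

    def test_log_without_base_means_log10(self):
        node = parse_mathml(
            '<math xmlns="http://www.w3.org/1998/Math/MathML">'
            "<apply><log/><ci>x</ci></apply></math>"
        )
        assert node == op("log10", sym("x"))


# ---------------------------------------------------------------------------
# Round trip: parse(serialize(n)) == n
# ---------------------------------------------------------------------------

_numbers = st.one_of(
    st.integers(min_value=-50, max_value=50).map(lambda i: num(float(i))),
    st.floats(min_value=-100, max_value=100, allow_nan=False,
              allow_infinity=False).map(num),
)
_symbols = st.sampled_from(["k", "A", "B", "Km", "Vmax", "t"]).map(sym)
_leaves = st.one_of(_numbers, _symbols)


def _compound(children):
    return st.one_of(
        st.tuples(children, children).map(lambda c: op("plus", *c)),
        st.tuples(children, children).map(lambda c: op("times", *c)),
        st.tuples(children, children).map(lambda c: op("minus", *c)),
        st.tuples(children, children).map(lambda c: op("divide", *c)),
        children.map(lambda c: op("minus", c)),
        children.map(lambda c: op("exp", c)),
        children.map(lambda c: op("abs", c)),
        st.tuples(children, children, children).map(
            lambda c: op("piecewise", c[0], op("lt", c[1], c[2]), c[1])
        ),
    )


_trees = st.recursive(_leaves, _compound, max_leaves=12)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(_trees)
def test_mathml_round_trip(tree):
    assert parse_mathml(serialize_mathml(tree)) == tree


# ---------------------------------------------------------------------------
# Infix printing
# ---------------------------------------------------------------------------

class TestToInfix:
    def test_simple_product(self):
        assert to_infix(op("times", sym("k"), sym("A")), "octave") == "k * A"

    @pytest.mark.parametrize("dialect", ["octave", "xpp"])
    def test_power_prints_caret(self, dialect):
        assert to_infix(op("power", sym("S"), num(2)), dialect) == "S^2"

    def test_piecewise_truth_table_matches_evaluator(self):
        node = op("piecewise", num(1.0), op("lt", sym("t"), num(5.0)), num(0.0))
        printed = to_infix(node, "octave")
        for t in (3.0, 5.0, 7.0):
            want = evaluate(node, {"t": t})
            got = evaluate(parse_infix(printed), {"t": t})
            assert got == want
        assert evaluate(node, {"t": 3.0}) == 1.0
        assert evaluate(node, {"t": 7.0}) == 0.0

    def test_piecewise_is_unprintable_as_dot_label(self):
        node = op("piecewise", num(1.0), op("lt", sym("t"), num(5.0)), num(0.0))
        with pytest.raises(DialectError):
            to_infix(node, "dot_label")

    def test_symbol_map_renames_at_print_time(self):
        node = op("times", sym("k"), sym("A"))
        assert to_infix(node, "octave", {"A": "x(1)"}) == "k * x(1)"

    def test_natural_log_prints_as_log(self):
        assert to_infix(op("ln", sym("x")), "octave") == "log(x)"
        assert to_infix(op("log10", sym("x")), "xpp") == "log10(x)"


@settings(max_examples=200, derandomize=True, deadline=None)
@given(_trees, st.integers(min_value=0, max_value=10_000))
def test_dialect_fidelity(tree, seed):
    """Printed expression, re-parsed by the independent infix grammar,
    evaluates identically to the tree (within 1e-12 relative)."""
    rng = random.Random(seed)
    for dialect in ("octave", "xpp"):
        printed = to_infix(tree, dialect)
        reparsed = parse_infix(printed)
        for _ in range(5):
            bindings = {name: rng.uniform(0.1, 10.0)
                        for name in free_symbols(tree)}
            want = evaluate(tree, bindings)
            got = evaluate(reparsed, bindings)
            if math.isnan(want):
                assert math.isnan(got)
            elif math.isinf(want):
                assert got == want
            else:
                assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _independent_eval(node, env):
    """Second, independently coded evaluator (oracle for evaluate())."""
    import functools
    import operator as _op

    if node.kind == "number":
        return node.value
    if node.kind == "symbol":
        return env[node.symbol_name]
    if node.kind == "piecewise":
        kids = list(node.children)
        while len(kids) >= 2:
            value, cond = kids[0], kids[1]
            if _independent_eval(cond, env):
                return _independent_eval(value, env)
            kids = kids[2:]
        return _independent_eval(kids[0], env) if kids else 0.0
    vals = [_independent_eval(c, env) for c in node.children]
    table = {
        "plus": lambda v: math.fsum(v),
        "times": lambda v: functools.reduce(_op.mul, v, 1.0),
        "minus": lambda v: -v[0] if len(v) == 1 else v[0] - v[1],
        "divide": lambda v: v[0] / v[1],
        "power": lambda v: v[0] ** v[1],
        "exp": lambda v: math.exp(v[0]),
        "abs": lambda v: abs(v[0]),
        "lt": lambda v: float(v[0] < v[1]),
        "leq": lambda v: float(v[0] <= v[1]),
        "gt": lambda v: float(v[0] > v[1]),
        "geq": lambda v: float(v[0] >= v[1]),
        "eq": lambda v: float(v[0] == v[1]),
        "neq": lambda v: float(v[0] != v[1]),
    }
    return table[node.op](vals)


class TestEvaluate:
    def test_product_of_constants(self):
        assert evaluate(op("times", num(2), num(3)), {}) == 6.0

    def test_michaelis_menten_value(self):
        assert evaluate(MM_TREE, {"Vmax": 10, "Km": 2, "S": 2}) == 5.0

    def test_unbound_symbol_is_named(self):
        with pytest.raises(EvaluationError, match="Km"):
            evaluate(MM_TREE, {"Vmax": 1, "S": 1})

    def test_division_by_zero_gives_infinity(self):
        assert evaluate(op("divide", num(1), num(0)), {}) == math.inf
        assert evaluate(op("divide", num(-1), num(0)), {}) == -math.inf


@settings(max_examples=300, derandomize=True, deadline=None)
@given(_trees, st.integers(min_value=0, max_value=10_000))
def test_evaluate_agrees_with_independent_evaluator(tree, seed):
    rng = random.Random(seed)
    env = {name: rng.uniform(0.5, 5.0) for name in free_symbols(tree)}
    try:
        want = _independent_eval(tree, env)
    except (ZeroDivisionError, OverflowError):
        return  # oracle hit an IEEE edge the tolerant evaluator absorbs
    if isinstance(want, complex):
        return  # negative base, fractional exponent; evaluator yields NaN
    got = evaluate(tree, env)
    if math.isnan(want):
        assert math.isnan(got)
    else:
        assert got == pytest.approx(want, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# Substitution
# ---------------------------------------------------------------------------

class TestSubstitute:
    def test_symbol_replaced_by_number(self):
        node = op("times", sym("k"), sym("A"))
        assert substitute(node, {"k": num(2)}) == op("times", num(2), sym("A"))

    def test_empty_map_is_identity(self):
        assert substitute(MM_TREE, {}) == MM_TREE

    def test_chain_resolves_to_fixed_point(self):
        result = substitute(sym("a"), {"a": sym("b"), "b": num(3)})
        assert result == num(3)

    def test_cycle_raises_listing_the_cycle(self):
        with pytest.raises(CycleError) as err:
            substitute(sym("a"), {"a": sym("b"), "b": sym("a")})
        assert set(err.value.cycle) >= {"a", "b"}

    def test_result_never_contains_replaced_symbols(self):
        repl = {"Km": op("times", num(2), sym("base")), "Vmax": sym("Km")}
        result = substitute(MM_TREE, repl)
        assert free_symbols(result).isdisjoint(repl.keys())

    def test_substitution_commutes_with_evaluation(self):
        repl = {"Km": op("plus", num(1), num(1))}
        bindings = {"Vmax": 10.0, "S": 2.0}
        direct = evaluate(substitute(MM_TREE, repl), bindings)
        merged = evaluate(MM_TREE, {**bindings, "Km": 2.0})
        assert direct == merged


def test_free_symbols_is_exact():
    assert free_symbols(MM_TREE) == {"Vmax", "Km", "S"}
    assert free_symbols(num(1.0)) == set()


def test_arity_invariants_enforced():
    with pytest.raises(Exception):
        MathNode(kind="operator", op="divide", children=(num(1),))
    with pytest.raises(Exception):
        MathNode(kind="number", value=1.0, children=(num(1),))
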