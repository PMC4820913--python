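"""Shared fixtures and oracle helpers for the test-suite.

The exported-code checks all follow the same dual route: the package
prints an expression, the tests re-parse it with the (independent) infix
grammar and evaluate it, and the result must agree with the in-memory
right-hand side.  The helpers implementing that route live here so every
test file uses the same machinery.
"""

from __future__ import annotations

import random
import re

import pytest

from modelconv.infix import parse_infix
from modelconv.mathexpr import evaluate
from modelconv.ode import OdeSystem, rhs
from modelconv.synthetic import corpus


@pytest.fixture(scope="session")
def corpus_models():
    return corpus()


def random_state(system: OdeSystem, rng: random.Random,
                 low: float = 0.05, high: float = 20.0) -> dict:
    return {sid: rng.uniform(low, high) for sid in system.all_state_ids}


# -- exported-file re-parsing ------------------------------------------------

_XDOT_RE = re.compile(r"xdot\((\d+)\) = (.*);")
_XPP_ODE_RE = re.compile(r"d(\w+)/dt=(.*)")
_XPP_MAP_RE = re.compile(r"#   (\S+) = (\S+)")
_X0_RE = re.compile(r"x0\((\d+)\) = (.*);")
_XPP_INIT_RE = re.compile(r"init (\w+)=(.*)")


def octave_derivatives(text: str) -> dict[int, object]:
    """index (1-based) -> parsed derivative expression from an m-file."""
    return {int(i): parse_infix(expr) for i, expr in _XDOT_RE.findall(text)}


def octave_initials(text: str) -> dict[int, float]:
    return {int(i): float(expr) for i, expr in _X0_RE.findall(text)}


def octave_rhs_from_text(text: str, system: OdeSystem, state: dict,
                         t: float) -> dict[str, float]:
    """Evaluate an exported m-file's derivative lines at a given state."""
    exprs = octave_derivatives(text)
    ids = system.all_state_ids
    bindings = {f"x({i + 1})": state[sid] for i, sid in enumerate(ids)}
    bindings["t"] = t
    out = {}
    for i, sid in enumerate(ids):
        node = exprs.get(i + 1)
        out[sid] = 0.0 if node is None else evaluate(node, bindings)
    return out


def xpp_name_map(text: str) -> dict[str, str]:
    """original id -> exported XPP name, from the header comments."""
    return {orig: name for name, orig in _XPP_MAP_RE.findall(text)}


def xpp_rhs_from_text(text: str, system: OdeSystem, state: dict,
                      t: float) -> dict[str, float]:
    """Evaluate an exported .ode file's ODE lines at a given state."""
    name_of = xpp_name_map(text)
    odes = {name: parse_infix(expr) for name, expr in _XPP_ODE_RE.findall(text)}
    bindings = {name_of[sid]: state[sid] for sid in system.all_state_ids}
    bindings["t"] = t
    return {
        sid: evaluate(odes[name_of[sid]], bindings)
        for sid in system.all_state_ids
    }


def max_export_deviation(text: str, system: OdeSystem, flavor: str,
                         rng: random.Random, n_states: int = 100) -> float:
    """Max |exported RHS - in-memory rhs| over random states."""
    worst = 0.0
    from_text = octave_rhs_from_text if flavor == "octave" else xpp_rhs_from_text
    for _ in range(n_states):
        state = random_state(system, rng)
        t = rng.uniform(0.0, 10.0)
        want = rhs(system, state, t)
        got = from_text(text, system, state, t)
        for sid in system.all_state_ids:
            worst = max(worst, abs(got[sid] - want[sid]))
    return worst
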