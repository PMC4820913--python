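"""Executable ODE code generation: Octave/Matlab m-files and XPP .ode files.

Both exporters work from the :class:`~modelconv.ode.OdeSystem` derived by
:func:`~modelconv.ode.build_ode_system`.  Constants (global parameters,
compartment sizes, fixed species) are substituted numerically into the
rate expressions, so the emitted right-hand sides close over the state
variables and time only; that keeps the generated files self-contained and
lets the test-suite re-parse and evaluate them without a numerical
environment installed.  Output is byte-deterministic.

SBML identifiers are not always legal Octave or XPP names, so each export
carries an :class:`IdentifierMap` — an injective, deterministic renaming
recorded in the file header.  XPP names are limited to 9 characters:
sanitized names are truncated to 7 and suffixed with a 2-digit counter on
collision (checked case-insensitively, since XPP is case-insensitive).
"""

from __future__ import annotations

import re

from .errors import SanitizationError
from .mathexpr import MathNode, format_number, num, substitute, to_infix
from .ode import OdeSystem
from .sbml import SbmlModel

__all__ = ["IdentifierMap", "sanitize_identifier", "to_octave", "to_xpp"]

_XPP_MAX = 9
_XPP_TRUNC = 7


def sanitize_identifier(identifier: str) -> str:
    """Map an arbitrary id to the common letters/digits/underscore grammar."""
    out = re.sub(r"[^A-Za-z0-9_]", "_", identifier)
    if not out or out[0].isdigit():
        out = "x" + out
    return out


class IdentifierMap:
    """Injective original-id -> sanitized-id mapping for one export."""

    def __init__(self, ids, max_length: int | None = None,
                 reserved: tuple[str, ...] = ("t",)):
        self.mapping: dict[str, str] = {}
        # "t" is the time symbol in every dialect and must stay free.
        taken: set[str] = {
            r.casefold() if max_length is not None else r for r in reserved
        }
        for identifier in ids:
            name = sanitize_identifier(identifier)
            if max_length is not None and len(name) > max_length:
                name = name[:_XPP_TRUNC]
            key = name.casefold() if max_length is not None else name
            if key in taken:
                base = name[:_XPP_TRUNC] if max_length is not None else name
                for counter in range(1, 100):
                    candidate = f"{base}{counter:02d}"
                    key = (candidate.casefold() if max_length is not None
                           else candidate)
                    if key not in taken and (
                        max_length is None or len(candidate) <= max_length
                    ):
                        name = candidate
                        break
                else:
                    raise SanitizationError(
                        f"cannot find a collision-free name for {identifier!r}"
                    )
            taken.add(key)
            self.mapping[identifier] = name

    def __getitem__(self, identifier: str) -> str:
        return self.mapping[identifier]

    def items(self):
        return self.mapping.items()


def _inline_constants(expr: MathNode, constants: dict[str, float]) -> MathNode:
    replacements = {k: num(v) for k, v in constants.items()}
    return substitute(expr, replacements)


# ---------------------------------------------------------------------------
# Octave / Matlab
# ---------------------------------------------------------------------------

_SOLVER_BOILERPLATE = {
    "octave": [
        "% Example solver invocation (GNU Octave, not executed):",
        "%   x0 = init_state();",
        "%   [x, t] = lsode(@(x, t) rhs_state(t, x), x0, linspace(0, 10, 101));",
    ],
    "matlab": [
        "% Example solver invocation (Matlab, not executed):",
        "%   x0 = init_state();",
        "%   [t, x] = ode45(@rhs_state, [0, 10], x0);",
    ],
}


def to_octave(system: OdeSystem, model: SbmlModel, dialect: str = "octave") -> str:
    """Emit a self-contained m-file for the derived ODE system.

    The file defines ``init_state()`` (initial-condition column vector) and
    ``rhs_state(t, x)`` (derivatives), with one ``xdot(i) = ...`` line per
    state generated through the infix printer over indexed state variables
    ``x(i)``.  The header comments carry the identifier map and the
    constant values that were inlined.  The octave and matlab dialects
    differ only in the commented solver-invocation boilerplate.
    """
    if dialect not in ("octave", "matlab"):
        raise ValueError(f"dialect must be octave or matlab, got {dialect!r}")
    ids = system.all_state_ids
    idmap = IdentifierMap(ids)
    index = {sid: i + 1 for i, sid in enumerate(ids)}
    symbol_map = {sid: f"x({index[sid]})" for sid in ids}

    lines: list[str] = []
    lines.append(f"% ODE model generated from SBML model '{model.id}'")
    lines.append(f"% dialect: {dialect}")
    lines.append("%")
    lines.append("% state vector:")
    for sid in ids:
        tag = " (rate rule)" if sid in system.rate_rules else ""
        lines.append(f"%   x({index[sid]}) = {idmap[sid]}  [{sid}]{tag}")
    if system.constants:
        lines.append("% constants (inlined numerically):")
        for cid, value in system.constants.items():
            lines.append(f"%   {cid} = {format_number(value)}")
    lines.append("%")
    lines.extend(_SOLVER_BOILERPLATE[dialect])
    lines.append("")
    lines.append("function x0 = init_state()")
    lines.append(f"  x0 = zeros({len(ids)}, 1);")
    for sid in ids:
        value = system.initial_state.get(sid, 0.0)
        lines.append(f"  x0({index[sid]}) = {format_number(value)};")
    lines.append("end")
    lines.append("")
    lines.append("function xdot = rhs_state(t, x)")
    lines.append(f"  xdot = zeros({len(ids)}, 1);")
    for i, sid in enumerate(system.state_ids):
        expr = _state_derivative(system, i)
        printed = to_infix(expr, "octave", symbol_map)
        lines.append(f"  xdot({index[sid]}) = {printed};")
    for vid, expr in system.rate_rules.items():
        inlined = _inline_constants(expr, system.constants)
        printed = to_infix(inlined, "octave", symbol_map)
        lines.append(f"  xdot({index[vid]}) = {printed};")
    lines.append("end")
    return "\n".join(lines) + "\n"


def _state_derivative(system: OdeSystem, row: int) -> MathNode:
    """Symbolic dx_i/dt = sum_j N_ij * v_j with constants inlined."""
    terms: list[MathNode] = []
    for j, rate in enumerate(system.rates):
        coeff = system.stoichiometry[row, j]
        if coeff == 0.0:
            continue
        inlined = _inline_constants(rate, system.constants)
        if coeff == 1.0:
            terms.append(inlined)
        elif coeff == -1.0:
            terms.append(MathNode(kind="operator", op="minus",
                                  children=(inlined,)))
        else:
            terms.append(
                MathNode(kind="operator", op="times",
                         children=(num(coeff), inlined))
            )
    if not terms:
        return num(0.0)
    if len(terms) == 1:
        return terms[0]
    return MathNode(kind="operator", op="plus", children=tuple(terms))


# ---------------------------------------------------------------------------
# XPP
# ---------------------------------------------------------------------------

def to_xpp(system: OdeSystem, model: SbmlModel) -> str:
    """Emit an XPPAUT .ode file for the derived ODE system.

    One ``d<name>/dt=<expr>`` and one ``init <name>=<value>`` line per
    state (including rate-rule variables), one ``param <name>=<value>``
    line per constant, and a terminating ``done``.  Names are sanitized to
    at most 9 characters; the header comments record the renaming.
    Constants are also inlined numerically into the rate expressions so
    the ODE lines stand on their own.
    """
    ids = system.all_state_ids
    idmap = IdentifierMap(list(ids) + list(system.constants),
                          max_length=_XPP_MAX)
    symbol_map = {sid: idmap[sid] for sid in ids}

    lines: list[str] = []
    lines.append(f"# XPP ODE file generated from SBML model '{model.id}'")
    lines.append("# name map:")
    for sid in ids:
        tag = " (rate rule)" if sid in system.rate_rules else ""
        lines.append(f"#   {idmap[sid]} = {sid}{tag}")
    for cid in system.constants:
        lines.append(f"#   {idmap[cid]} = {cid} (constant)")
    for i, sid in enumerate(system.state_ids):
        expr = _state_derivative(system, i)
        printed = to_infix(expr, "xpp", symbol_map)
        lines.append(f"d{idmap[sid]}/dt={printed}")
    for vid, expr in system.rate_rules.items():
        inlined = _inline_constants(expr, system.constants)
        printed = to_infix(inlined, "xpp", symbol_map)
        lines.append(f"d{idmap[vid]}/dt={printed}")
    for sid in ids:
        value = system.initial_state.get(sid, 0.0)
        lines.append(f"init {idmap[sid]}={format_number(value, 'xpp')}")
    for cid, value in system.constants.items():
        lines.append(f"param {idmap[cid]}={format_number(value, 'xpp')}")
    lines.append("done")
    return "\n".join(lines) + "\n"
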