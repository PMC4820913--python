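"""Derive the dynamical system implied by an SBML reaction network.

For a network with state vector ``x`` (the dynamic species), stoichiometry
matrix ``N`` (species x reactions, net product-minus-reactant coefficients)
and reaction rate vector ``v(x, t)`` (the kinetic laws), the system is

    dx/dt = N . v(x, t)

plus one extra ODE per rate rule.  A species is dynamic iff it is neither
a boundary condition nor constant and is not governed by an assignment
rule.  Kinetic laws are used as written (SBML defines them in amount per
time); the state variable is the species' amount if ``initialAmount`` is
given, otherwise its concentration, and compartment sizes enter as plain
constants.  Local kinetic-law parameters are substituted numerically and
assignment-rule variables symbolically, so each rate expression closes
over states, constants and ``t`` only.

The left-null vectors of ``N`` are the network's conservation laws:
``c . N = 0`` implies ``c . x`` is constant along trajectories, which the
test-suite uses as an independent correctness oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import CycleError, EvaluationError, MissingKineticsError
from .mathexpr import MathNode, evaluate, free_symbols, num, substitute
from .sbml import SbmlModel

__all__ = ["OdeSystem", "build_ode_system", "rhs", "conservation_laws"]


@dataclass
class OdeSystem:
    """Ordered dynamical system derived from a reaction network.

    ``state_ids`` are the dynamic species in document order;
    ``rate_rule_ids`` are additional ODE variables (species or parameters
    governed by rate rules), which exporters emit as state lines too.
    ``initial_state`` covers both groups.
    """

    state_ids: list[str]
    reaction_ids: list[str]
    stoichiometry: np.ndarray  # shape (len(state_ids), len(reaction_ids))
    rates: list[MathNode]      # one per reaction, closed over states/constants/t
    rate_rules: dict[str, MathNode] = field(default_factory=dict)
    initial_state: dict[str, float] = field(default_factory=dict)
    constants: dict[str, float] = field(default_factory=dict)

    @property
    def rate_rule_ids(self) -> list[str]:
        return list(self.rate_rules)

    @property
    def all_state_ids(self) -> list[str]:
        return self.state_ids + self.rate_rule_ids


def build_ode_system(model: SbmlModel) -> OdeSystem:
    """Derive the :class:`OdeSystem` for a supported-subset SBML model.

    Raises :class:`~modelconv.errors.MissingKineticsError` if a reaction
    that moves a dynamic species lacks a kinetic law, and
    :class:`~modelconv.errors.CycleError` for cyclic assignment rules.
    """
    assignment_rules = {
        r.variable: r.math for r in model.rules if r.rule_type == "assignment"
    }
    rate_rule_math = {
        r.variable: r.math for r in model.rules if r.rule_type == "rate"
    }

    species_by_id = {s.id: s for s in model.species}
    state_ids = [
        s.id
        for s in model.species
        if not s.boundary_condition
        and not s.constant
        and s.id not in assignment_rules
        and s.id not in rate_rule_math
    ]

    # Constants: compartment sizes, plain global parameters, and fixed
    # (boundary/constant) species not governed by any rule.
    constants: dict[str, float] = {}
    for c in model.compartments:
        if c.id not in assignment_rules and c.id not in rate_rule_math:
            constants[c.id] = 1.0 if c.size is None else c.size
    for p in model.parameters:
        if p.id in assignment_rules or p.id in rate_rule_math:
            continue
        if p.value is None:
            warnings.warn(f"parameter {p.id!r} has no value; defaulting to 0")
        constants[p.id] = 0.0 if p.value is None else p.value
    for s in model.species:
        if s.id in state_ids or s.id in assignment_rules or s.id in rate_rule_math:
            continue
        constants[s.id] = _initial_value(s)

    # Initial values for states and rate-rule variables (initial
    # assignments override, evaluated over constants + raw initials).
    initial_state: dict[str, float] = {}
    for sid in state_ids:
        initial_state[sid] = _initial_value(species_by_id[sid])
    for vid in rate_rule_math:
        if vid in species_by_id:
            initial_state[vid] = _initial_value(species_by_id[vid])
        else:
            par = next((p for p in model.parameters if p.id == vid), None)
            if par is not None:
                initial_state[vid] = 0.0 if par.value is None else par.value
            else:  # a compartment under a rate rule
                comp = next(c for c in model.compartments if c.id == vid)
                initial_state[vid] = 1.0 if comp.size is None else comp.size
    if model.initial_assignments:
        env = dict(constants)
        env.update(initial_state)
        for ia in model.initial_assignments:
            value = evaluate(ia.math, env)
            if ia.variable in initial_state:
                initial_state[ia.variable] = value
            else:
                constants[ia.variable] = value

    # Resolve assignment rules to closed form (detects cycles), then build
    # per-reaction rate expressions with locals substituted numerically.
    closed_assignments = _close_assignments(assignment_rules)

    reaction_ids = [r.id for r in model.reactions]
    rates: list[MathNode] = []
    n = np.zeros((len(state_ids), len(model.reactions)))
    state_index = {sid: i for i, sid in enumerate(state_ids)}
    for j, reaction in enumerate(model.reactions):
        touches_dynamic = False
        for ref in reaction.reactants:
            if ref.species in state_index:
                n[state_index[ref.species], j] -= ref.stoichiometry
                touches_dynamic = True
        for ref in reaction.products:
            if ref.species in state_index:
                n[state_index[ref.species], j] += ref.stoichiometry
                touches_dynamic = True
        if reaction.kinetic_law is None:
            if touches_dynamic:
                raise MissingKineticsError(
                    f"reaction {reaction.id!r} moves a dynamic species but "
                    "has no kinetic law"
                )
            rates.append(num(0.0))
            continue
        expr = reaction.kinetic_law.math
        locals_ = {
            k: num(v) for k, v in reaction.kinetic_law.local_parameters.items()
        }
        if locals_:
            expr = substitute(expr, locals_)
        expr = substitute(expr, closed_assignments)
        rates.append(expr)

    rate_rules = {
        vid: substitute(math, closed_assignments)
        for vid, math in rate_rule_math.items()
    }

    system = OdeSystem(
        state_ids=state_ids,
        reaction_ids=reaction_ids,
        stoichiometry=n,
        rates=rates,
        rate_rules=rate_rules,
        initial_state=initial_state,
        constants=constants,
    )
    _check_closure(system)
    return system


def _initial_value(species) -> float:
    if species.initial_amount is not None:
        return species.initial_amount
    if species.initial_concentration is not None:
        return species.initial_concentration
    warnings.warn(
        f"species {species.id!r} has no initial amount or concentration; "
        "defaulting to 0"
    )
    return 0.0


def _close_assignments(assignment_rules: dict[str, MathNode]) -> dict[str, MathNode]:
    """Resolve assignment rules into closed-form replacement trees."""
    if not assignment_rules:
        return {}
    try:
        closed = {}
        for var in assignment_rules:
            closed[var] = substitute(assignment_rules[var], assignment_rules)
        return closed
    except CycleError:
        raise


def _check_closure(system: OdeSystem) -> None:
    allowed = set(system.all_state_ids) | set(system.constants) | {"t"}
    for rid, expr in zip(system.reaction_ids, system.rates):
        extra = free_symbols(expr) - allowed
        if extra:
            raise EvaluationError(
                f"rate of reaction {rid!r} references unknown symbols "
                f"{sorted(extra)}"
            )
    for vid, expr in system.rate_rules.items():
        extra = free_symbols(expr) - allowed
        if extra:
            raise EvaluationError(
                f"rate rule for {vid!r} references unknown symbols "
                f"{sorted(extra)}"
            )


def rhs(system: OdeSystem, state: dict[str, float], t: float = 0.0
        ) -> dict[str, float]:
    """Evaluate dx/dt = N.v(x, t) plus rate-rule derivatives.

    ``state`` must bind every id in :attr:`OdeSystem.all_state_ids`.
    """
    bindings = dict(system.constants)
    for sid in system.all_state_ids:
        if sid not in state:
            raise EvaluationError(f"state id {sid!r} not bound")
        bindings[sid] = state[sid]
    bindings["t"] = t
    v = np.array([evaluate(expr, bindings) for expr in system.rates])
    dx = system.stoichiometry @ v if len(system.rates) else np.zeros(
        len(system.state_ids)
    )
    out = {sid: float(dx[i]) for i, sid in enumerate(system.state_ids)}
    for vid, expr in system.rate_rules.items():
        out[vid] = evaluate(expr, bindings)
    return out


def conservation_laws(system: OdeSystem, tol: float = 1e-10) -> np.ndarray:
    """Left-null-space basis of the stoichiometry matrix (rows are laws)."""
    n = system.stoichiometry
    if n.size == 0:
        return np.eye(len(system.state_ids))
    ns = scipy.linalg.null_space(n.T, rcond=tol)
    return ns.T
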