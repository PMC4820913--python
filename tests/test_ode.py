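"""ODE derivation: stoichiometry, rates, conservation laws."""

import random

import numpy as np
import pytest

from modelconv.errors import CycleError, MissingKineticsError
from modelconv.mathexpr import num, op, sym
from modelconv.ode import build_ode_system, conservation_laws, rhs
from modelconv.sbml import (
    Compartment,
    KineticLaw,
    Reaction,
    Rule,
    SbmlModel,
    Species,
    SpeciesReference,
)
from modelconv.synthetic import NetworkSpec, corpus, generate_model

from conftest import random_state


@pytest.fixture
def ab_system(corpus_models):
    return build_ode_system(dict(corpus_models)["ab_mass_action"])


class TestBuild:
    def test_smallest_network_structure(self, ab_system):
        assert ab_system.state_ids == ["A", "B"]
        assert ab_system.stoichiometry.tolist() == [[-1.0], [1.0]]
        assert ab_system.initial_state == {"A": 10.0, "B": 0.0}
        # rate is k*A with the global k kept symbolic in constants
        assert ab_system.constants["k"] == 2.0
        assert ab_system.rates[0] == op("times", sym("k"), sym("A"))

    def test_rhs_at_initial_state(self, ab_system):
        out = rhs(ab_system, {"A": 10.0, "B": 0.0})
        assert out == {"A": -20.0, "B": 20.0}

    def test_boundary_and_constant_species_are_not_states(self, corpus_models):
        system = build_ode_system(dict(corpus_models)["with_modifiers"])
        assert "E" not in system.state_ids  # boundary condition
        assert system.constants["E"] == 0.5
        system2 = build_ode_system(dict(corpus_models)["constant_only"])
        assert system2.state_ids == ["Y"]
        assert system2.constants["X"] == 1.0

    def test_local_parameters_substituted_numerically(self, corpus_models):
        system = build_ode_system(dict(corpus_models)["closed_cascade"])
        assert system.rates[0] == op("times", num(1.0), sym("A"))

    def test_assignment_rules_inlined_symbolically(self, corpus_models):
        system = build_ode_system(dict(corpus_models)["with_rules"])
        # scaling := ktot / cell was an assignment rule; it must be gone
        from modelconv.mathexpr import free_symbols
        for rate in system.rates:
            assert "scaling" not in free_symbols(rate)
        assert "drive" in system.rate_rules
        # initial assignment B = 0.5 * A overrides the raw initial amount
        assert system.initial_state["B"] == 2.0

    def test_missing_kinetic_law_raises(self):
        m = SbmlModel(id="m", level=3, version=1)
        m.compartments.append(Compartment(id="c"))
        m.species.append(Species(id="A", compartment="c", initial_amount=1.0))
        m.reactions.append(
            Reaction(id="r", reactants=[SpeciesReference("A")], products=[])
        )
        with pytest.raises(MissingKineticsError, match="r"):
            build_ode_system(m)

    def test_assignment_rule_cycle_raises(self):
        m = SbmlModel(id="m", level=3, version=1)
        m.compartments.append(Compartment(id="c"))
        from modelconv.sbml import Parameter
        m.parameters.append(Parameter(id="p", value=1.0, constant=False))
        m.parameters.append(Parameter(id="q", value=1.0, constant=False))
        m.rules.append(Rule("assignment", "p", sym("q")))
        m.rules.append(Rule("assignment", "q", sym("p")))
        with pytest.raises(CycleError):
            build_ode_system(m)


class TestRhs:
    def test_zero_state_gives_zero_rates_for_mass_action(self):
        model = generate_model(NetworkSpec(n_species=4, n_reactions=6, seed=5))
        system = build_ode_system(model)
        out = rhs(system, {sid: 0.0 for sid in system.all_state_ids})
        assert all(v == 0.0 for v in out.values())

    def test_detailed_balance_symmetry(self, corpus_models):
        """A <=> B with k_f = k_r and A = B sits at equilibrium."""
        system = build_ode_system(dict(corpus_models)["ab_reversible"])
        out = rhs(system, {"A": 3.3, "B": 3.3})
        assert out["A"] == 0.0 and out["B"] == 0.0

    def test_rate_rule_variables_get_derivatives(self, corpus_models):
        system = build_ode_system(dict(corpus_models)["with_rules"])
        state = {sid: 1.0 for sid in system.all_state_ids}
        early = rhs(system, state, t=3.0)
        late = rhs(system, state, t=7.0)
        assert early["drive"] == 0.1 and late["drive"] == 0.0


class TestStoichiometryOracle:
    def test_matrix_equals_brute_force_recount(self):
        """Independent pass over participant lists reproduces the matrix."""
        for seed in range(10):
            model = generate_model(
                NetworkSpec(n_species=6, n_reactions=8,
                            reversible_fraction=0.3, kinetics="mixed",
                            seed=seed)
            )
            system = build_ode_system(model)
            brute = np.zeros_like(system.stoichiometry)
            for j, reaction in enumerate(model.reactions):
                for ref in reaction.reactants:
                    if ref.species in system.state_ids:
                        i = system.state_ids.index(ref.species)
                        brute[i, j] -= ref.stoichiometry
                for ref in reaction.products:
                    if ref.species in system.state_ids:
                        i = system.state_ids.index(ref.species)
                        brute[i, j] += ref.stoichiometry
            assert (brute == system.stoichiometry).all()

    def test_corpus_matrices_match_brute_force(self, corpus_models):
        for name, model in corpus_models:
            system = build_ode_system(model)
            for j, reaction in enumerate(model.reactions):
                for i, sid in enumerate(system.state_ids):
                    net = sum(
                        r.stoichiometry for r in reaction.products
                        if r.species == sid
                    ) - sum(
                        r.stoichiometry for r in reaction.reactants
                        if r.species == sid
                    )
                    assert system.stoichiometry[i, j] == net, (name, sid)


class TestConservation:
    def test_closed_cascade_has_nontrivial_left_null_vector(self, corpus_models):
        system = build_ode_system(dict(corpus_models)["closed_cascade"])
        laws = conservation_laws(system)
        assert laws.shape[0] >= 1
        # the law is proportional to (1, 1, 1): total moiety conserved
        normalized = laws[0] / laws[0][0]
        assert np.allclose(normalized, [1.0, 1.0, 1.0])

    def test_conservation_along_rhs_for_closed_fixtures(self, corpus_models):
        rng = random.Random(7)
        for name in ("ab_mass_action", "ab_reversible",
                     "michaelis_menten_cycle", "closed_cascade"):
            system = build_ode_system(dict(corpus_models)[name])
            laws = conservation_laws(system)
            assert laws.shape[0] >= 1, name
            for _ in range(100):
                state = random_state(system, rng)
                out = rhs(system, state, t=rng.uniform(0, 10))
                dx = np.array([out[sid] for sid in system.state_ids])
                for law in laws:
                    assert abs(law @ dx) <= 1e-9, name
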