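"""Synthetic reaction-network generator and hand-authored example corpus.

Every module in the package is testable offline: :func:`generate_model`
builds random mass-action / Michaelis-Menten networks as a pure function
of a :class:`NetworkSpec` (same spec, byte-identical SBML), and
:func:`corpus` returns the small hand-authored models that pin down each
supported construct — the two-species mass-action chain, a reversible
pair, an enzyme cycle, a closed cascade with a conserved moiety, modifier
/ rule / annotation examples, and a model with pathological identifiers.

Generator conventions: each reaction draws 1-2 reactants and 1-2 products
(no species twice in the same role), rate constants are log-uniform on
[1e-2, 1e2] and initial amounts uniform on [1, 100] — ranges typical of
the BioModels-style kinetic models these converters serve.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .mathexpr import MathNode, num, op, sym
from .sbml import (
    Compartment,
    CVTerm,
    InitialAssignment,
    KineticLaw,
    Parameter,
    Reaction,
    Rule,
    SbmlModel,
    Species,
    SpeciesReference,
)

__all__ = ["NetworkSpec", "generate_model", "corpus"]


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of one synthetic network; generation is pure in the spec."""

    n_species: int = 5
    n_reactions: int = 5
    reversible_fraction: float = 0.0
    kinetics: str = "mass_action"  # mass_action | michaelis_menten | mixed
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if self.n_reactions < 0:
            raise ValueError("n_reactions must be >= 0")
        if not 0.0 <= self.reversible_fraction <= 1.0:
            raise ValueError("reversible_fraction must be in [0, 1]")
        if self.kinetics not in ("mass_action", "michaelis_menten", "mixed"):
            raise ValueError(f"unknown kinetics family {self.kinetics!r}")


def _round_sig(value: float, digits: int = 6) -> float:
    if value == 0:
        return 0.0
    magnitude = math.floor(math.log10(abs(value)))
    return round(value, digits - 1 - magnitude)


def generate_model(spec: NetworkSpec) -> SbmlModel:
    """Generate a random reaction network as an L3V1 :class:`SbmlModel`."""
    rng = random.Random(spec.seed)
    model = SbmlModel(id=f"synthetic_{spec.seed}", level=3, version=1)
    model.compartments.append(Compartment(id="cell", size=1.0))
    ids = [f"S{i + 1}" for i in range(spec.n_species)]
    for sid in ids:
        model.species.append(
            Species(
                id=sid, compartment="cell",
                initial_amount=_round_sig(rng.uniform(1.0, 100.0)),
            )
        )
    for j in range(spec.n_reactions):
        n_reactants = rng.randint(1, min(2, spec.n_species))
        reactants = rng.sample(ids, n_reactants)
        n_products = rng.randint(1, min(2, spec.n_species))
        products = rng.sample(ids, n_products)
        reversible = rng.random() < spec.reversible_fraction
        if spec.kinetics == "mixed":
            family = rng.choice(["mass_action", "michaelis_menten"])
        else:
            family = spec.kinetics
        rid = f"r{j + 1}"
        if family == "michaelis_menten" and not reversible:
            vmax = _round_sig(10.0 ** rng.uniform(-2.0, 2.0))
            km = _round_sig(10.0 ** rng.uniform(-2.0, 2.0))
            substrate = sym(reactants[0])
            math_expr = op(
                "divide",
                op("times", sym(f"Vmax_{rid}"), substrate),
                op("plus", sym(f"Km_{rid}"), substrate),
            )
            law = KineticLaw(
                math=math_expr,
                local_parameters={f"Vmax_{rid}": vmax, f"Km_{rid}": km},
            )
        else:
            kf = _round_sig(10.0 ** rng.uniform(-2.0, 2.0))
            forward = _mass_action_product(sym(f"kf_{rid}"), reactants)
            locals_ = {f"kf_{rid}": kf}
            if reversible:
                kr = _round_sig(10.0 ** rng.uniform(-2.0, 2.0))
                backward = _mass_action_product(sym(f"kr_{rid}"), products)
                math_expr = op("minus", forward, backward)
                locals_[f"kr_{rid}"] = kr
            else:
                math_expr = forward
            law = KineticLaw(math=math_expr, local_parameters=locals_)
        model.reactions.append(
            Reaction(
                id=rid,
                reversible=reversible,
                reactants=[SpeciesReference(s) for s in reactants],
                products=[SpeciesReference(s) for s in products],
                kinetic_law=law,
            )
        )
    return model


def _mass_action_product(rate_constant: MathNode, species_ids) -> MathNode:
    factors = [rate_constant] + [sym(s) for s in species_ids]
    if len(factors) == 1:
        return factors[0]
    return op("times", *factors)


# ---------------------------------------------------------------------------
# Hand-authored corpus
# ---------------------------------------------------------------------------

def _ab_mass_action() -> SbmlModel:
    """A -> B, v = k*A with k = 2, A(0) = 10, B(0) = 0."""
    m = SbmlModel(id="ab_mass_action", level=2, version=4)
    m.compartments.append(Compartment(id="cell", size=1.0))
    m.species.append(Species(id="A", compartment="cell", initial_amount=10.0))
    m.species.append(Species(id="B", compartment="cell", initial_amount=0.0))
    m.parameters.append(Parameter(id="k", value=2.0))
    m.reactions.append(
        Reaction(
            id="r1",
            reactants=[SpeciesReference("A")],
            products=[SpeciesReference("B")],
            kinetic_law=KineticLaw(math=op("times", sym("k"), sym("A"))),
        )
    )
    return m


def _ab_reversible() -> SbmlModel:
    """A <=> B with equal forward and reverse rate constants."""
    m = SbmlModel(id="ab_reversible", level=3, version=1)
    m.compartments.append(Compartment(id="cell", size=1.0))
    m.species.append(Species(id="A", compartment="cell", initial_amount=5.0))
    m.species.append(Species(id="B", compartment="cell", initial_amount=5.0))
    m.reactions.append(
        Reaction(
            id="r1",
            reversible=True,
            reactants=[SpeciesReference("A")],
            products=[SpeciesReference("B")],
            kinetic_law=KineticLaw(
                math=op(
                    "minus",
                    op("times", sym("kf"), sym("A")),
                    op("times", sym("kr"), sym("B")),
                ),
                local_parameters={"kf": 1.5, "kr": 1.5},
            ),
        )
    )
    return m


def _michaelis_menten_cycle() -> SbmlModel:
    """Substrate cycle S <-> P, each direction Michaelis-Menten."""
    m = SbmlModel(id="michaelis_menten_cycle", level=2, version=4)
    m.compartments.append(Compartment(id="cell", size=1.0))
    m.species.append(Species(id="S", compartment="cell", initial_amount=8.0))
    m.species.append(Species(id="P", compartment="cell", initial_amount=2.0))
    m.parameters.append(Parameter(id="Vmax_f", value=10.0))
    m.parameters.append(Parameter(id="Km_f", value=2.0))
    m.reactions.append(
        Reaction(
            id="forward",
            reactants=[SpeciesReference("S")],
            products=[SpeciesReference("P")],
            kinetic_law=KineticLaw(
                math=op(
                    "divide",
                    op("times", sym("Vmax_f"), sym("S")),
                    op("plus", sym("Km_f"), sym("S")),
                )
            ),
        )
    )
    m.reactions.append(
        Reaction(
            id="backward",
            reactants=[SpeciesReference("P")],
            products=[SpeciesReference("S")],
            kinetic_law=KineticLaw(
                math=op(
                    "divide",
                    op("times", sym("Vmax_b"), sym("P")),
                    op("plus", sym("Km_b"), sym("P")),
                ),
                local_parameters={"Vmax_b": 4.0, "Km_b": 1.0},
            ),
        )
    )
    return m


def _closed_cascade() -> SbmlModel:
    """A -> B -> C -> A: closed loop, total A+B+C conserved."""
    m = SbmlModel(id="closed_cascade", level=3, version=1)
    m.compartments.append(Compartment(id="cell", size=1.0))
    for sid, x0 in (("A", 6.0), ("B", 3.0), ("C", 1.0)):
        m.species.append(Species(id=sid, compartment="cell", initial_amount=x0))
    steps = [("r1", "A", "B", 1.0), ("r2", "B", "C", 0.5), ("r3", "C", "A", 0.25)]
    for rid, src, dst, k in steps:
        m.reactions.append(
            Reaction(
                id=rid,
                reactants=[SpeciesReference(src)],
                products=[SpeciesReference(dst)],
                kinetic_law=KineticLaw(
                    math=op("times", sym(f"k_{rid}"), sym(src)),
                    local_parameters={f"k_{rid}": k},
                ),
            )
        )
    return m


def _with_modifiers() -> SbmlModel:
    """Enzyme E catalyses S -> P (E a modifier, rate k*E*S)."""
    m = SbmlModel(id="with_modifiers", level=2, version=4)
    m.compartments.append(Compartment(id="cell", size=1.0))
    m.species.append(Species(id="S", compartment="cell", initial_amount=10.0))
    m.species.append(Species(id="P", compartment="cell", initial_amount=0.0))
    m.species.append(
        Species(id="E", compartment="cell", initial_concentration=0.5,
                boundary_condition=True)
    )
    m.parameters.append(Parameter(id="kcat", value=3.0))
    m.reactions.append(
        Reaction(
            id="cat",
            reactants=[SpeciesReference("S")],
            products=[SpeciesReference("P")],
            modifiers=["E"],
            kinetic_law=KineticLaw(
                math=op("times", sym("kcat"), sym("E"), sym("S"))
            ),
        )
    )
    return m


def _with_rules() -> SbmlModel:
    """Assignment rule, rate rule on a parameter, piecewise forcing, and an
    initial assignment — the rule-bearing corner of the subset."""
    m = SbmlModel(id="with_rules", level=3, version=1)
    m.compartments.append(Compartment(id="cell", size=2.0))
    m.species.append(Species(id="A", compartment="cell", initial_amount=4.0))
    m.species.append(Species(id="B", compartment="cell", initial_amount=1.0))
    m.parameters.append(Parameter(id="ktot", value=5.0))
    m.parameters.append(Parameter(id="scaling", value=0.0, constant=False))
    m.parameters.append(Parameter(id="drive", value=0.5, constant=False))
    # scaling := ktot / cell  (assignment rule, inlined into rates)
    m.rules.append(
        Rule(rule_type="assignment", variable="scaling",
             math=op("divide", sym("ktot"), sym("cell")))
    )
    # d(drive)/dt = piecewise(0.1 if t < 5, else 0)
    m.rules.append(
        Rule(
            rule_type="rate", variable="drive",
            math=op("piecewise", num(0.1), op("lt", sym("t"), num(5.0)),
                    num(0.0)),
        )
    )
    m.initial_assignments.append(
        InitialAssignment(variable="B", math=op("times", num(0.5), sym("A")))
    )
    m.reactions.append(
        Reaction(
            id="conv",
            reactants=[SpeciesReference("A")],
            products=[SpeciesReference("B")],
            kinetic_law=KineticLaw(
                math=op("times", sym("scaling"), sym("drive"), sym("A"))
            ),
        )
    )
    return m


def _with_annotations() -> SbmlModel:
    """Mass-action pair with MIRIAM URN annotations on model and species."""
    m = _ab_mass_action()
    m.id = "with_annotations"
    m.cv_terms["with_annotations"] = [
        CVTerm(qualifier="bqmodel:is",
               resources=["urn:miriam:biomodels.db:BIOMD0000000001"]),
    ]
    m.cv_terms["A"] = [
        CVTerm(
            qualifier="bqbiol:is",
            resources=[
                "urn:miriam:obo.chebi:CHEBI%3A36927",
                "urn:miriam:pubmed:16333295",
            ],
        )
    ]
    m.cv_terms["B"] = [
        CVTerm(qualifier="bqbiol:isVersionOf",
               resources=["urn:miriam:obo.chebi:CHEBI%3A17234"]),
    ]
    return m


def _pathological_ids() -> SbmlModel:
    """Identifiers that stress sanitization: XPP truncation collisions and a
    non-ASCII display name."""
    m = SbmlModel(id="pathological_ids", level=3, version=1)
    m.compartments.append(Compartment(id="cell", size=1.0))
    long_a = "phosphorylated_MAPK_cascade_intermediate"
    long_b = "phosphorylated_MAPK_cascade_intermediary"
    m.species.append(
        Species(id=long_a, compartment="cell", initial_amount=7.0,
                name="αB-crystallin complex")
    )
    m.species.append(
        Species(id=long_b, compartment="cell", initial_amount=1.0,
                name='doubly "quoted" label')
    )
    m.reactions.append(
        Reaction(
            id="transfer",
            reactants=[SpeciesReference(long_a)],
            products=[SpeciesReference(long_b)],
            kinetic_law=KineticLaw(
                math=op("times", sym("k"), sym(long_a)),
                local_parameters={"k": 0.7},
            ),
        )
    )
    return m


def _constant_only() -> SbmlModel:
    """No reactions; a single constant species (all-zero derivatives)."""
    m = SbmlModel(id="constant_only", level=2, version=4)
    m.compartments.append(Compartment(id="cell", size=1.0))
    m.species.append(
        Species(id="X", compartment="cell", initial_amount=1.0, constant=True)
    )
    m.species.append(Species(id="Y", compartment="cell", initial_amount=2.0))
    return m


def corpus() -> list[tuple[str, SbmlModel]]:
    """The hand-authored fixture corpus (name, model), order-stable."""
    builders = [
        _ab_mass_action,
        _ab_reversible,
        _michaelis_menten_cycle,
        _closed_cascade,
        _with_modifiers,
        _with_rules,
        _with_annotations,
        _pathological_ids,
        _constant_only,
    ]
    return [(b().id, b()) for b in builders]
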