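"""SBML reading, writing, round trips and level conversion."""

import random
from pathlib import Path

import pytest

from modelconv.errors import (
    SbmlReadError,
    UnsupportedConstructError,
    ValidationError,
)
from modelconv.mathexpr import op, sym
from modelconv.ode import build_ode_system, rhs
from modelconv.sbml import (
    Compartment,
    SbmlModel,
    Species,
    convert_level,
    models_equal,
    read_sbml,
    write_sbml,
)
from modelconv.synthetic import NetworkSpec, generate_model

from conftest import random_state

DATA = Path(__file__).parent / "data"

MINIMAL_L3 = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" level="3" version="1">
  <model id="tiny">
    <listOfCompartments>
      <compartment id="cell" spatialDimensions="3" size="1" constant="true"/>
    </listOfCompartments>
  </model>
</sbml>
"""


class TestRead:
    def test_minimal_document(self):
        model = read_sbml(MINIMAL_L3)
        assert model.id == "tiny"
        assert (model.level, model.version) == (3, 1)
        assert len(model.compartments) == 1
        assert model.species == []

    def test_hand_authored_two_step_pathway(self):
        model = read_sbml((DATA / "two_step_pathway.xml").read_text())
        assert [s.id for s in model.species] == ["A", "B", "C"]
        assert [r.id for r in model.reactions] == ["step1", "step2"]
        assert model.reactions[0].kinetic_law.math == op(
            "times", sym("k1"), sym("A")
        )
        assert model.reactions[1].kinetic_law.math == op(
            "times", sym("k2"), sym("B")
        )
        # L2 attribute defaults
        assert model.species[0].initial_amount == 10.0
        assert model.compartments[0].size == 1.0

    def test_event_is_rejected_by_name(self):
        with pytest.raises(UnsupportedConstructError, match="event"):
            read_sbml((DATA / "event_model.xml").read_text())

    def test_unknown_namespace_is_rejected(self):
        doc = MINIMAL_L3.replace("level3/version1/core", "level3/version2/core")
        with pytest.raises(SbmlReadError, match="namespace"):
            read_sbml(doc)

    def test_function_definitions_expand_inline(self):
        model = read_sbml((DATA / "function_def_model.xml").read_text())
        expected = op(
            "divide",
            op("times", sym("Vm"), sym("S")),
            op("plus", sym("Km"), sym("S")),
        )
        assert model.reactions[0].kinetic_law.math == expected


class TestWrite:
    def test_serialization_is_a_fixed_point(self, corpus_models):
        for name, model in corpus_models:
            once = write_sbml(model)
            twice = write_sbml(read_sbml(once))
            thrice = write_sbml(read_sbml(twice))
            assert once == twice == thrice, name

    def test_empty_model_is_minimal_valid_document(self):
        text = write_sbml(SbmlModel(id="empty", level=3, version=1))
        model = read_sbml(text)
        assert model.id == "empty"
        assert model.species == [] and model.reactions == []

    def test_round_trip_semantic_equality_over_corpus(self, corpus_models):
        for name, model in corpus_models:
            recovered = read_sbml(write_sbml(model))
            assert models_equal(model, recovered), name

    def test_invariant_violations_are_all_listed(self):
        bad = SbmlModel(id="bad", level=3, version=1)
        bad.species.append(Species(id="A", compartment="nowhere"))
        bad.species.append(
            Species(id="A", compartment="nowhere", initial_amount=1.0,
                    initial_concentration=2.0)
        )
        with pytest.raises(ValidationError) as err:
            write_sbml(bad)
        text = str(err.value)
        assert "duplicate" in text and "nowhere" in text and "both" in text

    def test_identical_models_write_identical_bytes(self):
        a = generate_model(NetworkSpec(seed=11))
        b = generate_model(NetworkSpec(seed=11))
        assert write_sbml(a) == write_sbml(b)


class TestLevelConversion:
    def test_l2_l3_l2_round_trip_is_identity(self, corpus_models):
        for name, model in corpus_models:
            up = convert_level(model, 3, 1)
            back = convert_level(up, model.level, model.version)
            assert models_equal(model, back), name

    def test_identity_conversion_copies(self, corpus_models):
        _, model = corpus_models[0]
        copy = convert_level(model, model.level, model.version)
        assert models_equal(model, copy)
        assert copy is not model

    def test_unsupported_target_is_rejected(self, corpus_models):
        _, model = corpus_models[0]
        with pytest.raises(ValueError):
            convert_level(model, 1, 2)

    def test_level_conversion_commutes_with_ode_derivation(self, corpus_models):
        """Stoichiometry and RHS identical before and after level change."""
        rng = random.Random(42)
        for name, model in corpus_models:
            before = build_ode_system(model)
            target = (3, 1) if model.level == 2 else (2, 4)
            after = build_ode_system(convert_level(model, *target))
            assert (before.stoichiometry == after.stoichiometry).all(), name
            assert before.state_ids == after.state_ids, name
            for _ in range(20):
                state = random_state(before, rng)
                t = rng.uniform(0.0, 10.0)
                va, vb = rhs(before, state, t), rhs(after, state, t)
                for sid in before.all_state_ids:
                    assert abs(va[sid] - vb[sid]) <= 1e-12, (name, sid)


def test_cv_terms_round_trip(corpus_models):
    annotated = dict(corpus_models)["with_annotations"]
    recovered = read_sbml(write_sbml(annotated))
    assert recovered.cv_terms == annotated.cv_terms


def test_species_compartment_reference_checked():
    model = SbmlModel(id="m", level=3, version=1)
    model.compartments.append(Compartment(id="cell"))
    model.species.append(Species(id="A", compartment="other"))
    with pytest.raises(ValidationError, match="other"):
        write_sbml(model)
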