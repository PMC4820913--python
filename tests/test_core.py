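"""Registry, dispatch and converter-composition behaviour."""

import pytest

from modelconv.core import (
    ConverterDescriptor,
    ConverterRegistry,
    FormatDescriptor,
    FunctionConverter,
    TextModel,
    compose,
)
from modelconv.errors import (
    CompositionError,
    ConversionError,
    FormatMismatchError,
    RegistrationError,
    UnknownConverterError,
)
from modelconv.formats import SbmlDocumentModel, default_registry
from modelconv.sbml import write_sbml

FMT_A = FormatDescriptor(uri="urn:modelconv:format:a", name="A", file_extension="a")
FMT_B = FormatDescriptor(uri="urn:modelconv:format:b", name="B", file_extension="b")
FMT_C = FormatDescriptor(uri="urn:modelconv:format:c", name="C", file_extension="c")
FMT_D = FormatDescriptor(uri="urn:modelconv:format:d", name="D", file_extension="d")


class _AModel(TextModel):
    FORMAT = FMT_A


class _BModel(TextModel):
    FORMAT = FMT_B


class _CModel(TextModel):
    FORMAT = FMT_C


class _DModel(TextModel):
    FORMAT = FMT_D


def _tagger(name, out_cls, in_fmt, out_fmt):
    """A toy converter that appends its own name to the text."""
    return FunctionConverter(
        ConverterDescriptor(name=name, input_format=in_fmt, output_format=out_fmt),
        lambda model: out_cls(model.to_string() + f"|{name}"),
    )


@pytest.fixture
def toy_registry():
    reg = ConverterRegistry()
    reg.register_converter(_tagger("A2B", _BModel, FMT_A, FMT_B))
    reg.register_converter(_tagger("B2C", _CModel, FMT_B, FMT_C))
    reg.register_converter(_tagger("C2D", _DModel, FMT_C, FMT_D))
    return reg


def test_registered_converter_is_retrievable_and_enumerated(toy_registry):
    assert toy_registry.get_converter("A2B").descriptor.name == "A2B"
    assert toy_registry.converter_names() == ["A2B", "B2C", "C2D"]


def test_duplicate_converter_name_is_rejected(toy_registry):
    with pytest.raises(RegistrationError, match="A2B"):
        toy_registry.register_converter(_tagger("A2B", _BModel, FMT_A, FMT_B))


def test_duplicate_format_uri_is_rejected():
    reg = ConverterRegistry()
    reg.register_format(FMT_A)
    clone = FormatDescriptor(uri=FMT_A.uri, name="other", file_extension="x")
    with pytest.raises(RegistrationError):
        reg.register_format(clone)


def test_convert_returns_declared_output_format(toy_registry):
    out = toy_registry.convert("A2B", _AModel("payload"))
    assert out.format.uri == FMT_B.uri
    assert out.to_string() == "payload|A2B"


def test_format_mismatch_names_both_uris(toy_registry):
    with pytest.raises(FormatMismatchError) as err:
        toy_registry.convert("A2B", _BModel("payload"))
    message = str(err.value)
    assert FMT_A.uri in message and FMT_B.uri in message


def test_unknown_converter_is_a_lookup_error(toy_registry):
    with pytest.raises(UnknownConverterError):
        toy_registry.convert("NoSuchConverter", _AModel(""))


def test_conversion_failure_is_wrapped_with_converter_name():
    def boom(model):
        raise ValueError("inner failure")

    reg = ConverterRegistry()
    reg.register_function(
        ConverterDescriptor(name="A2B", input_format=FMT_A, output_format=FMT_B),
        boom,
    )
    with pytest.raises(ConversionError, match="A2B"):
        reg.convert("A2B", _AModel(""))


def test_registry_isolation():
    reg1 = ConverterRegistry()
    reg2 = ConverterRegistry()
    reg1.register_converter(_tagger("A2B", _BModel, FMT_A, FMT_B))
    with pytest.raises(UnknownConverterError):
        reg2.get_converter("A2B")


def test_composition_equals_manual_two_step(toy_registry):
    a2b = toy_registry.get_converter("A2B")
    b2c = toy_registry.get_converter("B2C")
    chained = compose(a2b, b2c)
    model = _AModel("seed")
    manual = b2c.convert(a2b.convert(model)).to_string()
    assert chained.convert(model).to_string() == manual
    assert chained.descriptor.input_format == FMT_A
    assert chained.descriptor.output_format == FMT_C


def test_composition_rejects_incompatible_intermediates(toy_registry):
    a2b = toy_registry.get_converter("A2B")
    c2d = toy_registry.get_converter("C2D")
    with pytest.raises(CompositionError):
        compose(a2b, c2d)


def test_composition_is_associative(toy_registry):
    a2b = toy_registry.get_converter("A2B")
    b2c = toy_registry.get_converter("B2C")
    c2d = toy_registry.get_converter("C2D")
    left = compose(compose(a2b, b2c), c2d)
    right = compose(a2b, compose(b2c, c2d))
    model = _AModel("assoc")
    assert left.convert(model).to_string() == right.convert(model).to_string()


def test_level_up_then_octave_composition_matches_manual_chain(corpus_models):
    """Chaining the level converter into the Octave exporter is byte-stable."""
    registry = default_registry()
    level_up = registry.get_converter("SBML2SBML")
    to_octave = registry.get_converter("SBML2Octave")
    chained = compose(level_up, to_octave)
    for name, model in corpus_models:
        doc = SbmlDocumentModel.from_string(write_sbml(model))
        manual = to_octave.convert(level_up.convert(doc)).to_string()
        assert chained.convert(doc).to_string() == manual, name


def test_dispatch_totality_over_default_registry(corpus_models):
    """Every registered converter either returns its declared output format
    or raises a typed error — never a silently wrong format."""
    registry = default_registry()
    _, model = corpus_models[0]
    doc = SbmlDocumentModel.from_string(write_sbml(model))
    wrong = _AModel("not sbml")
    for conv in registry.converters():
        out = conv.convert(doc)  # all shipped converters take SBML
        assert out.format.uri == conv.descriptor.output_format.uri
        with pytest.raises(FormatMismatchError):
            conv.convert(wrong)
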