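"""Concrete format classes and the default converter registry.

Each supported file format gets a :class:`~modelconv.core.FormatDescriptor`
and a :class:`~modelconv.core.GeneralModel` implementation; each conversion
the package ships is registered under its conventional class-style name
(``SBML2Octave``, ``URN2URL``, ...).  Where a public identifier for a
format exists (identifiers.org entry or internet media type) it is used;
otherwise a stable placeholder URI ``urn:modelconv:format:<name>`` is
minted.
"""

from __future__ import annotations

from . import annotations as annot
from . import codegen, graphs, sbml
from .core import (
    ConverterDescriptor,
    ConverterRegistry,
    FormatDescriptor,
    FunctionConverter,
    GeneralConverter,
    GeneralModel,
    TextModel,
)
from .ode import build_ode_system

__all__ = [
    "SBML_FORMAT",
    "OCTAVE_FORMAT",
    "MATLAB_FORMAT",
    "XPP_FORMAT",
    "DOT_FORMAT",
    "SBGNML_FORMAT",
    "SbmlDocumentModel",
    "OctaveModel",
    "MatlabModel",
    "XppModel",
    "DotModel",
    "SbgnmlModel",
    "default_registry",
]

SBML_FORMAT = FormatDescriptor(
    uri="http://identifiers.org/combine.specifications/sbml",
    name="SBML",
    file_extension="xml",
)
OCTAVE_FORMAT = FormatDescriptor(
    uri="urn:modelconv:format:octave",
    name="Octave",
    file_extension="m",
)
MATLAB_FORMAT = FormatDescriptor(
    uri="urn:modelconv:format:matlab",
    name="Matlab",
    file_extension="m",
)
XPP_FORMAT = FormatDescriptor(
    uri="urn:modelconv:format:xpp",
    name="XPP",
    file_extension="ode",
)
DOT_FORMAT = FormatDescriptor(
    uri="text/vnd.graphviz",
    name="Dot",
    file_extension="dot",
)
SBGNML_FORMAT = FormatDescriptor(
    uri="http://identifiers.org/combine.specifications/sbgn",
    name="SBGN-ML",
    file_extension="sbgn",
)


class SbmlDocumentModel(GeneralModel):
    """An SBML document carried as a parsed :class:`~modelconv.sbml.SbmlModel`."""

    def __init__(self, model: sbml.SbmlModel):
        self.model = model

    @property
    def format(self) -> FormatDescriptor:
        return SBML_FORMAT

    def to_string(self) -> str:
        return sbml.write_sbml(self.model)

    @classmethod
    def from_string(cls, text: str) -> "SbmlDocumentModel":
        return cls(sbml.read_sbml(text))


class OctaveModel(TextModel):
    FORMAT = OCTAVE_FORMAT


class MatlabModel(TextModel):
    FORMAT = MATLAB_FORMAT


class XppModel(TextModel):
    FORMAT = XPP_FORMAT


class DotModel(TextModel):
    FORMAT = DOT_FORMAT


class SbgnmlModel(TextModel):
    FORMAT = SBGNML_FORMAT


# ---------------------------------------------------------------------------
# Converter implementations
# ---------------------------------------------------------------------------

def _sbml_to_octave(model: SbmlDocumentModel) -> OctaveModel:
    system = build_ode_system(model.model)
    return OctaveModel(codegen.to_octave(system, model.model, dialect="octave"))


def _sbml_to_matlab(model: SbmlDocumentModel) -> MatlabModel:
    system = build_ode_system(model.model)
    return MatlabModel(codegen.to_octave(system, model.model, dialect="matlab"))


def _sbml_to_xpp(model: SbmlDocumentModel) -> XppModel:
    system = build_ode_system(model.model)
    return XppModel(codegen.to_xpp(system, model.model))


def _sbml_to_dot(model: SbmlDocumentModel) -> DotModel:
    return DotModel(graphs.to_dot(model.model))


def _sbml_to_sbgnml(model: SbmlDocumentModel) -> SbgnmlModel:
    return SbgnmlModel(graphs.to_sbgnml(model.model))


def _level_converter(level: int, version: int):
    def convert(model: SbmlDocumentModel) -> SbmlDocumentModel:
        return SbmlDocumentModel(sbml.convert_level(model.model, level, version))
    return convert


def _annotation_converter(direction: str):
    def convert(model: SbmlDocumentModel) -> SbmlDocumentModel:
        converted, _report = annot.convert_model_annotations(
            model.model, direction
        )
        return SbmlDocumentModel(converted)
    return convert


def default_registry() -> ConverterRegistry:
    """Registry pre-populated with every format and converter shipped here.

    Registered converters: SBML2SBML (level up-conversion to L3V1),
    SBML2SBML_L2V4 (down-conversion), SBML2Octave, SBML2Matlab, SBML2XPP,
    SBML2Dot, SBML2SBGNML, URN2URL, URL2URN.
    """
    registry = ConverterRegistry()
    for fmt in (SBML_FORMAT, OCTAVE_FORMAT, MATLAB_FORMAT, XPP_FORMAT,
                DOT_FORMAT, SBGNML_FORMAT):
        registry.register_format(fmt)
    registry.register_model_class("SBMLModel", SbmlDocumentModel)
    registry.register_model_class("OctaveModel", OctaveModel)
    registry.register_model_class("MatlabModel", MatlabModel)
    registry.register_model_class("XPPModel", XppModel)
    registry.register_model_class("DotModel", DotModel)
    registry.register_model_class("SBGNMLModel", SbgnmlModel)

    def add(name, in_fmt, out_fmt, func):
        registry.register_converter(
            FunctionConverter(
                ConverterDescriptor(name=name, input_format=in_fmt,
                                    output_format=out_fmt),
                func,
            )
        )

    add("SBML2SBML", SBML_FORMAT, SBML_FORMAT, _level_converter(3, 1))
    add("SBML2SBML_L2V4", SBML_FORMAT, SBML_FORMAT, _level_converter(2, 4))
    add("SBML2Octave", SBML_FORMAT, OCTAVE_FORMAT, _sbml_to_octave)
    add("SBML2Matlab", SBML_FORMAT, MATLAB_FORMAT, _sbml_to_matlab)
    add("SBML2XPP", SBML_FORMAT, XPP_FORMAT, _sbml_to_xpp)
    add("SBML2Dot", SBML_FORMAT, DOT_FORMAT, _sbml_to_dot)
    add("SBML2SBGNML", SBML_FORMAT, SBGNML_FORMAT, _sbml_to_sbgnml)
    add("URN2URL", SBML_FORMAT, SBML_FORMAT, _annotation_converter("urn_to_url"))
    add("URL2URN", SBML_FORMAT, SBML_FORMAT, _annotation_converter("url_to_urn"))
    return registry
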