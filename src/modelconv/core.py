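"""Registry and dispatch core: formats, general models, general converters.

Every file format handled by the package is described by a
:class:`FormatDescriptor` and carried by an object implementing the
:class:`GeneralModel` contract (content readable as text, writable to a
file, format fixed for the object's lifetime).  Every conversion is a
:class:`GeneralConverter` with a declared input and output format; a
:class:`ConverterRegistry` keys converters by name and dispatches on the
model's format URI.  Converters compose: chaining A2B and B2C yields an A2C
whose output is byte-identical to running the two steps manually.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from pathlib import Path

from .errors import (
    CompositionError,
    ConversionError,
    FormatMismatchError,
    ModelConvError,
    RegistrationError,
    UnknownConverterError,
    UnknownFormatError,
)

__all__ = [
    "FormatDescriptor",
    "GeneralModel",
    "TextModel",
    "ConverterDescriptor",
    "GeneralConverter",
    "FunctionConverter",
    "ComposedConverter",
    "compose",
    "ConverterRegistry",
]


@dataclass(frozen=True)
class FormatDescriptor:
    """Identity of a file format used for dispatch.

    Parameters
    ----------
    uri:
        identifiers.org-style URI or internet media type.  Where no public
        identifier exists a stable placeholder of the shape
        ``urn:modelconv:format:<name>`` is minted.
    name:
        Human-readable format name (e.g. ``"SBML"``).
    file_extension:
        Lowercase file extension without the leading dot.
    """

    uri: str
    name: str
    file_extension: str

    def __post_init__(self):
        if not self.uri:
            raise ValueError("format uri must be non-empty")
        if not self.file_extension:
            raise ValueError("file_extension must be non-empty")
        if self.file_extension != self.file_extension.lower():
            raise ValueError("file_extension must be lowercase")


class GeneralModel(abc.ABC):
    """Contract every format-bearing model object implements.

    The format reported by :attr:`format` never changes over the model's
    lifetime, and reading a model back from the text produced by its own
    :meth:`to_string` yields an equivalent model.
    """

    @property
    @abc.abstractmethod
    def format(self) -> FormatDescriptor:  # pragma: no cover - interface
        ...

    @abc.abstractmethod
    def to_string(self) -> str:
        """Serialize the model to its on-disk text representation."""

    def to_file(self, file_name) -> None:
        """Write :meth:`to_string` to ``file_name`` (UTF-8)."""
        Path(file_name).write_text(self.to_string(), encoding="utf-8")

    @classmethod
    @abc.abstractmethod
    def from_string(cls, text: str) -> "GeneralModel":
        """Parse a model from its text representation."""

    @classmethod
    def from_file(cls, file_name) -> "GeneralModel":
        return cls.from_string(Path(file_name).read_text(encoding="utf-8"))


class TextModel(GeneralModel):
    """A model that is nothing but text in a fixed format.

    Output-only formats (Octave m-files, XPP .ode files, Dot, SBGN-ML) are
    carried this way: the text is the model.
    """

    FORMAT: FormatDescriptor  # set by subclasses

    def __init__(self, text: str):
        self._text = text

    @property
    def format(self) -> FormatDescriptor:
        return self.FORMAT

    def to_string(self) -> str:
        return self._text

    @classmethod
    def from_string(cls, text: str) -> "TextModel":
        return cls(text)

    def __eq__(self, other):
        return (
            isinstance(other, TextModel)
            and self.format == other.format
            and self._text == other._text
        )

    def __hash__(self):
        return hash((self.format, self._text))


@dataclass(frozen=True)
class ConverterDescriptor:
    """Name plus declared input and output format of a converter."""

    name: str
    input_format: FormatDescriptor
    output_format: FormatDescriptor

    def __post_init__(self):
        if not self.name:
            raise ValueError("converter name must be non-empty")


class GeneralConverter(abc.ABC):
    """Generic conversion algorithm from one format into another.

    :meth:`convert` first checks that the input model's format URI is the
    one this converter supports and refuses otherwise with a typed error
    naming both URIs; any exception raised by the conversion logic itself
    is wrapped in :class:`~modelconv.errors.ConversionError` so partial
    output is never returned.
    """

    descriptor: ConverterDescriptor

    def convert(self, model: GeneralModel) -> GeneralModel:
        expected = self.descriptor.input_format.uri
        got = model.format.uri
        if got != expected:
            raise FormatMismatchError(self.descriptor.name, expected, got)
        try:
            result = self._convert(model)
        except ModelConvError as exc:
            raise ConversionError(self.descriptor.name, exc) from exc
        except Exception as exc:  # noqa: BLE001 - deliberate wrap-all
            raise ConversionError(self.descriptor.name, exc) from exc
        out_uri = result.format.uri
        declared = self.descriptor.output_format.uri
        if out_uri != declared:
            raise ConversionError(
                self.descriptor.name,
                FormatMismatchError(self.descriptor.name, declared, out_uri),
            )
        return result

    @abc.abstractmethod
    def _convert(self, model: GeneralModel) -> GeneralModel:
        """Format-specific conversion logic (input already format-checked)."""


class FunctionConverter(GeneralConverter):
    """Adapter turning a plain function into a :class:`GeneralConverter`."""

    def __init__(self, descriptor: ConverterDescriptor, func):
        self.descriptor = descriptor
        self._func = func

    def _convert(self, model: GeneralModel) -> GeneralModel:
        return self._func(model)


class ComposedConverter(GeneralConverter):
    """Chain of two converters run back to back.

    The output is, by construction, byte-identical to applying the two
    converters manually: ``second.convert(first.convert(model))``.
    """

    def __init__(self, first: GeneralConverter, second: GeneralConverter):
        if first.descriptor.output_format.uri != second.descriptor.input_format.uri:
            raise CompositionError(
                f"cannot compose {first.descriptor.name!r} (output "
                f"{first.descriptor.output_format.uri!r}) with "
                f"{second.descriptor.name!r} (input "
                f"{second.descriptor.input_format.uri!r})"
            )
        self.first = first
        self.second = second
        self.descriptor = ConverterDescriptor(
            name=f"{first.descriptor.name}+{second.descriptor.name}",
            input_format=first.descriptor.input_format,
            output_format=second.descriptor.output_format,
        )

    def _convert(self, model: GeneralModel) -> GeneralModel:
        return self.second.convert(self.first.convert(model))


def compose(first: GeneralConverter, second: GeneralConverter) -> ComposedConverter:
    """Compose two converters; the intermediate format URIs must match."""
    return ComposedConverter(first, second)


@dataclass
class ConverterRegistry:
    """Holds formats, model classes, and converters; dispatches by name.

    Registries are isolated: converters added to one registry are invisible
    to another.  Enumeration order is insertion order (stable).
    """

    _formats: dict = field(default_factory=dict)  # name -> FormatDescriptor
    _model_classes: dict = field(default_factory=dict)  # name -> GeneralModel cls
    _converters: dict = field(default_factory=dict)  # name -> GeneralConverter

    # -- formats -----------------------------------------------------------
    def register_format(self, descriptor: FormatDescriptor) -> None:
        if descriptor.name in self._formats:
            raise RegistrationError(
                f"format name {descriptor.name!r} already registered"
            )
        for existing in self._formats.values():
            if existing.uri == descriptor.uri:
                raise RegistrationError(
                    f"format uri {descriptor.uri!r} already registered "
                    f"under name {existing.name!r}"
                )
        self._formats[descriptor.name] = descriptor

    def formats(self) -> list[FormatDescriptor]:
        return list(self._formats.values())

    def get_format(self, name: str) -> FormatDescriptor:
        try:
            return self._formats[name]
        except KeyError:
            raise UnknownFormatError(name) from None

    # -- model classes -----------------------------------------------------
    def register_model_class(self, name: str, cls) -> None:
        """Register a :class:`GeneralModel` implementation under a name.

        Several implementations per format URI are allowed; the registry
        keys them by name.
        """
        if name in self._model_classes:
            raise RegistrationError(f"model class name {name!r} already registered")
        self._model_classes[name] = cls

    def model_classes(self) -> dict:
        return dict(self._model_classes)

    def get_model_class(self, name: str):
        try:
            return self._model_classes[name]
        except KeyError:
            raise UnknownFormatError(name) from None

    # -- converters --------------------------------------------------------
    def register_converter(self, converter: GeneralConverter) -> None:
        name = converter.descriptor.name
        if name in self._converters:
            raise RegistrationError(f"converter name {name!r} already registered")
        self._converters[name] = converter

    def register_function(self, descriptor: ConverterDescriptor, func) -> None:
        self.register_converter(FunctionConverter(descriptor, func))

    def converters(self) -> list[GeneralConverter]:
        return list(self._converters.values())

    def converter_names(self) -> list[str]:
        return list(self._converters)

    def get_converter(self, name: str) -> GeneralConverter:
        try:
            return self._converters[name]
        except KeyError:
            raise UnknownConverterError(name) from None

    def convert(self, converter_name: str, model: GeneralModel) -> GeneralModel:
        """Look up a converter by name and run it on ``model``."""
        return self.get_converter(converter_name).convert(model)
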