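"""Exception hierarchy shared by all modelconv modules.

Every failure mode a converter can hit maps to a typed exception so that
callers (and the CLI batch runner) can distinguish user errors, unsupported
input constructs, and internal conversion failures.
"""


class ModelConvError(Exception):
    """Base class for all modelconv errors."""


class RegistrationError(ModelConvError):
    """A format or converter name clashes with one already registered."""


class UnknownConverterError(ModelConvError, KeyError):
    """Converter name not present in the registry."""


class UnknownFormatError(ModelConvError, KeyError):
    """Format name/URI not present in the registry."""


class FormatMismatchError(ModelConvError):
    """A converter was handed a model whose format URI it does not accept."""

    def __init__(self, converter_name: str, expected_uri: str, got_uri: str):
        self.converter_name = converter_name
        self.expected_uri = expected_uri
        self.got_uri = got_uri
        super().__init__(
            f"converter {converter_name!r} expects input format URI "
            f"{expected_uri!r} but was given a model of format {got_uri!r}"
        )


class CompositionError(ModelConvError):
    """Two converters cannot be chained: intermediate formats differ."""


class ConversionError(ModelConvError):
    """Wraps any failure raised inside a converter's conversion logic."""

    def __init__(self, converter_name: str, cause: BaseException):
        self.converter_name = converter_name
        self.cause = cause
        super().__init__(f"converter {converter_name!r} failed: {cause}")


class MathError(ModelConvError):
    """Base class for expression-tree errors."""


class UnsupportedConstructError(ModelConvError):
    """Input uses a construct outside the supported subset."""


class DialectError(MathError):
    """Expression cannot be printed in the requested dialect."""


class EvaluationError(MathError):
    """Numeric evaluation failed (typically an unbound symbol)."""


class CycleError(ModelConvError):
    """A substitution / assignment-rule chain is cyclic."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("cyclic definition: " + " -> ".join(self.cycle))


class SbmlReadError(ModelConvError):
    """Document is not readable as supported SBML."""


class ValidationError(ModelConvError):
    """Model invariants violated; carries the full list of violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class MissingKineticsError(ModelConvError):
    """A reaction that moves a dynamic species has no kinetic law."""


class SanitizationError(ModelConvError):
    """Identifier sanitization could not produce a collision-free map."""


class AnnotationParseError(ModelConvError, ValueError):
    """A MIRIAM URN or identifiers.org URL does not match its grammar."""
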