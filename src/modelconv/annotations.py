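"""MIRIAM URN <-> identifiers.org URL annotation rewriting.

The same controlled-vocabulary annotation has two historical syntaxes:

    urn:miriam:<collection>:<percent-encoded id>
    http://identifiers.org/<collection>/<id>

e.g. ``urn:miriam:obo.chebi:CHEBI%3A36927`` and
``http://identifiers.org/obo.chebi/CHEBI:36927``.  This module provides
the two string transforms (exact mutual inverses on well-formed
identifiers) and a model-level pass that rewrites every CVTerm resource in
the source scheme while leaving everything else untouched and counted in a
report.  Only syntax is validated — no network lookup of the collection
registry is performed, so conversions are deterministic and offline.

Percent-encoding policy: when building a URN, every character of the
entity id outside the RFC 3986 unreserved set (letters, digits, ``-._~``)
is encoded — in particular ``:`` and ``%`` — which guarantees the URL ->
URN -> URL round trip is the identity.  Decoding accepts any valid percent
sequence.
"""

from __future__ import annotations

import copy
import re
import urllib.parse
from dataclasses import dataclass

from .errors import AnnotationParseError
from .sbml import SbmlModel

__all__ = [
    "MiriamIdentifier",
    "parse_urn",
    "parse_url",
    "urn_to_url",
    "url_to_urn",
    "AnnotationReport",
    "convert_model_annotations",
]

_COLLECTION_RE = re.compile(r"[a-z0-9]+(?:\.[a-z0-9]+)*")
_URN_RE = re.compile(
    r"urn:miriam:(?P<collection>[a-z0-9]+(?:\.[a-z0-9]+)*):(?P<id>.+)",
    re.DOTALL,
)
_URL_RE = re.compile(
    r"https?://identifiers\.org/"
    r"(?P<collection>[a-z0-9]+(?:\.[a-z0-9]+)*)/(?P<id>.+)",
    re.DOTALL,
)


@dataclass(frozen=True)
class MiriamIdentifier:
    """A controlled-vocabulary identifier: namespace key plus raw entity id."""

    collection: str
    entity_id: str

    def __post_init__(self):
        if not _COLLECTION_RE.fullmatch(self.collection):
            raise AnnotationParseError(
                f"invalid collection {self.collection!r}: must be lowercase "
                "dot-separated tokens"
            )
        if not self.entity_id:
            raise AnnotationParseError("entity id must be non-empty")

    def to_urn(self) -> str:
        encoded = urllib.parse.quote(self.entity_id, safe="")
        return f"urn:miriam:{self.collection}:{encoded}"

    def to_url(self) -> str:
        return f"http://identifiers.org/{self.collection}/{self.entity_id}"


def parse_urn(urn: str) -> MiriamIdentifier:
    """Parse ``urn:miriam:<collection>:<percent-encoded id>``."""
    m = _URN_RE.fullmatch(urn)
    if not m:
        raise AnnotationParseError(f"not a MIRIAM URN: {urn!r}")
    raw_id = m.group("id")
    try:
        decoded = urllib.parse.unquote(raw_id, errors="strict")
    except UnicodeDecodeError as exc:
        raise AnnotationParseError(
            f"invalid percent-encoding in URN id {raw_id!r}: {exc}"
        ) from exc
    return MiriamIdentifier(collection=m.group("collection"), entity_id=decoded)


def parse_url(url: str) -> MiriamIdentifier:
    """Parse ``http(s)://identifiers.org/<collection>/<id>``."""
    m = _URL_RE.fullmatch(url)
    if not m:
        raise AnnotationParseError(f"not an identifiers.org URL: {url!r}")
    return MiriamIdentifier(collection=m.group("collection"),
                            entity_id=m.group("id"))


def urn_to_url(urn: str) -> str:
    """Rewrite a MIRIAM URN as an identifiers.org URL (http host form)."""
    return parse_urn(urn).to_url()


def url_to_urn(url: str) -> str:
    """Rewrite an identifiers.org URL (http or https) as a MIRIAM URN."""
    return parse_url(url).to_urn()


@dataclass
class AnnotationReport:
    """Per-model conversion tally: resources rewritten vs left untouched."""

    converted: int = 0
    skipped: int = 0
    skipped_resources: list[str] = None

    def __post_init__(self):
        if self.skipped_resources is None:
            self.skipped_resources = []


def convert_model_annotations(
    model: SbmlModel, direction: str
) -> tuple[SbmlModel, AnnotationReport]:
    """Rewrite every CVTerm resource in the source scheme.

    ``direction`` is ``"urn_to_url"`` or ``"url_to_urn"``.  Resources
    already in the target scheme, or in neither scheme, are left untouched
    and counted in the report; nothing outside the annotations is changed.
    """
    if direction == "urn_to_url":
        transform = urn_to_url
    elif direction == "url_to_urn":
        transform = url_to_urn
    else:
        raise ValueError(
            f"direction must be 'urn_to_url' or 'url_to_urn', got {direction!r}"
        )
    out = copy.deepcopy(model)
    report = AnnotationReport()
    for terms in out.cv_terms.values():
        for term in terms:
            new_resources = []
            for resource in term.resources:
                try:
                    new_resources.append(transform(resource))
                    report.converted += 1
                except AnnotationParseError:
                    new_resources.append(resource)
                    report.skipped += 1
                    report.skipped_resources.append(resource)
            term.resources = new_resources
    return out, report
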