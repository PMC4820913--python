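"""SBML reading, writing and level conversion.

Supports the core constructs of SBML Level 2 Version 4 and Level 3
Version 1 needed for kinetic reaction-network models: compartments,
species, global parameters, reactions (with kinetic laws and local
parameters), assignment and rate rules, initial assignments, and MIRIAM
controlled-vocabulary annotations.  Events, constraints, algebraic rules
and all Level 3 packages are rejected loudly; function definitions are
accepted and expanded inline at read time.

Writing is deterministic: identical models produce identical bytes (fixed
attribute order, 2-space indent, UTF-8), which is what makes converter
composition byte-stable.
"""

from __future__ import annotations

import copy
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

from . import mathexpr
from .errors import SbmlReadError, UnsupportedConstructError, ValidationError
from .mathexpr import MathNode, format_number, parse_lambda, parse_mathml

__all__ = [
    "Compartment",
    "Species",
    "Parameter",
    "SpeciesReference",
    "KineticLaw",
    "Reaction",
    "Rule",
    "InitialAssignment",
    "CVTerm",
    "SbmlModel",
    "read_sbml",
    "write_sbml",
    "convert_level",
    "validate_model",
    "models_equal",
    "SUPPORTED_LEVELS",
]

NS_L2V4 = "http://www.sbml.org/sbml/level2/version4"
NS_L3V1 = "http://www.sbml.org/sbml/level3/version1/core"
SUPPORTED_LEVELS = {(2, 4): NS_L2V4, (3, 1): NS_L3V1}

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
BQMODEL_NS = "http://biomodels.net/model-qualifiers/"


@dataclass
class Compartment:
    id: str
    name: str = ""
    size: float | None = 1.0
    constant: bool = True
    spatial_dimensions: int = 3


@dataclass
class Species:
    id: str
    compartment: str
    name: str = ""
    initial_amount: float | None = None
    initial_concentration: float | None = None
    boundary_condition: bool = False
    constant: bool = False
    has_only_substance_units: bool = False


@dataclass
class Parameter:
    id: str
    value: float | None = None
    name: str = ""
    constant: bool = True


@dataclass
class SpeciesReference:
    species: str
    stoichiometry: float = 1.0


@dataclass
class KineticLaw:
    math: MathNode
    local_parameters: dict[str, float] = field(default_factory=dict)


@dataclass
class Reaction:
    id: str
    name: str = ""
    reversible: bool = False
    reactants: list[SpeciesReference] = field(default_factory=list)
    products: list[SpeciesReference] = field(default_factory=list)
    modifiers: list[str] = field(default_factory=list)
    kinetic_law: KineticLaw | None = None


@dataclass
class Rule:
    rule_type: str  # "assignment" | "rate"
    variable: str
    math: MathNode


@dataclass
class InitialAssignment:
    variable: str
    math: MathNode


@dataclass
class CVTerm:
    qualifier: str  # e.g. "bqbiol:is"
    resources: list[str] = field(default_factory=list)


@dataclass
class SbmlModel:
    """In-memory reaction-network model (level-agnostic core subset)."""

    id: str
    name: str = ""
    level: int = 3
    version: int = 1
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    rules: list[Rule] = field(default_factory=list)
    initial_assignments: list[InitialAssignment] = field(default_factory=list)
    cv_terms: dict[str, list[CVTerm]] = field(default_factory=dict)

    def element_ids(self) -> list[str]:
        out = [c.id for c in self.compartments]
        out += [s.id for s in self.species]
        out += [p.id for p in self.parameters]
        out += [r.id for r in self.reactions]
        return out

    def species_by_id(self, sid: str) -> Species:
        for s in self.species:
            if s.id == sid:
                return s
        raise KeyError(sid)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_model(model: SbmlModel) -> list[str]:
    """Return all invariant violations (empty list means valid)."""
    problems: list[str] = []
    ids = model.element_ids()
    seen: set[str] = set()
    for eid in ids:
        if eid in seen:
            problems.append(f"duplicate element id {eid!r}")
        seen.add(eid)
    compartment_ids = {c.id for c in model.compartments}
    species_ids = {s.id for s in model.species}
    parameter_ids = {p.id for p in model.parameters}
    for s in model.species:
        if s.compartment not in compartment_ids:
            problems.append(
                f"species {s.id!r} references missing compartment "
                f"{s.compartment!r}"
            )
        if s.initial_amount is not None and s.initial_concentration is not None:
            problems.append(
                f"species {s.id!r} has both initialAmount and "
                "initialConcentration"
            )
    for r in model.reactions:
        for role, refs in (("reactant", r.reactants), ("product", r.products)):
            seen_in_role: set[str] = set()
            for ref in refs:
                if ref.species not in species_ids:
                    problems.append(
                        f"reaction {r.id!r} {role} references missing species "
                        f"{ref.species!r}"
                    )
                if ref.stoichiometry <= 0:
                    problems.append(
                        f"reaction {r.id!r} {role} {ref.species!r} has "
                        f"non-positive stoichiometry {ref.stoichiometry}"
                    )
                if ref.species in seen_in_role:
                    problems.append(
                        f"reaction {r.id!r} lists {ref.species!r} twice as "
                        f"{role}"
                    )
                seen_in_role.add(ref.species)
        for m in r.modifiers:
            if m not in species_ids:
                problems.append(
                    f"reaction {r.id!r} modifier references missing species "
                    f"{m!r}"
                )
    ruled: set[str] = set()
    for rule in model.rules:
        if rule.rule_type not in ("assignment", "rate"):
            problems.append(f"unknown rule type {rule.rule_type!r}")
        if rule.variable not in species_ids | parameter_ids | compartment_ids:
            problems.append(
                f"rule variable {rule.variable!r} references no species, "
                "parameter or compartment"
            )
        if rule.variable in ruled:
            problems.append(f"variable {rule.variable!r} appears in two rules")
        ruled.add(rule.variable)
    if (model.level, model.version) not in SUPPORTED_LEVELS:
        problems.append(
            f"unsupported SBML level/version L{model.level}V{model.version}"
        )
    return problems


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _ns_of(tag: str) -> str:
    if tag.startswith("{"):
        return tag[1:].split("}", 1)[0]
    return ""


def _get_bool(el, attr: str, default: bool) -> bool:
    raw = el.get(attr)
    if raw is None:
        return default
    return raw in ("true", "1")


def _get_float(el, attr: str):
    raw = el.get(attr)
    return None if raw is None else float(raw)


def read_sbml(document: str) -> SbmlModel:
    """Parse an SBML L2v4 or L3v1 core document into an :class:`SbmlModel`.

    Document order of all list-of elements is preserved.  Constructs
    outside the supported subset raise
    :class:`~modelconv.errors.UnsupportedConstructError` naming the
    construct; an unrecognized namespace raises
    :class:`~modelconv.errors.SbmlReadError`.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise SbmlReadError(f"not well-formed XML: {exc}") from exc
    if _local(root.tag) != "sbml":
        raise SbmlReadError(f"root element is <{_local(root.tag)}>, not <sbml>")
    ns = _ns_of(root.tag)
    for (lvl, ver), known_ns in SUPPORTED_LEVELS.items():
        if ns == known_ns:
            level, version = lvl, ver
            break
    else:
        raise SbmlReadError(
            f"unsupported SBML namespace {ns!r}; supported: "
            f"{sorted(SUPPORTED_LEVELS.values())}"
        )

    model_el = None
    for child in root:
        if _local(child.tag) == "model":
            model_el = child
            break
    if model_el is None:
        raise SbmlReadError("document has no <model> element")

    model = SbmlModel(
        id=model_el.get("id", "model"),
        name=model_el.get("name", ""),
        level=level,
        version=version,
    )

    # First pass: reject unsupported top-level constructs, collect
    # function definitions so math can be expanded inline.
    fdefs: dict[str, tuple[list[str], MathNode]] = {}
    for section in model_el:
        tag = _local(section.tag)
        if tag in ("listOfEvents", "listOfConstraints"):
            raise UnsupportedConstructError(tag.replace("listOf", "").lower()[:-1]
                                            if tag.endswith("s") else tag)
        if tag == "listOfFunctionDefinitions":
            for fd in section:
                fid = fd.get("id")
                math_el = _find_math(fd)
                if math_el is None:
                    raise SbmlReadError(f"functionDefinition {fid!r} without math")
                fdefs[fid] = parse_lambda(math_el, fdefs)

    for section in model_el:
        tag = _local(section.tag)
        if tag == "listOfCompartments":
            for el in section:
                _read_compartment(el, level, model)
        elif tag == "listOfSpecies":
            for el in section:
                _read_species(el, model)
        elif tag == "listOfParameters":
            for el in section:
                _read_parameter(el, model)
        elif tag == "listOfReactions":
            for el in section:
                _read_reaction(el, level, model, fdefs)
        elif tag == "listOfRules":
            for el in section:
                _read_rule(el, model, fdefs)
        elif tag == "listOfInitialAssignments":
            for el in section:
                math_el = _find_math(el)
                if math_el is None:
                    raise SbmlReadError("initialAssignment without math")
                model.initial_assignments.append(
                    InitialAssignment(
                        variable=el.get("symbol"),
                        math=parse_mathml(math_el, fdefs),
                    )
                )
        elif tag == "annotation":
            terms = _read_cv_terms(section)
            if terms:
                model.cv_terms[model.id] = terms
        elif tag in ("listOfFunctionDefinitions", "listOfUnitDefinitions",
                     "notes"):
            pass  # function defs handled above; unit defs carried implicitly
        elif tag == "listOfEvents":
            raise UnsupportedConstructError("event")
        else:
            raise UnsupportedConstructError(f"model section <{tag}>")
    return model


def _find_math(el):
    for child in el:
        if _local(child.tag) == "math":
            return child
    return None


def _read_element_annotation(el, eid: str, model: SbmlModel) -> None:
    for child in el:
        if _local(child.tag) == "annotation":
            terms = _read_cv_terms(child)
            if terms:
                model.cv_terms[eid] = terms


def _read_compartment(el, level: int, model: SbmlModel) -> None:
    size = _get_float(el, "size")
    dims_raw = el.get("spatialDimensions")
    dims = 3 if dims_raw is None else int(float(dims_raw))
    comp = Compartment(
        id=el.get("id"),
        name=el.get("name", ""),
        size=size,
        constant=_get_bool(el, "constant", True),
        spatial_dimensions=dims,
    )
    model.compartments.append(comp)
    _read_element_annotation(el, comp.id, model)


def _read_species(el, model: SbmlModel) -> None:
    sp = Species(
        id=el.get("id"),
        compartment=el.get("compartment"),
        name=el.get("name", ""),
        initial_amount=_get_float(el, "initialAmount"),
        initial_concentration=_get_float(el, "initialConcentration"),
        boundary_condition=_get_bool(el, "boundaryCondition", False),
        constant=_get_bool(el, "constant", False),
        has_only_substance_units=_get_bool(el, "hasOnlySubstanceUnits", False),
    )
    model.species.append(sp)
    _read_element_annotation(el, sp.id, model)


def _read_parameter(el, model: SbmlModel) -> None:
    p = Parameter(
        id=el.get("id"),
        value=_get_float(el, "value"),
        name=el.get("name", ""),
        constant=_get_bool(el, "constant", True),
    )
    model.parameters.append(p)
    _read_element_annotation(el, p.id, model)


def _read_reaction(el, level: int, model: SbmlModel, fdefs) -> None:
    # L2 default for reversible is true; L3 requires it explicitly.
    reaction = Reaction(
        id=el.get("id"),
        name=el.get("name", ""),
        reversible=_get_bool(el, "reversible", level == 2),
    )
    for section in el:
        tag = _local(section.tag)
        if tag == "listOfReactants":
            reaction.reactants = [_read_species_ref(x) for x in section]
        elif tag == "listOfProducts":
            reaction.products = [_read_species_ref(x) for x in section]
        elif tag == "listOfModifiers":
            reaction.modifiers = [x.get("species") for x in section]
        elif tag == "kineticLaw":
            reaction.kinetic_law = _read_kinetic_law(section, fdefs)
        elif tag in ("annotation", "notes"):
            pass
        else:
            raise UnsupportedConstructError(
                f"reaction section <{tag}> in reaction {reaction.id!r}"
            )
    model.reactions.append(reaction)
    _read_element_annotation(el, reaction.id, model)


def _read_species_ref(el) -> SpeciesReference:
    sto = _get_float(el, "stoichiometry")
    return SpeciesReference(
        species=el.get("species"),
        stoichiometry=1.0 if sto is None else sto,
    )


def _read_kinetic_law(el, fdefs) -> KineticLaw:
    math_el = _find_math(el)
    if math_el is None:
        raise SbmlReadError("kineticLaw without math")
    locals_: dict[str, float] = {}
    for section in el:
        tag = _local(section.tag)
        if tag in ("listOfParameters", "listOfLocalParameters"):
            for p in section:
                locals_[p.get("id")] = float(p.get("value"))
    return KineticLaw(math=parse_mathml(math_el, fdefs),
                      local_parameters=locals_)


def _read_rule(el, model: SbmlModel, fdefs) -> None:
    tag = _local(el.tag)
    if tag == "algebraicRule":
        raise UnsupportedConstructError("algebraicRule")
    if tag == "assignmentRule":
        rtype = "assignment"
    elif tag == "rateRule":
        rtype = "rate"
    else:
        raise UnsupportedConstructError(f"rule <{tag}>")
    math_el = _find_math(el)
    if math_el is None:
        raise SbmlReadError(f"{tag} without math")
    model.rules.append(
        Rule(rule_type=rtype, variable=el.get("variable"),
             math=parse_mathml(math_el, fdefs))
    )


def _read_cv_terms(annotation_el) -> list[CVTerm]:
    terms: list[CVTerm] = []
    for rdf in annotation_el.iter(f"{{{RDF_NS}}}RDF"):
        for desc in rdf.iter(f"{{{RDF_NS}}}Description"):
            for qual_el in desc:
                ns = _ns_of(qual_el.tag)
                if ns == BQBIOL_NS:
                    prefix = "bqbiol"
                elif ns == BQMODEL_NS:
                    prefix = "bqmodel"
                else:
                    continue
                qualifier = f"{prefix}:{_local(qual_el.tag)}"
                resources = [
                    li.get(f"{{{RDF_NS}}}resource")
                    for bag in qual_el.iter(f"{{{RDF_NS}}}Bag")
                    for li in bag
                    if li.get(f"{{{RDF_NS}}}resource")
                ]
                if resources:
                    terms.append(CVTerm(qualifier=qualifier, resources=resources))
    return terms


# ---------------------------------------------------------------------------
# Writing (byte-deterministic)
# ---------------------------------------------------------------------------

def _xml_escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _attrs(pairs) -> str:
    """Render attributes in the given (fixed) order, skipping None values."""
    parts = []
    for key, value in pairs:
        if value is None:
            continue
        if isinstance(value, bool):
            value = "true" if value else "false"
        elif isinstance(value, float):
            value = format_number(value)
        parts.append(f'{key}="{_xml_escape(str(value))}"')
    return (" " + " ".join(parts)) if parts else ""


def write_sbml(model: SbmlModel) -> str:
    """Serialize deterministically; raises on invariant violations.

    The same model always yields byte-identical output: fixed attribute
    order per construct, 2-space indentation, UTF-8 text.
    """
    problems = validate_model(model)
    if problems:
        raise ValidationError(problems)
    level3 = model.level == 3
    ns = SUPPORTED_LEVELS[(model.level, model.version)]
    w: list[str] = ['<?xml version="1.0" encoding="UTF-8"?>']
    w.append(
        f'<sbml xmlns="{ns}" level="{model.level}" version="{model.version}">'
    )
    model_attrs = [("id", model.id)]
    if model.name:
        model_attrs.append(("name", model.name))
    w.append(f"  <model{_attrs(model_attrs)}>")
    _write_annotation(w, model.id, model.cv_terms.get(model.id), indent=2)

    if model.compartments:
        w.append("    <listOfCompartments>")
        for c in model.compartments:
            pairs = [("id", c.id)]
            if c.name:
                pairs.append(("name", c.name))
            if level3:
                pairs += [("spatialDimensions", float(c.spatial_dimensions)),
                          ("size", c.size), ("constant", c.constant)]
            else:
                pairs += [("spatialDimensions", c.spatial_dimensions),
                          ("size", c.size), ("constant", c.constant)]
            _write_leaf(w, "compartment", pairs, model, c.id, indent=3)
        w.append("    </listOfCompartments>")

    if model.species:
        w.append("    <listOfSpecies>")
        for s in model.species:
            pairs = [("id", s.id)]
            if s.name:
                pairs.append(("name", s.name))
            pairs.append(("compartment", s.compartment))
            pairs.append(("initialAmount", s.initial_amount))
            pairs.append(("initialConcentration", s.initial_concentration))
            if level3:
                pairs += [
                    ("hasOnlySubstanceUnits", s.has_only_substance_units),
                    ("boundaryCondition", s.boundary_condition),
                    ("constant", s.constant),
                ]
            else:
                pairs += [
                    ("hasOnlySubstanceUnits", s.has_only_substance_units),
                    ("boundaryCondition", s.boundary_condition),
                    ("constant", s.constant),
                ]
            _write_leaf(w, "species", pairs, model, s.id, indent=3)
        w.append("    </listOfSpecies>")

    if model.parameters:
        w.append("    <listOfParameters>")
        for p in model.parameters:
            pairs = [("id", p.id)]
            if p.name:
                pairs.append(("name", p.name))
            pairs += [("value", p.value), ("constant", p.constant)]
            _write_leaf(w, "parameter", pairs, model, p.id, indent=3)
        w.append("    </listOfParameters>")

    if model.initial_assignments:
        w.append("    <listOfInitialAssignments>")
        for ia in model.initial_assignments:
            w.append(f'      <initialAssignment symbol="{_xml_escape(ia.variable)}">')
            _write_math(w, ia.math, indent=4)
            w.append("      </initialAssignment>")
        w.append("    </listOfInitialAssignments>")

    if model.rules:
        w.append("    <listOfRules>")
        for rule in model.rules:
            tag = "assignmentRule" if rule.rule_type == "assignment" else "rateRule"
            w.append(f'      <{tag} variable="{_xml_escape(rule.variable)}">')
            _write_math(w, rule.math, indent=4)
            w.append(f"      </{tag}>")
        w.append("    </listOfRules>")

    if model.reactions:
        w.append("    <listOfReactions>")
        for r in model.reactions:
            _write_reaction(w, r, model, level3)
        w.append("    </listOfReactions>")

    w.append("  </model>")
    w.append("</sbml>")
    return "\n".join(w) + "\n"


def _write_leaf(w, tag, pairs, model, eid, indent):
    pad = "  " * indent
    terms = model.cv_terms.get(eid)
    if terms:
        w.append(f"{pad}<{tag}{_attrs(pairs)} metaid=\"meta_{_xml_escape(eid)}\">")
        _write_annotation(w, eid, terms, indent + 1)
        w.append(f"{pad}</{tag}>")
    else:
        w.append(f"{pad}<{tag}{_attrs(pairs)}/>")


def _write_annotation(w, eid, terms, indent):
    if not terms:
        return
    pad = "  " * indent
    w.append(f"{pad}<annotation>")
    w.append(
        f'{pad}  <rdf:RDF xmlns:rdf="{RDF_NS}" xmlns:bqbiol="{BQBIOL_NS}" '
        f'xmlns:bqmodel="{BQMODEL_NS}">'
    )
    w.append(f'{pad}    <rdf:Description rdf:about="#meta_{_xml_escape(eid)}">')
    for term in terms:
        w.append(f"{pad}      <{term.qualifier}>")
        w.append(f"{pad}        <rdf:Bag>")
        for res in term.resources:
            w.append(f'{pad}          <rdf:li rdf:resource="{_xml_escape(res)}"/>')
        w.append(f"{pad}        </rdf:Bag>")
        w.append(f"{pad}      </{term.qualifier}>")
    w.append(f"{pad}    </rdf:Description>")
    w.append(f"{pad}  </rdf:RDF>")
    w.append(f"{pad}</annotation>")


def _write_math(w, math: MathNode, indent):
    pad = "  " * indent
    body = mathexpr.serialize_mathml(math, wrap=True)
    for line in body.splitlines():
        w.append(f"{pad}{line}")


def _write_reaction(w, r: Reaction, model: SbmlModel, level3: bool):
    pairs = [("id", r.id)]
    if r.name:
        pairs.append(("name", r.name))
    pairs.append(("reversible", r.reversible))
    if level3:
        pairs.append(("fast", False))
    terms = model.cv_terms.get(r.id)
    metaid = f' metaid="meta_{_xml_escape(r.id)}"' if terms else ""
    w.append(f"      <reaction{_attrs(pairs)}{metaid}>")
    if terms:
        _write_annotation(w, r.id, terms, indent=4)
    for tag, refs in (("listOfReactants", r.reactants),
                      ("listOfProducts", r.products)):
        if refs:
            w.append(f"        <{tag}>")
            for ref in refs:
                ref_pairs = [("species", ref.species),
                             ("stoichiometry", ref.stoichiometry)]
                if level3:
                    ref_pairs.append(("constant", True))
                w.append(f"          <speciesReference{_attrs(ref_pairs)}/>")
            w.append(f"        </{tag}>")
    if r.modifiers:
        w.append("        <listOfModifiers>")
        for m in r.modifiers:
            w.append(
                f'          <modifierSpeciesReference species="{_xml_escape(m)}"/>'
            )
        w.append("        </listOfModifiers>")
    if r.kinetic_law is not None:
        w.append("        <kineticLaw>")
        _write_math(w, r.kinetic_law.math, indent=5)
        if r.kinetic_law.local_parameters:
            tag = "listOfLocalParameters" if level3 else "listOfParameters"
            leaf = "localParameter" if level3 else "parameter"
            w.append(f"          <{tag}>")
            for pid, val in r.kinetic_law.local_parameters.items():
                w.append(
                    f'            <{leaf} id="{_xml_escape(pid)}" '
                    f'value="{format_number(val)}"/>'
                )
            w.append(f"          </{tag}>")
        w.append("        </kineticLaw>")
    w.append("      </reaction>")


# ---------------------------------------------------------------------------
# Level conversion (the SBML-to-SBML rewriter)
# ---------------------------------------------------------------------------

def convert_level(model: SbmlModel, target_level: int,
                  target_version: int) -> SbmlModel:
    """Rewrite a model at another supported level/version.

    The in-memory representation is level-agnostic with all flags explicit,
    so within the supported subset the conversion is lossless: species,
    reactions, rules, kinetic laws and annotations are carried over
    unchanged; level-specific representation differences (which defaults
    must be written explicitly) are handled by the writer.
    """
    if (target_level, target_version) not in SUPPORTED_LEVELS:
        raise ValueError(
            f"unsupported target L{target_level}V{target_version}; "
            f"supported: {sorted(SUPPORTED_LEVELS)}"
        )
    out = copy.deepcopy(model)
    out.level = target_level
    out.version = target_version
    return out


# ---------------------------------------------------------------------------
# Semantic equality (used by round-trip tests and converters)
# ---------------------------------------------------------------------------

def models_equal(a: SbmlModel, b: SbmlModel, ignore_level: bool = False) -> bool:
    """Field-by-field semantic equality, order-sensitive."""
    if ignore_level:
        a = replace(copy.deepcopy(a), level=b.level, version=b.version)
    return (
        a.id == b.id and a.name == b.name
        and (ignore_level or (a.level, a.version) == (b.level, b.version))
        and a.compartments == b.compartments
        and a.species == b.species
        and a.parameters == b.parameters
        and a.reactions == b.reactions
        and a.rules == b.rules
        and a.initial_assignments == b.initial_assignments
        and a.cv_terms == b.cv_terms
    )
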