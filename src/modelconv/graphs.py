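"""Render a reaction network as a GraphViz Dot graph or an SBGN-ML map.

Both views share the same abstract bipartite graph: one node per species,
one node per reaction, consumption edges species->reaction, production
edges reaction->species, modulation edges species->reaction.

The Dot rendering draws species as boxes (labelled with name-or-id),
reactions as small circles, and modifier edges dashed.  The SBGN-ML
rendering is a process-description map: every species becomes a
"macromolecule" glyph, every reaction a "process" glyph, and arcs of class
consumption / production / catalysis mirror the bipartite edges.  Glyph
positions come from a deterministic fixed-pitch grid: species are placed
row-major in document order, and each process glyph is placed at the
centroid of its participants, nudged to the nearest free grid cell, so
bounding boxes never overlap and identical models get identical
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .sbml import SbmlModel

__all__ = [
    "BipartiteGraph",
    "SbgnGlyph",
    "SbgnArc",
    "SbgnMap",
    "model_to_bipartite",
    "to_dot",
    "read_dot_bipartite",
    "model_to_sbgn_map",
    "to_sbgnml",
]

SBGN_NS = "http://sbgn.org/libsbgn/0.2"

# grid geometry (abstract units)
_CELL_W, _CELL_H = 150.0, 90.0
_SPECIES_W, _SPECIES_H = 100.0, 50.0
_PROCESS_W, _PROCESS_H = 24.0, 24.0


@dataclass
class BipartiteGraph:
    species_nodes: list[tuple[str, str]] = field(default_factory=list)
    reaction_nodes: list[tuple[str, str]] = field(default_factory=list)
    edges: list[tuple[str, str, str]] = field(default_factory=list)
    # edge roles: consumption (species->reaction), production
    # (reaction->species), modulation (species->reaction)


def model_to_bipartite(model: SbmlModel) -> BipartiteGraph:
    graph = BipartiteGraph()
    for s in model.species:
        graph.species_nodes.append((s.id, s.name or s.id))
    for r in model.reactions:
        graph.reaction_nodes.append((r.id, r.name or r.id))
        for ref in r.reactants:
            graph.edges.append((ref.species, r.id, "consumption"))
        for ref in r.products:
            graph.edges.append((r.id, ref.species, "production"))
        for m in r.modifiers:
            graph.edges.append((m, r.id, "modulation"))
    return graph


# ---------------------------------------------------------------------------
# Dot
# ---------------------------------------------------------------------------

def _dot_quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(model: SbmlModel) -> str:
    """Render the model's bipartite reaction graph in Dot (digraph)."""
    graph = model_to_bipartite(model)
    lines = [f"digraph {_dot_quote(model.id)} {{"]
    for node_id, label in graph.species_nodes:
        lines.append(
            f"  {_dot_quote(node_id)} [shape=box, label={_dot_quote(label)}];"
        )
    for node_id, label in graph.reaction_nodes:
        lines.append(
            f"  {_dot_quote(node_id)} [shape=circle, width=0.2, "
            f"label={_dot_quote(label)}, fixedsize=true, fontsize=8];"
        )
    for source, target, role in graph.edges:
        attrs = " [style=dashed, arrowhead=odot]" if role == "modulation" else ""
        lines.append(f"  {_dot_quote(source)} -> {_dot_quote(target)}{attrs};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def read_dot_bipartite(text: str) -> BipartiteGraph:
    """Minimal reader for the Dot dialect :func:`to_dot` emits.

    Reconstructs the abstract bipartite graph: node kind from the shape
    attribute, edge role from direction and style.
    """
    graph = BipartiteGraph()
    species: set[str] = set()
    edge_lines: list[tuple[str, str, bool]] = []
    for raw in text.splitlines():
        line = raw.strip().rstrip(";")
        if not line or line.startswith("digraph") or line == "}":
            continue
        if "->" in line:
            left, right = line.split("->", 1)
            dashed = "style=dashed" in right
            if "[" in right:
                right = right[: right.index("[")]
            edge_lines.append(
                (_dot_unquote(left.strip()), _dot_unquote(right.strip()), dashed)
            )
        elif "[" in line:
            name = _dot_unquote(line[: line.index("[")].strip())
            attrs = line[line.index("["):]
            label = name
            if "label=" in attrs:
                rest = attrs.split("label=", 1)[1]
                label = _dot_unquote_prefix(rest)
            if "shape=box" in attrs:
                graph.species_nodes.append((name, label))
                species.add(name)
            else:
                graph.reaction_nodes.append((name, label))
    for source, target, dashed in edge_lines:
        if dashed:
            role = "modulation"
        elif source in species:
            role = "consumption"
        else:
            role = "production"
        graph.edges.append((source, target, role))
    return graph


def _dot_unquote(token: str) -> str:
    token = token.strip()
    if token.startswith('"') and token.endswith('"'):
        token = token[1:-1]
    return token.replace('\\"', '"').replace("\\\\", "\\")


def _dot_unquote_prefix(rest: str) -> str:
    """Extract a quoted string from the start of an attribute tail."""
    if not rest.startswith('"'):
        return rest.split(",")[0].rstrip("]")
    out = []
    i = 1
    while i < len(rest):
        ch = rest[i]
        if ch == "\\" and i + 1 < len(rest):
            out.append(rest[i + 1])
            i += 2
            continue
        if ch == '"':
            break
        out.append(ch)
        i += 1
    return "".join(out)


# ---------------------------------------------------------------------------
# SBGN-ML
# ---------------------------------------------------------------------------

@dataclass
class SbgnGlyph:
    id: str
    cls: str  # macromolecule | simple chemical | process | compartment
    label: str
    x: float
    y: float
    w: float
    h: float


@dataclass
class SbgnArc:
    id: str
    cls: str  # consumption | production | catalysis
    source: str
    target: str


@dataclass
class SbgnMap:
    glyphs: list[SbgnGlyph] = field(default_factory=list)
    arcs: list[SbgnArc] = field(default_factory=list)


def model_to_sbgn_map(model: SbmlModel) -> SbgnMap:
    """Build the process-description map with the deterministic grid layout."""
    sbgn = SbgnMap()
    n_cells = len(model.species) + len(model.reactions)
    n_cols = max(1, math.ceil(math.sqrt(max(n_cells, 1))))
    occupied: set[tuple[int, int]] = set()
    cell_of: dict[str, tuple[int, int]] = {}

    def cell_center(cell: tuple[int, int]) -> tuple[float, float]:
        col, row = cell
        return (col + 0.5) * _CELL_W, (row + 0.5) * _CELL_H

    for i, s in enumerate(model.species):
        cell = (i % n_cols, i // n_cols)
        occupied.add(cell)
        cell_of[s.id] = cell
        cx, cy = cell_center(cell)
        sbgn.glyphs.append(
            SbgnGlyph(
                id=f"glyph_{s.id}", cls="macromolecule", label=s.name or s.id,
                x=cx - _SPECIES_W / 2, y=cy - _SPECIES_H / 2,
                w=_SPECIES_W, h=_SPECIES_H,
            )
        )

    arc_counter = 0
    for r in model.reactions:
        participants = (
            [ref.species for ref in r.reactants]
            + [ref.species for ref in r.products]
            + list(r.modifiers)
        )
        cells = [cell_of[p] for p in participants if p in cell_of]
        if cells:
            mean_col = sum(c[0] for c in cells) / len(cells)
            mean_row = sum(c[1] for c in cells) / len(cells)
        else:
            mean_col = mean_row = 0.0
        cell = _nearest_free_cell(mean_col, mean_row, occupied)
        occupied.add(cell)
        cx, cy = cell_center(cell)
        process_id = f"process_{r.id}"
        sbgn.glyphs.append(
            SbgnGlyph(
                id=process_id, cls="process", label="",
                x=cx - _PROCESS_W / 2, y=cy - _PROCESS_H / 2,
                w=_PROCESS_W, h=_PROCESS_H,
            )
        )
        for ref in r.reactants:
            sbgn.arcs.append(
                SbgnArc(f"arc{arc_counter}", "consumption",
                        f"glyph_{ref.species}", process_id)
            )
            arc_counter += 1
        for ref in r.products:
            sbgn.arcs.append(
                SbgnArc(f"arc{arc_counter}", "production",
                        process_id, f"glyph_{ref.species}")
            )
            arc_counter += 1
        for m in r.modifiers:
            sbgn.arcs.append(
                SbgnArc(f"arc{arc_counter}", "catalysis",
                        f"glyph_{m}", process_id)
            )
            arc_counter += 1
    return sbgn


def _nearest_free_cell(col: float, row: float,
                       occupied: set[tuple[int, int]]) -> tuple[int, int]:
    """Nearest free non-negative grid cell; deterministic tie-break."""
    base = (round(col), round(row))
    best = None
    for radius in range(0, 1000):
        candidates = []
        for dc in range(-radius, radius + 1):
            for dr in range(-radius, radius + 1):
                if max(abs(dc), abs(dr)) != radius:
                    continue
                cand = (base[0] + dc, base[1] + dr)
                if cand[0] < 0 or cand[1] < 0 or cand in occupied:
                    continue
                dist = (cand[0] - col) ** 2 + (cand[1] - row) ** 2
                candidates.append((dist, cand))
        if candidates:
            candidates.sort()
            best = candidates[0][1]
            break
    if best is None:  # pragma: no cover - grid effectively unbounded
        raise RuntimeError("no free grid cell found")
    return best


def _xml_escape(text: str) -> str:
    return (
        text.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;")
        .replace('"', "&quot;")
    )


def _fmt(value: float) -> str:
    if value == int(value):
        return str(int(value))
    return repr(value)


def to_sbgnml(model: SbmlModel) -> str:
    """Serialize the model as an SBGN-ML 0.2 process-description document."""
    sbgn = model_to_sbgn_map(model)
    lines = ['<?xml version="1.0" encoding="UTF-8"?>']
    lines.append(f'<sbgn xmlns="{SBGN_NS}">')
    lines.append('  <map language="process description">')
    for g in sbgn.glyphs:
        lines.append(f'    <glyph id="{_xml_escape(g.id)}" class="{g.cls}">')
        if g.label:
            lines.append(f'      <label text="{_xml_escape(g.label)}"/>')
        lines.append(
            f'      <bbox x="{_fmt(g.x)}" y="{_fmt(g.y)}" '
            f'w="{_fmt(g.w)}" h="{_fmt(g.h)}"/>'
        )
        lines.append("    </glyph>")
    for a in sbgn.arcs:
        lines.append(
            f'    <arc id="{a.id}" class="{a.cls}" '
            f'source="{_xml_escape(a.source)}" target="{_xml_escape(a.target)}"/>'
        )
    lines.append("  </map>")
    lines.append("</sbgn>")
    return "\n".join(lines) + "\n"
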