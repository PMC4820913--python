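"""Render a reaction network as GraphViz Dot and as an SBGN-ML map.

Uses the enzyme-catalysis fixture (E modifies S -> P): the Dot output has
3 species boxes + 1 reaction circle and a dashed modifier edge; the
SBGN-ML map has 4 glyphs (3 macromolecule + 1 process) and 3 arcs
(1 consumption, 1 production, 1 catalysis), with grid-layout coordinates.
"""

from modelconv import corpus, to_dot, to_sbgnml
from modelconv.graphs import model_to_sbgn_map

model = dict(corpus())["with_modifiers"]

print(to_dot(model))
sbgn = model_to_sbgn_map(model)
print(f"SBGN map: {len(sbgn.glyphs)} glyphs, {len(sbgn.arcs)} arcs")
for arc in sbgn.arcs:
    print(f"  {arc.cls}: {arc.source} -> {arc.target}")
print()
print(to_sbgnml(model))
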