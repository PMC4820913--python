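"""Chain existing converters into a new one.

Composes the SBML level up-converter with the Octave exporter into a
single L2-SBML-to-Octave converter; its output is byte-identical to
running the two steps manually — which is what makes new converters cheap
to add on top of existing ones.
"""

from modelconv import compose, corpus, default_registry, write_sbml
from modelconv.formats import SbmlDocumentModel

registry = default_registry()
print("available converters:", ", ".join(registry.converter_names()))

level_up = registry.get_converter("SBML2SBML")
to_octave = registry.get_converter("SBML2Octave")
l2_to_octave = compose(level_up, to_octave)

model = dict(corpus())["ab_mass_action"]  # an L2v4 model
doc = SbmlDocumentModel.from_string(write_sbml(model))
chained = l2_to_octave.convert(doc).to_string()
manual = to_octave.convert(level_up.convert(doc)).to_string()
print("composed == manual two-step:", chained == manual)
print(f"composed converter: {l2_to_octave.descriptor.name} "
      f"({l2_to_octave.descriptor.input_format.name} -> "
      f"{l2_to_octave.descriptor.output_format.name})")
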