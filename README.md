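# modelconv

A modular format-conversion framework for systems-biology models.

Kinetic models in systems biology are exchanged as SBML, but the tools that
simulate, continue, or draw them each speak their own language: GNU
Octave/Matlab want an m-file with a derivative function, XPPAUT wants a
`.ode` file, GraphViz wants Dot, and pathway viewers want SBGN-ML maps.
`modelconv` is a library (plus a thin CLI) for modellers and tool authors
that turns SBML Level 2 Version 4 / Level 3 Version 1 kinetic models into
those formats, converts between SBML levels, and rewrites MIRIAM URN
annotations (`urn:miriam:<collection>:<id>`) to identifiers.org URLs and
back.

The architectural idea is a single conversion contract: every format is a
*general model* (a format descriptor plus text read/write), every conversion
a *general converter* with declared input/output formats, and a registry
dispatches by name after checking the model's format URI. Because all
converters share the contract, they compose: chaining `A2B` and `B2C` yields
an `A2C` whose output is byte-identical to the manual two-step run, so new
converters can be assembled from existing ones without touching the core.

## The mathematics underneath

For a reaction network with dynamic species vector **x**, stoichiometry
matrix **N** (rows = species, columns = reactions, entries = net
product-minus-reactant stoichiometry) and kinetic-law rate vector
**v**(**x**, *t*), every ODE exporter emits

&nbsp;&nbsp;&nbsp;&nbsp;d**x**/dt = **N** · **v**(**x**, *t*)

plus one equation per SBML rate rule. Kinetic laws arrive as content MathML
and are held as operator trees that can be printed in each target dialect
and evaluated numerically; that internal right-hand side is the oracle every
exported file is checked against. Left-null vectors **c** of **N**
(**c**·**N** = 0) are conservation laws — the test-suite verifies
**c**·d**x**/dt = 0 along random states of every closed network.

## Worked example

```python
from modelconv import build_ode_system, corpus, rhs, to_octave

model = dict(corpus())["ab_mass_action"]   # A -> B, v = k*A, k = 2, A(0) = 10
system = build_ode_system(model)
print(system.state_ids)                    # ['A', 'B']
print(system.stoichiometry.tolist())       # [[-1.0], [1.0]]
print(rhs(system, system.initial_state))   # {'A': -20.0, 'B': 20.0}
```

The derivative at the initial state is (−20, +20): A is consumed at
k·A = 2·10 = 20 per time unit and B gains exactly that flux. Exporting the
same system (`to_octave(system, model)`) yields an m-file whose core is

```
function xdot = rhs_state(t, x)
  xdot = zeros(2, 1);
  xdot(1) = -(2 * x(1));
  xdot(2) = 2 * x(1);
end
```

and `to_xpp` produces the matching `dA/dt=-(2*A)` / `init A=10` / `done`
lines for XPPAUT. The scripts in `examples/` run each capability end to end
(ODE export, Dot/SBGN-ML rendering, annotation rewriting, converter
composition) and print what the numbers mean.

## Command line

```sh
modelconv list                                  # formats and converters
modelconv convert SBMLModel SBML2Octave model.xml
modelconv sbml2xpp models/                      # batch: every *.xml inside
modelconv urn2url model.xml --outdir out/ --json-summary
```

Batch mode converts each matching file independently; a per-file failure is
reported without aborting the rest (exit code 2 if any job failed).

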