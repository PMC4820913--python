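# Methods

This note records the model of conversion the package implements, the
choices made where the design was genuinely open, and what the test corpus
does and does not establish.

## Conversion contract and dispatch

A format is identified by a URI: an identifiers.org entry where one exists
(SBML, SBGN), an internet media type (`text/vnd.graphviz` for Dot), or a
minted stable placeholder `urn:modelconv:format:<name>` (Octave, Matlab,
XPP). A converter declares one input and one output format and refuses, with
a typed error naming both URIs, any model whose format URI is not exactly
its declared input. URI comparison is **exact string equality**; aliasing
between a media type and an identifiers.org URI for the same format is
deliberately not attempted (it would make dispatch depend on registry
state). Several model classes may serve one format URI; the registry
therefore keys converters by *name*, not by format pair. Failures inside
conversion logic are wrapped in a single typed error carrying the converter
name and cause — partial output is never returned.

Composition (`compose(A2B, B2C)`) simply runs the two `convert()` calls in
sequence, which is why composed output is byte-identical to the manual
chain and composition is associative; both properties are asserted over the
whole fixture corpus.

## Supported SBML subset

Levels 2v4 and 3v1 (core only), with compartments, species, global and
local parameters, reactions (reactants/products/modifiers, kinetic laws),
assignment and rate rules, initial assignments, and RDF
controlled-vocabulary annotations. Events, constraints, algebraic rules and
all L3 packages raise a named unsupported-construct error: these constructs
change simulation semantics, and silent partial support would produce
wrong-but-plausible exports. Function definitions are accepted and expanded
inline at read time (lambda application by substitution), so downstream
modules never see them. Element ids are never renamed by read/write; only
the exporters sanitize. Serialization is byte-deterministic (UTF-8, 2-space
indent, fixed attribute order per construct) because composed-converter
byte identity and the write-idempotence check depend on it.

Level conversion is implemented on the level-agnostic in-memory model: all
flags that one level defaults and the other requires (constant flags,
spatial dimensions, hasOnlySubstanceUnits, reversible) are stored
explicitly, so within this subset L2v4 ↔ L3v1 is lossless by construction
and conversion reduces to relabeling plus writer-side representation
differences.

## Expression trees

Kinetic-law mathematics is held as an operator tree over the subset that
covers mass-action, Michaelis–Menten and Hill kinetics plus piecewise
switching: `plus, minus, times, divide, power`, the relational and logical
operators, `exp, ln, log10, sqrt, abs, floor, ceiling, sin, cos, tan`, and
`piecewise`. The MathML csymbol for simulation time maps to the symbol `t`;
avogadro maps to its numeric value. `<log/>` without a base means log10
(only base 10 is accepted); `<root/>` without a degree means square root.
Delay, factorial and vector constructs are rejected by name.

Dialect printing rules, chosen for determinism over elegance:

- every compound child is parenthesized — precedence subtleties of the
  target grammars are never relied on;
- numbers print as the shortest decimal that round-trips the binary value,
  integers without a decimal point; the XPP dialect forces e-notation
  outside [1e-4, 1e6];
- natural log `ln` prints as `log(x)` (Octave/Matlab/XPP all use `log` for
  the natural logarithm); `log10` stays `log10`;
- relational operators print as `(a < b)` etc., which evaluate to 0/1 in
  all three target languages;
- logical operators and `piecewise` print as indicator arithmetic over
  those 0/1 values: `and` → product, `or` → a + b − a·b, `not` → 1 − a, and
  piecewise as nested `(cond * value + (1 - cond) * (rest))`. This needs no
  helper function in the generated files and evaluates identically in every
  target;
- piecewise cannot be printed as a Dot label and raises a dialect error.

Evaluation follows IEEE semantics (division by zero → signed infinity,
0/0 → NaN, negative base with fractional exponent → NaN). Substitution
resolves chains to a fixed point and raises a cycle error listing the
cycle, which is also how cyclic assignment rules are detected.

## ODE derivation

A species is dynamic iff it is neither boundary nor constant and is not
governed by an assignment rule. The state variable is the species' amount
if `initialAmount` is given, else its concentration; kinetic laws are used
exactly as written (SBML defines them in amount/time) and compartment sizes
enter as constants — unit reconciliation is out of scope and documented as
such. Species with no initial value default to 0 with a warning. Reversible
reactions keep their single signed kinetic law; no forward/backward
splitting. State and reaction order follow SBML document order, which makes
every export deterministic. Rate-rule variables (species or parameters) are
carried as additional ODE variables with their own initial values, because
the XPP exporter must emit them as state lines.

Initial assignments are evaluated once over constants plus raw initial
values, in document order.

## Code generation

The m-file contains `init_state()` and `rhs_state(t, x)` with one
`xdot(i) = …` line per state over indexed variables `x(i)`; the identifier
map and inlined constant values are recorded in header comments, and a
solver invocation appears in comments only (octave: `lsode`; matlab:
`ode45`) so the file is testable without any numerical environment
installed — the two dialects differ in nothing but those comment lines.
Constants are substituted numerically into the rate expressions, which
makes each emitted expression close over states and `t` only.

XPP files carry `d<name>/dt=`, `init`, `param` and `done` lines. Constants
are both inlined into the ODE lines (self-containment, and the natural
reading of a rate like `-(2*A)`) and declared as `param` lines (XPP accepts
unused parameters). XPP names are at most 9 characters and
case-insensitive: sanitization maps non-alphanumerics to `_`, prefixes a
leading digit, truncates to 7 characters and appends a 2-digit counter on
(case-folded) collision. The symbol `t` is reserved in every identifier map
so a species named `t` cannot shadow time.

## Graph export

Dot and SBGN-ML share one abstract bipartite graph: species and reaction
nodes, consumption (species→reaction), production (reaction→species) and
modulation (species→reaction) edges. Dot draws species as boxes labelled
name-or-id, reactions as small circles, modifier edges dashed, with
standard quote escaping. SBGN-ML 0.2 process-description maps use class
"macromolecule" for every species (no SBO-term mapping — listed as an
extension point) and one "process" glyph per reaction; reversible reactions
keep plain consumption/production arcs. Layout is a fixed-pitch grid
(150×90 units, species boxes 100×50, process glyphs 24×24): species
row-major in document order, each process at the centroid of its
participants nudged to the nearest free cell (deterministic ring search
with distance-then-order tie-break). Because every glyph is centered in its
own cell and strictly smaller than the cell, boxes can touch but never
overlap, with no external layout engine.

## Annotation rewriting

`urn:miriam:<collection>:<id>` ↔ `http://identifiers.org/<collection>/<id>`
is a pure syntax transform: collections are validated against the lowercase
dot-separated-token grammar only — no network lookup of the live registry,
so results are deterministic offline (a local registry snapshot hook is a
possible extension). Encoding policy: building a URN percent-encodes every
id character outside the RFC 3986 unreserved set (in particular `:` and
`%`); decoding accepts any valid percent sequence. Encoding strictly more
than MIRIAM historically required costs nothing and guarantees the
round-trip identity in both directions. Resources in the target scheme or
in neither scheme (including strings valid in both grammars only as their
own scheme) are left untouched and counted in the conversion report.

## Synthetic networks and the fixture corpus

The generator is a pure function of its spec (species count, reaction
count, reversible fraction, kinetics family, seed): each reaction draws 1–2
reactants and 1–2 products with no species repeated within a role, rate
constants are log-uniform on [1e-2, 1e2] and initial amounts uniform on
[1, 100] — magnitudes typical of the curated kinetic models these
converters serve. The hand corpus pins each construct: mass-action chain,
reversible pair at detailed balance, Michaelis–Menten substrate cycle,
closed three-species cascade (nontrivial conservation law), modifier,
assignment/rate/piecewise rules with an initial assignment, URN
annotations, pathological identifiers (truncation collisions, non-ASCII
names), and a reaction-free model.

What passing these tests shows: structural and numerical correctness of
every conversion pathway on models within the supported subset, at the
sizes the corpus exercises (≤ ~12 species). What it does not show: behaviour
on real curated models using events, delays, units, or L3 packages (all
rejected by design), and it does not execute the generated files under real
Octave/Matlab/XPPAUT — equivalence is established by re-parsing the printed
expressions with an independent infix grammar and comparing numerics
against the in-memory right-hand side (tolerance 1e-9 absolute over 100
random states per file; level-conversion commutation is checked at 1e-12).

## Problem sizes

The verification harness (`scripts/acceptance.py` and the test-suite) uses
the 9-model hand corpus plus 50 generated networks of 3–7 species and 2–7
reactions, 100 random states per numerical check and 1000 randomized
annotation identifiers — sizes at which every property is exercised while
the whole run stays near-instant.
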