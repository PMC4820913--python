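"""Derive the ODE system of a small reaction network and export it.

Builds the two-species mass-action chain A -> B (v = k*A, k = 2,
A(0) = 10), derives dx/dt = N.v(x), and prints the generated Octave m-file
and XPPAUT .ode file.  The printed derivative at the initial state is
(-20, +20): A decays at rate k*A = 2*10 and B gains the same flux.
"""

from modelconv import build_ode_system, corpus, rhs, to_octave, to_xpp

model = dict(corpus())["ab_mass_action"]
system = build_ode_system(model)

print("state vector:", system.state_ids)
print("stoichiometry matrix:\n", system.stoichiometry)
print("rhs at initial state:", rhs(system, system.initial_state))
print()
print("--- Octave m-file " + "-" * 40)
print(to_octave(system, model, dialect="octave"))
print("--- XPP .ode file " + "-" * 40)
print(to_xpp(system, model))
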