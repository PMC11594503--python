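"""What a 10 kJ catabolic budget buys at the proton-motive force.

A recurring argument for a minimum biological energy quantum is that small
reaction energies cannot be conserved.  Dividing a 10 kJ/mol budget by the
cost of pumping one mole of protons across a typical membrane gradient —
and by the phosphorylation cost of ATP — shows it is far from nothing.
"""

from poregibbs import MembraneState, atp_yield, pmf_energy_per_proton, protons_translocatable

state = MembraneState(delta_psi_mv=120.0, delta_ph=-0.5, temperature=25.0, dG_ATP=60.0)
budget = 10.0  # kJ per mol reaction

cost = pmf_energy_per_proton(state)
n_mol, n_protons = protons_translocatable(budget, state)
n_mol_lit, _ = protons_translocatable(budget, state, convention="literal")
atp = atp_yield(budget, state.dG_ATP)

print(f"membrane state: {state.delta_psi_mv:.0f} mV, dpH {state.delta_ph}, {state.temperature:.0f} C")
print(f"per-proton cost:          {cost:.2f} kJ/mol H+")
print(f"protons per mol reaction: {n_mol:.3f} mol ({n_protons:.2e} protons)")
print(f"  (literal sign reading:  {n_mol_lit:.3f} mol)")
print(f"ATP yield at 60 kJ/mol:   {atp:.3f} mol ATP per mol reaction")
print(f"ATP yield at 75 kJ/mol:   {atp_yield(budget, 75.0):.3f} (older, higher ATP cost)")
print("\nA fifth of a mole of ATP per mole of reaction is ample to sustain")
print("life, arguing against a hard minimum energy quantum.")
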