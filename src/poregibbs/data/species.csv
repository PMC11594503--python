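name,charge,dG_f_kJ_mol,S_J_mol_K,ion_size_A,C,H,O,S_atoms,provenance
HCO3-,-1,-586.940,98.450,3.787,1,1,3,0,SUPCRT92 aqueous species (converted from cal/mol); ion size calibrated to gamma=0.661 at I=0.7 M and 24 C
CO2(aq),0,-385.974,117.570,,1,0,2,0,SUPCRT92 aqueous species (converted from cal/mol)
CO3--,-2,-527.983,-50.000,4.5,1,0,3,0,SUPCRT92 aqueous species (converted from cal/mol); ion size from the Kielland compilation
CH4(aq),0,-34.451,87.822,,1,4,0,0,SUPCRT92 aqueous species (converted from cal/mol)
H2(aq),0,17.723,57.739,,0,2,0,0,SUPCRT92 aqueous species (converted from cal/mol)
SO4--,-2,-744.459,18.828,4.0,0,0,4,1,SUPCRT92 aqueous species (converted from cal/mol); ion size from the Kielland compilation
HS-,-1,11.966,68.199,3.5,0,1,0,1,SUPCRT92 aqueous species (converted from cal/mol); ion size from the Kielland compilation
H+,1,0.000,0.000,9.0,0,1,0,0,convention (zero by definition); ion size from the Kielland compilation
H2O,0,-237.183,69.923,,0,2,1,0,SUPCRT92 liquid water (converted from cal/mol)
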