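"""Physical constants in the package's working units (kJ/mol, ps, Å, amu, K)."""

#: Molar gas constant, kJ/mol/K.
R_KJ = 8.314462618e-3

#: Planck constant times Avogadro's number, kJ·ps/mol.
H_PLANCK = 0.399031271

#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Conversion factor: 1 amu·Å²/ps² expressed in kJ/mol.
AMU_A2_PS2_TO_KJ_MOL = 0.01

#: Number density of a 1 mol/L solution, molecules per nm³.
C_STANDARD_PER_NM3 = 0.602214076

#: 1 kcal in kJ.
KCAL_TO_KJ = 4.184

#: PV term of 1 bar · 1 nm³, in kJ/mol.
BAR_NM3_TO_KJ_MOL = 1.0e5 * 1.0e-27 * N_AVOGADRO / 1000.0
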