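"""Physical constants and unit conventions.

Units throughout the package: distances in Angstrom, energies in
kcal/mol, charges in elementary charge (e), temperatures in Kelvin,
times in picoseconds, masses in Dalton.
"""

#: Coulomb constant in kcal A mol^-1 e^-2 (electrostatic energy = K q1 q2 / r).
K_COULOMB = 332.0636

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.98720425e-3

#: Hartree to kcal/mol conversion.
HARTREE_TO_KCAL = 627.5095

#: Average-mass difference between fluorine and hydrogen (Da); the shift
#: incurred per H -> F substitution on an aromatic ring.
F_MINUS_H_MASS = 17.9905

#: Number density of bulk water at ambient conditions (A^-3).
BULK_WATER_DENSITY = 0.0334

#: Default analysis temperature (K).
DEFAULT_TEMPERATURE = 298.15
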