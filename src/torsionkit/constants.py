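"""Physical constants and unit-conversion factors used throughout the toolkit.

Internal units are kcal/mol for energies, radians for angles, Angstrom for
distances and Kelvin for temperatures.  Everything else is converted at the
I/O boundary.
"""

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL = 0.0019872041

#: kJ per kcal (thermochemical calorie).
KJ_PER_KCAL = 4.184

#: Hartree to kcal/mol.
HARTREE_TO_KCAL = 627.509474

#: Angstrom per nanometre.
ANGSTROM_PER_NM = 10.0

#: Volume per molecule at the standard concentration C0 = 1 mol/L, in A^3.
#: 1 L / N_A = 1e27 A^3 / 6.02214076e23.
C0_VOLUME_A3 = 1660.5389

TWO_PI = 6.283185307179586
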