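"""Bundled reference study: baricitinib solubility in DMSO + water mixtures.

This module carries the published experimental dataset and physical
constants for the baricitinib (BNB) / dimethyl sulfoxide (DMSO) / water
co-solvency system, measured by the isothermal shake-flask method at
0.1 MPa over 298.2-323.2 K.  Eleven solvent compositions (DMSO mass
fraction m = 0.0 ... 1.0 in steps of 0.1) were each equilibrated at five
temperatures, giving a 55-cell mole-fraction solubility surface.

One cell of the published table, (m = 0.2, T = 323.2 K), is printed as
7.05e-5, which breaks the otherwise universal monotone increase of
solubility with temperature and contradicts the van't Hoff correlation
published for that same series (a = 16.31, b = -7610.3 K predicts
~7.2e-4 at 323.2 K).  The bundled dataset stores the cell as 7.05e-4 and
records the correction in the grid's provenance notes; the verbatim
value is available via ``load_reference_dataset(corrected=False)``.
"""

from __future__ import annotations

# Study temperatures, K
TEMPERATURES_K: tuple[float, ...] = (298.2, 303.2, 308.2, 313.2, 323.2)

# Mole-fraction solubility x_e by DMSO mass fraction, one value per
# temperature in TEMPERATURES_K order.  The (0.2, 323.2 K) cell carries
# the power-of-ten correction described in the module docstring.
SOLUBILITY_X: dict[float, tuple[float, ...]] = {
    0.0: (2.23e-5, 3.90e-5, 5.61e-5, 8.02e-5, 1.71e-4),
    0.1: (4.66e-5, 7.99e-5, 1.17e-4, 1.65e-4, 3.57e-4),
    0.2: (9.29e-5, 1.65e-4, 2.36e-4, 3.36e-4, 7.05e-4),
    0.3: (1.99e-4, 3.34e-4, 4.79e-4, 6.83e-4, 1.42e-3),
    0.4: (4.09e-4, 6.77e-4, 9.72e-4, 1.41e-3, 2.79e-3),
    0.5: (8.43e-4, 1.41e-3, 2.00e-3, 2.83e-3, 5.52e-3),
    0.6: (1.76e-3, 2.83e-3, 4.07e-3, 5.75e-3, 1.10e-2),
    0.7: (3.60e-3, 5.78e-3, 8.25e-3, 1.19e-2, 2.18e-2),
    0.8: (7.42e-3, 1.18e-2, 1.69e-2, 2.40e-2, 4.32e-2),
    0.9: (1.55e-2, 2.40e-2, 3.44e-2, 4.86e-2, 8.53e-2),
    1.0: (3.15e-2, 4.86e-2, 6.96e-2, 9.85e-2, 1.69e-1),
}

# Reported standard deviations of x_e, same layout and exponents as
# SOLUBILITY_X (a printed "2.23 (0.02) x 10^-5" becomes sd 0.02e-5).
SOLUBILITY_SD: dict[float, tuple[float, ...]] = {
    0.0: (0.02e-5, 0.03e-5, 0.03e-5, 0.03e-5, 0.01e-4),
    0.1: (0.04e-5, 0.05e-5, 0.03e-4, 0.03e-4, 0.04e-4),
    0.2: (0.05e-5, 0.01e-4, 0.02e-4, 0.03e-4, 0.05e-4),
    0.3: (0.03e-4, 0.04e-4, 0.05e-4, 0.06e-4, 0.06e-3),
    0.4: (0.01e-4, 0.02e-4, 0.04e-4, 0.03e-3, 0.04e-3),
    0.5: (0.06e-4, 0.07e-3, 0.08e-3, 0.07e-3, 0.08e-3),
    0.6: (0.07e-3, 0.07e-3, 0.08e-3, 0.08e-3, 0.09e-2),
    0.7: (0.06e-3, 0.07e-3, 0.07e-3, 0.08e-2, 0.08e-2),
    0.8: (0.04e-3, 0.03e-2, 0.05e-2, 0.05e-2, 0.06e-2),
    0.9: (0.01e-2, 0.03e-2, 0.03e-2, 0.04e-2, 0.04e-2),
    1.0: (0.02e-2, 0.04e-2, 0.05e-2, 0.05e-2, 0.01e-1),
}

UNCORRECTED_CELL = (0.2, 323.2)
UNCORRECTED_VALUE = 7.05e-5
CORRECTION_NOTE = (
    "cell (m=0.2, T=323.2 K): published value 7.05e-5 treated as a "
    "power-of-ten typo and stored as 7.05e-4; the published value breaks "
    "the monotone temperature trend of every series and contradicts the "
    "published van't Hoff correlation for the m=0.2 series "
    "(a=16.31, b=-7610.3 K -> x ~ 7.2e-4 at 323.2 K)"
)

# Molar masses as published in the study's materials table, g/mol.
# Note water is given there as 18.07 g/mol (standard value 18.015); the
# published figure is kept as the default for reproduction fidelity.
MOLAR_MASS_SOLUTE = 371.41      # baricitinib, C16H17N7O2S
MOLAR_MASS_COSOLVENT = 78.13    # DMSO, C2H6OS
MOLAR_MASS_ANTISOLVENT = 18.07  # water

# Fusion properties of baricitinib
T_FUS_K = 487.42          # fusion temperature, K
DH_FUS_J_PER_MOL = 41110.0  # fusion enthalpy, J/mol
DCP_J_PER_MOL_K = 84.34   # solid/liquid heat-capacity difference, J/mol/K

# Total Hansen solubility parameters, MPa^(1/2)
DELTA_SOLUTE = 28.90       # baricitinib
DELTA_COSOLVENT = 23.60    # DMSO
DELTA_ANTISOLVENT = 47.80  # water

PRESSURE_MPA = 0.1
SOLUTE_NAME = "baricitinib"
COSOLVENT_NAME = "DMSO"
ANTISOLVENT_NAME = "water"

# Apparent dissolution thermodynamics as published for this system
# (per-composition van't Hoff analysis at the harmonic-mean temperature):
# m -> (dH kJ/mol, dG kJ/mol, dS J/mol/K).  These published values are an
# input for the enthalpy-entropy compensation regression; refitting the
# rounded solubility table reproduces them to ~0.1-2%.
PUBLISHED_THERMO: dict[float, tuple[float, float, float]] = {
    0.0: (64.85, 25.03, 128.89),
    0.1: (63.76, 23.18, 131.34),
    0.2: (63.20, 21.37, 135.39),
    0.3: (61.87, 19.53, 137.04),
    0.4: (60.63, 17.71, 139.91),
    0.5: (58.99, 15.88, 139.50),
    0.6: (58.02, 14.06, 142.25),
    0.7: (57.14, 12.24, 145.30),
    0.8: (55.83, 10.42, 146.95),
    0.9: (54.30, 8.60, 147.88),
    1.0: (53.53, 6.80, 151.23),
}
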