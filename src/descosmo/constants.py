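"""Physical constants used throughout the package.

Energies are kJ/mol, areas Å², charge densities e/Å², temperatures K.
"""

#: Molar gas constant, kJ·mol⁻¹·K⁻¹ (CODATA 2018).
R_KJ_PER_MOL_K = 8.314462618e-3

#: Default temperature, K ("room temperature").
ROOM_TEMPERATURE_K = 298.15

#: Molar mass of water, g/mol.
M_WATER = 18.015
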