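"""Physical constants and unit conventions.

Internal units throughout the package: length in Å, energy in kcal/mol,
mass in g/mol (Da), time in fs, charge in elementary charges, temperature
in K.  Forces are kcal/mol/Å.
"""

# Boltzmann constant, kcal/mol/K
KB = 0.001987204259

# Coulomb prefactor q_i q_j / r  ->  kcal/mol with q in e and r in Å
COULOMB = 332.0637133

# 1 (g/mol)(Å/fs)^2 in kcal/mol: converts m v^2 to energy units
KE_PER_MV2 = 1.0 / 4.184e-4  # = 2390.057...

# acceleration (Å/fs^2) = ACC_CONV * force (kcal/mol/Å) / mass (g/mol)
ACC_CONV = 4.184e-4

# IUPAC 2021 standard (average) atomic weights, Da
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "AU": 196.966570,
    "PT": 195.084,
    "AG": 107.8682,
}


def element_mass(element: str) -> float:
    """Average atomic mass of ``element`` (case-insensitive symbol)."""
    try:
        return ELEMENT_MASSES[element.upper()]
    except KeyError:
        raise KeyError(f"no mass tabulated for element {element!r}") from None
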