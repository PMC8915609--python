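"""Physical constants and unit conventions used throughout the toolkit.

Units are fixed repo-wide: energies in kJ/mol, lengths in nm, charges in
elementary charges, temperatures in K, pressures in bar, densities in kg/m^3.
"""

#: Molar gas constant, kJ/(mol K).
R_GAS = 8.314462618e-3

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Coulomb prefactor e^2/(4 pi eps0) in kJ nm / mol, i.e. the energy of two
#: unit charges at 1 nm separation.
COULOMB_K = 138.935458

#: bar * nm^3 expressed in kJ/mol (for p*V work terms).
BAR_NM3_TO_KJ_PER_MOL = 1.0e5 * 1.0e-27 * N_AVOGADRO / 1000.0


def beta(temperature: float) -> float:
    """Inverse temperature 1/(R T) in mol/kJ."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (R_GAS * temperature)
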