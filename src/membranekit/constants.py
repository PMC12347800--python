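"""Physical constants and package-wide unit conventions.

Units are fixed across the package: lengths in nm, energies in kJ/mol,
masses in amu, temperatures in K, times in ps.  All file I/O converts at
the boundary.
"""

#: Molar gas constant in kJ/(mol K).
R_KJ_PER_MOL_K: float = 8.314462618e-3

#: Avogadro constant, 1/mol.
AVOGADRO: float = 6.02214076e23

#: Molar concentration of pure liquid water, mol/L.  Used to express a
#: solute load as an aqueous-phase molarity via the mole ratio
#: n_solute / n_water * WATER_MOLARITY.
WATER_MOLARITY: float = 55.35

#: Number density of liquid water near the simulated temperatures
#: (~330-345 K), molecules per nm^3.  Sets the aqueous-slab volume of the
#: synthetic builder.
WATER_NUMBER_DENSITY: float = 33.0


def rt(temperature: float) -> float:
    """Thermal energy R*T in kJ/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ_PER_MOL_K * temperature
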