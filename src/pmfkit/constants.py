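"""Physical constants and unit helpers.

Energies are kcal/mol throughout; lengths are Angstrom.
"""

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041

#: Default simulation temperature (K).
DEFAULT_TEMPERATURE = 298.15


def kt(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature


def kcal_to_kt(energy: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convert an energy in kcal/mol to units of k_B*T."""
    return energy / kt(temperature)
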