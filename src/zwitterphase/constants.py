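"""Physical constants and unit conventions.

Distances are carried in nm and energies in kJ/mol at rest; conversion to
thermal units (kBT) happens only at computation boundaries. Harmonic force
constants are kJ mol^-1 nm^-2 (0.6 J mol^-1 pm^-2 = 600 kJ mol^-1 nm^-2).
"""

#: Molar gas constant, kJ mol^-1 K^-1.
R_KJ_PER_MOL_K = 0.008314462618

#: Production temperature for all ground-truth generation, K.
DEFAULT_TEMPERATURE_K = 300.0


def kbt_kj_per_mol(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Thermal energy R*T in kJ/mol (2.494 kJ/mol at 300 K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KJ_PER_MOL_K * temperature
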