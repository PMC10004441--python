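"""Physical constants and unit conversions used throughout the package.

Internal unit system: length nm, time ps, energy kcal/mol, charge e,
mass amu, concentration M.  Rate constants computed in ps⁻¹ (or ps⁻¹M⁻¹)
and converted to SI time units only at reporting boundaries.
"""

from __future__ import annotations

#: Coulomb constant e²/(4πε₀) in kcal·nm·mol⁻¹·e⁻².
COULOMB_KCAL_NM: float = 33.2063

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹.
KB_KCAL: float = 0.0019872041

#: Avogadro constant, mol⁻¹.
AVOGADRO: float = 6.02214076e23

#: Picosecond in seconds.
PS_TO_S: float = 1e-12

#: Cubic nanometre in litres.
NM3_TO_L: float = 1e-24

#: kcal → kJ.  Note 1 kJ/mol ≡ 1 amu·nm²·ps⁻², which makes speed
#: conversions exact in the internal unit system.
KCAL_TO_KJ: float = 4.184


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(kB·T) in mol/kcal.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin; must be positive.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB_KCAL * temperature)


def thermal_energy_amu_nm2_ps2(temperature: float) -> float:
    """kB·T expressed in amu·nm²·ps⁻² (numerically equal to kJ/mol)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL * temperature * KCAL_TO_KJ
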