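"""Unit system and physical constants.

Internal units everywhere: energies in kcal/mol, lengths in Å, times in ps,
masses in amu (g/mol).  Temperatures in K.  Conversions to the kJ/nm
conventions common in MD input files happen only at I/O boundaries.
"""

from __future__ import annotations

#: Boltzmann constant, kcal mol^-1 K^-1
KB_KCAL = 0.0019872041

#: kcal/mol per kJ/mol
KCAL_PER_KJ = 1.0 / 4.184

#: energy carried by 1 amu * (Å/ps)^2, in kcal/mol.
#: 1 amu Å²/ps² = 1e4 (g/mol)(m/s)² = 10 J/mol.
KCAL_PER_AMU_A2_PS2 = 0.01 * KCAL_PER_KJ

#: seconds per nanosecond reciprocal: k[s^-1] = NS_TO_S_INV / tau[ns]
NS_PER_S = 1.0e9


def kbt(temperature: float) -> float:
    """Thermal energy k_B T in kcal/mol at the given temperature in K.

    At 300 K this is 0.5962 kcal/mol (2.494 kJ/mol, i.e. the 2.50 kJ/mol
    commonly quoted for room temperature).
    """
    return KB_KCAL * temperature


def kj_per_nm2_to_kcal_per_A2(k: float) -> float:
    """Force constants: kJ mol^-1 nm^-2 -> kcal mol^-1 Å^-2."""
    return k * KCAL_PER_KJ / 100.0


def kcal_to_kj(e: float) -> float:
    return e / KCAL_PER_KJ


def kj_to_kcal(e: float) -> float:
    return e * KCAL_PER_KJ
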