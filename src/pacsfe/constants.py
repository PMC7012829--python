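"""Physical constants (CODATA 2018, via scipy) and unit conversions.

Internal conventions: lengths in Å, times in ps, pressures in MPa.
Energies are either in reduced units (multiples of kT) or kcal/mol and are
always tagged; see :mod:`pacsfe.units`.
"""
from scipy import constants as _codata

#: Boltzmann constant, J/K
KB_J_PER_K: float = _codata.k
#: Planck constant, J s
H_J_S: float = _codata.h
#: Avogadro constant, 1/mol
AVOGADRO: float = _codata.N_A
#: Molar gas constant, J/(mol K)
R_J_PER_MOL_K: float = _codata.R
#: Boltzmann constant, kcal/(mol K)  (= R expressed per kcal)
KB_KCAL_PER_MOL_K: float = _codata.R / (_codata.calorie * 1000.0)

#: Volume per molecule at 1 M concentration, Å^3 (the standard-state volume)
STANDARD_STATE_VOLUME_A3: float = 1e27 / AVOGADRO

#: Reference (ambient) pressure in MPa used by the pressure-dependent toy model.
REFERENCE_PRESSURE_MPA: float = 0.1


def kt_kcal_per_mol(temperature: float) -> float:
    """Thermal energy kT in kcal/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_KCAL_PER_MOL_K * temperature
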