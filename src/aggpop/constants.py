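"""Physical constants in the package's internal unit system.

Internal units are fixed package-wide: Å for length, amu for mass,
cm⁻¹ for frequency, kcal mol⁻¹ for energy, mol L⁻¹ for concentration
and K for temperature.  Converters live at the I/O boundaries only.
"""

from scipy import constants as _c

#: Gas constant, kcal mol⁻¹ K⁻¹.
R_KCAL = _c.R / _c.calorie / 1000.0

#: Gas constant, L bar mol⁻¹ K⁻¹ (for the ideal-gas molar volume RT/p°).
R_LBAR = _c.R / 100.0  # J/(mol K) -> L bar/(mol K)

#: hc·N_A per wavenumber, kcal mol⁻¹ cm.  Multiplying by ν̃ in cm⁻¹
#: gives the photon energy per mole.
HC_KCAL_CM = _c.h * _c.c * 100.0 * _c.N_A / _c.calorie / 1000.0

#: Avogadro constant, mol⁻¹.
N_AVOGADRO = _c.N_A

#: Boltzmann constant, J K⁻¹ (SI; used only inside partition functions).
K_B = _c.k

#: Planck constant, J s.
H_PLANCK = _c.h

#: Speed of light, cm s⁻¹.
C_CM = _c.c * 100.0

#: Standard atmosphere in bar.
ATM_BAR = _c.atm / 1e5

#: hartree -> kcal mol⁻¹ converter for the I/O boundary.
HARTREE_KCAL = 627.5094740631

#: 1 amu in kg.
AMU_KG = _c.atomic_mass

#: Å³ -> L.
A3_TO_L = 1e-27

#: Integrated band intensity conversion: km mol⁻¹ -> L mol⁻¹ cm⁻².
#: Decadic molar absorptivity with unit-area lineshapes:
#: 10⁵ cm/km divided by (ln 10 · 10³ cm³/L).
KM_MOL_TO_LMOLCM2 = 1e5 / (2.302585092994046 * 1e3)
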