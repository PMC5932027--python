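"""Physical constants and unit conversions.

All magnetometry internals use CGS-Gaussian units (emu, gauss, erg): the
Langevin argument x = mu_p * H / (k_B * T) is dimensionless when the particle
moment is in erg/G, the field in gauss and k_B in erg/K.  EPR internals use
millitesla and GHz.  SI values are provided for boundary conversions.
"""

from __future__ import annotations

# --- CODATA-level constants, CGS-Gaussian view ---
MU_B_CGS = 9.2740100783e-21  # Bohr magneton, erg/G
K_B_CGS = 1.380649e-16       # Boltzmann constant, erg/K
H_PLANCK_CGS = 6.62607015e-27  # Planck constant, erg*s

# --- SI view ---
MU_B_SI = 9.2740100783e-24   # J/T
K_B_SI = 1.380649e-23        # J/K
H_PLANCK_SI = 6.62607015e-34  # J*s

# Electron Zeeman conversion: mu_B / h in GHz per mT (per unit g-factor).
# A g = 2 electron resonates at ~28 GHz/T.
GHZ_PER_MT = MU_B_SI / H_PLANCK_SI * 1e-3 * 1e-9  # = 0.01399624...

# k_B / h in GHz per kelvin, used for Boltzmann factors of GHz-scale levels.
KELVIN_TO_GHZ = K_B_SI / H_PLANCK_SI * 1e-9  # = 20.8366...

# --- Chemistry / tissue ---
FE_MOLAR_MASS = 55.845       # g/mol
TISSUE_DENSITY = 1.0         # g/mL, assumed for wet tissue

# --- Ferritin ---
FE3_ION_MOMENT = 5.92        # Bohr magnetons, ionic moment of high-spin Fe(III)
FERRITIN_CAPACITY = 4500     # maximum Fe atoms per ferritin core

# --- Saturation magnetizations (emu per gram of mineral) ---
MS_MAGNETITE = 84.0          # magnetite/maghemite, blocked particles >~25 nm
MS_FERRIHYDRITE = 0.62       # ferrihydrite (ferritin core mineral)

# --- Field units ---
GAUSS_PER_MT = 10.0
GAUSS_PER_T = 1.0e4


def mass_to_molar(conc_ug_per_g: float, molar_mass: float = FE_MOLAR_MASS,
                  density: float = TISSUE_DENSITY) -> float:
    """Convert a tissue concentration in ug/g (wet weight) to micromolar.

    Assumes the tissue density given in g/mL, so 1 g of tissue occupies
    1/density mL.  ug/g * density -> ug/mL = mg/L; dividing by the molar
    mass (g/mol) gives mmol/L * 1e-3, i.e. uM after the 1e3 factor.

    >>> round(mass_to_molar(14.95), 1)
    267.7
    """
    if conc_ug_per_g < 0:
        raise ValueError("concentration must be non-negative")
    return conc_ug_per_g * density / molar_mass * 1e3


def molar_to_mass(conc_um: float, molar_mass: float = FE_MOLAR_MASS,
                  density: float = TISSUE_DENSITY) -> float:
    """Inverse of :func:`mass_to_molar` (uM -> ug/g wet weight)."""
    if conc_um < 0:
        raise ValueError("concentration must be non-negative")
    return conc_um * molar_mass / density * 1e-3
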