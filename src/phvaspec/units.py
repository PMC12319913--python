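"""Physical constants and unit conversions.

All internal tensor math is done in Hartree atomic units with masses in
dalton; geometries are exchanged in angstrom and vibrational wavenumbers
reported in cm^-1.  Constants come from :mod:`scipy.constants` (current
CODATA adjustment).
"""

from __future__ import annotations

import math

import scipy.constants as _const

# --- base constants (SI) ---
BOHR_M: float = _const.value("Bohr radius")  # m
HARTREE_J: float = _const.value("Hartree energy")  # J
DALTON_KG: float = _const.value("atomic mass constant")  # kg
E_CHARGE_C: float = _const.e  # C
C_LIGHT_M_S: float = _const.c  # m/s
H_PLANCK_J_S: float = _const.h  # J s
K_BOLTZMANN_J_K: float = _const.k  # J/K
N_AVOGADRO: float = _const.N_A  # 1/mol
EPSILON0: float = _const.epsilon_0  # F/m

ANGSTROM_PER_BOHR: float = BOHR_M * 1e10
BOHR_PER_ANGSTROM: float = 1.0 / ANGSTROM_PER_BOHR

#: one debye in C m
DEBYE_C_M: float = 1e-21 / C_LIGHT_M_S

#: sqrt of a mass-weighted Hessian eigenvalue (Hartree Bohr^-2 Da^-1)
#: times this factor gives a wavenumber in cm^-1 (~5140.49)
WAVENUMBER_PER_SQRT_EIGVAL: float = (
    math.sqrt(HARTREE_J / (BOHR_M**2 * DALTON_KG)) / (2.0 * math.pi * C_LIGHT_M_S) / 100.0
)

#: dipole gradient along a normal coordinate, a.u. (e / sqrt(Da)) -> SI (C / sqrt(kg))
DMU_DQ_AU_TO_SI: float = E_CHARGE_C / math.sqrt(DALTON_KG)

#: polarizability gradient along a normal coordinate,
#: a.u. (e^2 a0^2 E_h^-1 / (a0 sqrt(Da))) -> SI (C^2 m J^-1 kg^-1/2)
DALPHA_DQ_AU_TO_SI: float = E_CHARGE_C**2 * BOHR_M / (HARTREE_J * math.sqrt(DALTON_KG))

#: |dmu/dQ|^2 of 1 (D / (A sqrt(amu)))^2 -> integrated molar absorption, km/mol (~42.256)
KM_PER_MOL_PER_DEBYE_UNIT: float = (
    N_AVOGADRO
    / (12.0 * EPSILON0 * C_LIGHT_M_S**2)
    * (DEBYE_C_M / (1e-10 * math.sqrt(DALTON_KG))) ** 2
    / 1000.0
)


def angstrom_to_bohr(x):
    return x * BOHR_PER_ANGSTROM


def bohr_to_angstrom(x):
    return x * ANGSTROM_PER_BOHR


def eigenvalue_to_wavenumber(lam):
    """Signed wavenumber (cm^-1) from a mass-weighted Hessian eigenvalue.

    Negative eigenvalues (imaginary frequencies) map to negative
    wavenumbers of the corresponding magnitude.
    """
    import numpy as np

    lam = np.asarray(lam, dtype=float)
    return np.sign(lam) * np.sqrt(np.abs(lam)) * WAVENUMBER_PER_SQRT_EIGVAL


def wavenumber_to_eigenvalue(nu):
    """Inverse of :func:`eigenvalue_to_wavenumber`."""
    import numpy as np

    nu = np.asarray(nu, dtype=float)
    return np.sign(nu) * (nu / WAVENUMBER_PER_SQRT_EIGVAL) ** 2
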