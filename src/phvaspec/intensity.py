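"""Harmonic IR and Raman intensities from normal-mode property gradients.

Double-harmonic expressions: the partial dipole gradient and partial
polarizability gradient are mass-weighted, contracted with the PHVA
eigenvectors to per-mode derivatives dmu/dQ and dalpha/dQ, and turned
into

* integrated molar absorption coefficients A_I (reported in km/mol;
  the spectral profile of the molar decadic attenuation coefficient
  epsilon is assembled in :mod:`phvaspec.spectrum`), and
* absolute differential Raman scattering cross sections sigma'_I for
  Stokes scattering at a given incident wavelength and temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import units
from .phva import NormalModeSet

#: default incident wavelength (nm) and temperature (K)
DEFAULT_WAVELENGTH_NM = 514.5
DEFAULT_TEMPERATURE_K = 300.0


@dataclass
class ModeGradients:
    """Per-mode dipole and polarizability derivatives (atomic units).

    ``dmu_dq`` has shape (n_modes, 3) in e/sqrt(Da); ``dalpha_dq`` has
    shape (n_modes, 3, 3), symmetric in the last two axes, in a.u. of
    polarizability per (Bohr sqrt(Da)).
    """

    labels: np.ndarray
    dmu_dq: np.ndarray
    dalpha_dq: np.ndarray


@dataclass
class RamanInvariants:
    """Rotational invariants of the polarizability derivatives.

    a' is the isotropic mean derivative, gamma'2 the anisotropy, and
    S = 45 a'^2 + 7 gamma'2 the standard Raman activity combination.
    """

    a_iso: np.ndarray
    gamma2: np.ndarray

    @property
    def activity(self) -> np.ndarray:
        return 45.0 * self.a_iso**2 + 7.0 * self.gamma2


def transform_gradients(D_mu: np.ndarray,
                        D_alpha: np.ndarray,
                        modes: NormalModeSet,
                        masses: np.ndarray,
                        kept_labels: np.ndarray | None = None) -> ModeGradients:
    """Mass-weight property gradients and contract with mode eigenvectors.

    Component (a, i) of each gradient is divided by sqrt(m_a), then
    contracted with the mass-weighted eigenvector of each kept mode:
    dmu/dQ_I = sum_{a,i} v_I(a,i) D_mu(a,i,:) / sqrt(m_a).
    """
    masses = np.asarray(masses, dtype=float)
    if kept_labels is None:
        kept_labels = modes.labels
    kept_labels = np.asarray(kept_labels, dtype=int)
    if np.any(kept_labels < 1) or np.any(kept_labels > modes.n_modes):
        raise ValueError("kept label outside the mode set")
    w = 1.0 / np.sqrt(np.repeat(masses, 3))
    V = modes.eigenvectors[:, kept_labels - 1]
    dmu = V.T @ (D_mu * w[:, None])
    dalpha = np.einsum("ci,cjk->ijk", V, D_alpha * w[:, None, None])
    return ModeGradients(labels=kept_labels, dmu_dq=dmu, dalpha_dq=dalpha)


def ir_intensity(gradients: ModeGradients) -> np.ndarray:
    """Integrated molar absorption A_I in km/mol.

    A_I = N_A / (12 eps0 c^2) |dmu/dQ_I|^2 with the derivative converted
    from e/sqrt(Da) to SI.
    """
    d2 = (np.linalg.norm(gradients.dmu_dq, axis=1) * units.DMU_DQ_AU_TO_SI) ** 2
    A_si = units.N_AVOGADRO / (12.0 * units.EPSILON0 * units.C_LIGHT_M_S**2) * d2
    return A_si / 1000.0  # m/mol -> km/mol


def raman_invariants(gradients: ModeGradients) -> RamanInvariants:
    """Isotropic/anisotropic invariants of dalpha/dQ (atomic units)."""
    a = gradients.dalpha_dq
    if not np.allclose(a, np.swapaxes(a, 1, 2), rtol=0, atol=1e-10 * max(np.abs(a).max(), 1.0)):
        raise ValueError("polarizability derivative tensors must be symmetric")
    a_iso = np.trace(a, axis1=1, axis2=2) / 3.0
    d = a.diagonal(axis1=1, axis2=2)
    gamma2 = 0.5 * ((d[:, 0] - d[:, 1]) ** 2 + (d[:, 1] - d[:, 2]) ** 2
                    + (d[:, 2] - d[:, 0]) ** 2) \
        + 3.0 * (a[:, 0, 1] ** 2 + a[:, 1, 2] ** 2 + a[:, 2, 0] ** 2)
    return RamanInvariants(a_iso=a_iso, gamma2=gamma2)


def raman_cross_section(invariants: RamanInvariants,
                        wavenumbers: np.ndarray,
                        wavelength_nm: float = DEFAULT_WAVELENGTH_NM,
                        temperature: float = DEFAULT_TEMPERATURE_K) -> np.ndarray:
    """Absolute differential Stokes Raman cross sections sigma'_I.

    sigma'_I = h / (8 pi^2 c nu_I) * (2 pi)^4 / 45 * (nu_in - nu_I)^4
               * S_I / (1 - exp(-h c nu_I / k_B T))

    with all quantities in SI inside the formula; the result is in
    C^4 s^2 m^-2 J^-1 kg^-1.  ``wavenumbers`` are the kept-mode band
    centers in cm^-1 and must be positive (pseudomodes with zero or
    imaginary frequencies must be filtered out first).
    """
    nu = np.asarray(wavenumbers, dtype=float)
    if np.any(nu <= 0):
        raise ValueError(
            "non-positive wavenumber among kept modes; discard "
            "pseudotranslational/pseudorotational modes before computing "
            "Raman cross sections")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    nu_si = nu * 100.0  # cm^-1 -> m^-1
    nu_in = 1.0 / (wavelength_nm * 1e-9)  # m^-1
    if np.any(nu_si >= nu_in):
        raise ValueError("incident wavenumber must exceed every band center")
    S_si = invariants.activity * units.DALPHA_DQ_AU_TO_SI**2
    h, c, kB = units.H_PLANCK_J_S, units.C_LIGHT_M_S, units.K_BOLTZMANN_J_K
    with np.errstate(over="ignore"):
        boltz = 1.0 - np.exp(-h * c * nu_si / (kB * temperature))
    pref = h / (8.0 * math.pi**2 * c * nu_si) * (2.0 * math.pi) ** 4 / 45.0
    return pref * (nu_in - nu_si) ** 4 * S_si / boltz


def incident_wavenumber_cm(wavelength_nm: float) -> float:
    """Incident wavenumber in cm^-1 for a laser wavelength in nm."""
    return 1e7 / wavelength_nm
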