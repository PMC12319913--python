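"""Spectral composition: Lorentzian broadening, averaging, differences.

Stick spectra (band center, intensity) from every retained snapshot are
convoluted with a Cauchy-Lorentz profile

    f(nu; nu_I, gamma_I) = (1/pi) * gamma_I / ((nu_I - nu)^2 + gamma_I^2)

of half-width at half-maximum gamma_I (default 3.0 cm^-1 for all modes)
and averaged over snapshots.  IR spectra are reported as the molar
decadic attenuation coefficient epsilon (integrated absorption divided
by ln 10), Raman spectra as cross-section density per cm^-1.  An
empirical scaling factor may be applied to the band centers to offset
the systematic overestimation of harmonic frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .ensemble import EnsembleTable

DEFAULT_HWHM_CM = 3.0
LN10 = math.log(10.0)

#: km/mol -> cm/mol combined with the 1000 cm^2/mol per L mol^-1 cm^-1,
#: so epsilon[L mol^-1 cm^-1] = A[km/mol] * 100 * f[cm] / ln10
_KM_MOL_TO_EPS = 100.0


@dataclass
class SpectrumGrid:
    """A spectrum on a uniform wavenumber axis.

    ``intensity`` is epsilon in L mol^-1 cm^-1 for IR, cross-section
    density (sigma' per cm^-1) for Raman.
    """

    wavenumbers: np.ndarray
    intensity: np.ndarray
    kind: str
    scale: float = 1.0
    n_snapshots: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if len(self.wavenumbers) != len(self.intensity):
            raise ValueError("axis/intensity length mismatch")

    def to_tsv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.wavenumbers, self.intensity]),
                   delimiter="\t", header=f"wavenumber_cm-1\t{self.kind}")


def lorentzian(grid: np.ndarray, center: float,
               gamma: float = DEFAULT_HWHM_CM) -> np.ndarray:
    """Unit-area Cauchy-Lorentz profile with HWHM ``gamma`` (cm^-1)."""
    if gamma <= 0:
        raise ValueError("HWHM must be positive")
    grid = np.asarray(grid, dtype=float)
    return gamma / (math.pi * ((center - grid) ** 2 + gamma**2))


def make_grid(start: float = 0.0, stop: float = 4000.0,
              spacing: float = 0.5) -> np.ndarray:
    """Uniform wavenumber axis in cm^-1 (default 0-4000 at 0.5)."""
    n = int(round((stop - start) / spacing)) + 1
    return start + spacing * np.arange(n)


def compose_spectrum(table: EnsembleTable,
                     kind: Literal["ir", "raman"],
                     outlier_mask: np.ndarray | None = None,
                     hwhm: float = DEFAULT_HWHM_CM,
                     grid: np.ndarray | None = None,
                     scale: float = 1.0) -> SpectrumGrid:
    """Ensemble-averaged broadened spectrum.

    S(nu) = (1/N_snap) sum_snapshots sum_modes I_sI f(nu; scale*nu_sI, gamma)

    The scaling factor multiplies band centers only, never intensities.
    For IR the stick weights A_I (km/mol) enter as A_I/ln10 so the
    result is the decadic epsilon profile.
    """
    if kind not in ("ir", "raman"):
        raise ValueError("kind must be 'ir' or 'raman'")
    if grid is None:
        grid = make_grid()
    sub = table if outlier_mask is None else table.subset(outlier_mask)
    if sub.n_snapshots == 0:
        raise ValueError("no snapshots left after outlier masking")
    if hwhm <= 0:
        raise ValueError("HWHM must be positive")
    centers = (scale * sub.frequency).ravel()
    weights = sub.property_array(kind).ravel()
    if kind == "ir":
        weights = weights * _KM_MOL_TO_EPS / LN10
    intensity = np.zeros_like(grid)
    chunk = max(1, 2_000_000 // max(len(grid), 1))
    for lo in range(0, len(centers), chunk):
        diff = centers[lo:lo + chunk, None] - grid[None, :]
        prof = hwhm / (math.pi * (diff**2 + hwhm**2))
        intensity += weights[lo:lo + chunk] @ prof
    intensity /= sub.n_snapshots
    return SpectrumGrid(wavenumbers=grid, intensity=intensity, kind=kind,
                        scale=scale, n_snapshots=sub.n_snapshots)


def difference_spectrum(a: SpectrumGrid, b: SpectrumGrid) -> SpectrumGrid:
    """Pointwise a - b on identical axes (e.g. solvent-model contrasts)."""
    if a.wavenumbers.shape != b.wavenumbers.shape or \
            not np.allclose(a.wavenumbers, b.wavenumbers, rtol=0, atol=1e-9):
        raise ValueError("spectra are on different wavenumber axes")
    return SpectrumGrid(wavenumbers=a.wavenumbers.copy(),
                        intensity=a.intensity - b.intensity,
                        kind=f"diff({a.kind})", scale=a.scale,
                        n_snapshots=a.n_snapshots,
                        meta={"minuend": a.meta, "subtrahend": b.meta})


def normalize_to_peak(spec: SpectrumGrid, target_peak: float) -> SpectrumGrid:
    """Rescale so the highest intensity equals ``target_peak``.

    Used only for visual comparison against experimental spectra of
    unknown absolute scale; off by default everywhere else.
    """
    peak = spec.intensity.max()
    if peak <= 0:
        raise ValueError("spectrum has no positive intensity")
    return SpectrumGrid(wavenumbers=spec.wavenumbers.copy(),
                        intensity=spec.intensity * (target_peak / peak),
                        kind=spec.kind, scale=spec.scale,
                        n_snapshots=spec.n_snapshots,
                        meta={**spec.meta, "normalized_to": target_peak})
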