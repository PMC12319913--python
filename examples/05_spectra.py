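"""Ensemble-averaged IR/Raman spectra and a difference spectrum.

Composes Lorentzian-broadened (HWHM 3 cm^-1) ensemble spectra for two
coupling strengths of the synthetic cluster, applies the empirical 0.96
frequency scaling, and prints the largest peaks plus the extrema of the
difference spectrum ("stronger-coupling minus weaker-coupling").
"""

import numpy as np

from phvaspec import (acetone_like_spec, compose_spectrum,
                      difference_spectrum, make_ensemble, make_grid,
                      with_coupling, zscore_outliers)
from phvaspec.pipeline import analyze_ensemble

grid = make_grid(0, 4000, 0.5)
spectra = {}
for k_c in (0.005, 0.02):
    spec = with_coupling(acetone_like_spec(n_env=20), k_c)
    records = make_ensemble(spec, n_snapshots=25, seed=11)
    result = analyze_ensemble(records, metric="mass_weighted")
    mask = zscore_outliers(result.table).discard_mask
    spectra[k_c] = compose_spectrum(result.table, "ir", outlier_mask=mask,
                                    hwhm=3.0, grid=grid, scale=0.96)

for k_c, s in spectra.items():
    peak = grid[np.argmax(s.intensity)]
    print(f"k_c={k_c}: strongest IR band at {peak:.1f} cm^-1, "
          f"epsilon_max = {s.intensity.max():.1f} L mol^-1 cm^-1 "
          f"({s.n_snapshots} snapshots averaged)")

diff = difference_spectrum(spectra[0.02], spectra[0.005])
imax, imin = np.argmax(diff.intensity), np.argmin(diff.intensity)
print(f"\ndifference spectrum extremes: +{diff.intensity[imax]:.2f} at "
      f"{grid[imax]:.1f} cm^-1, {diff.intensity[imin]:.2f} at "
      f"{grid[imin]:.1f} cm^-1")
print("Positive/negative lobe pairs mark bands that shift when the "
      "core-environment coupling changes — the same construction used "
      "to contrast solvent models.")
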