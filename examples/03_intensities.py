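"""Harmonic IR and Raman intensities of one snapshot.

Analyzes a single synthetic snapshot and prints, per kept mode, the
wavenumber, the integrated molar absorption (km/mol), the Raman
activity invariants, and the absolute differential Raman cross section
at 514.5 nm / 300 K.
"""

import numpy as np

from phvaspec import (acetone_like_spec, ir_intensity, make_cluster,
                      raman_cross_section, raman_invariants,
                      transform_gradients)
from phvaspec.pipeline import analyze_snapshot

record, _ = make_cluster(acetone_like_spec(n_env=20, k_c=0.01), seed=3)
analysis = analyze_snapshot(record, metric="mass_weighted")

# keep the modes with little rigid-body character and positive frequency
kept = analysis.modes.labels[analysis.profile.total < 0.1]
grads = transform_gradients(record.D_mu, record.D_alpha, analysis.modes,
                            record.core_masses, kept_labels=kept)
nu = analysis.modes.wavenumbers[kept - 1]
A = ir_intensity(grads)
inv = raman_invariants(grads)
sigma = raman_cross_section(inv, nu, wavelength_nm=514.5, temperature=300.0)

print(f"{'label':>5} {'nu/cm-1':>9} {'A_IR/km mol-1':>14} "
      f"{'S/a.u.':>10} {'sigma/C4 s2 m-2 J-1 kg-1':>26}")
for i, lab in enumerate(kept):
    print(f"{lab:>5} {nu[i]:>9.1f} {A[i]:>14.3f} "
          f"{inv.activity[i]:>10.4f} {sigma[i]:>26.3e}")

print("\nA_IR integrates the band's decadic absorption; sigma is the "
      "per-molecule Stokes scattering cross section per solid angle "
      "(strongly weighted toward low wavenumbers by the Boltzmann and "
      "1/nu factors).")
print(f"strongest IR band: {nu[np.argmax(A)]:.1f} cm^-1; "
      f"strongest Raman band: {nu[np.argmax(sigma)]:.1f} cm^-1")
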