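# Methods

## Model and assumptions

`phvaspec` post-processes harmonic vibrational data for a solute ("core")
embedded in a fixed environment. The central approximation is the
partial-Hessian truncation: only the 3N_core × 3N_core core block of the
cluster Hessian is mass-weighted and diagonalized; core–environment and
environment–environment blocks are discarded. Consequences the package is
built around:

- The analysis yields 3N_core modes, not 3N_core − 6. Up to 3 + n_rot of
  them (n_rot = 3, or 2 for a linear core) describe the core translating or
  rotating against the frozen surroundings. These pseudomodes are artifacts
  of the truncation — their restoring force comes entirely from the
  discarded coupling blocks — and are removed before intensities and spectra
  are assembled.
- Within the double-harmonic approximation, band positions come from the
  eigenvalues (ν̃_I = sign(λ_I)(2πc)⁻¹√|λ_I|; negative wavenumbers encode
  imaginary frequencies) and band intensities from first derivatives of the
  dipole moment (IR) and polarizability (Raman) along the normal
  coordinates. No anharmonicity, no resonance effects.
- Ensemble spectra are means over snapshot spectra, not sums, so the molar
  attenuation coefficient keeps its per-mole meaning and spectra from
  different snapshot counts are comparable.

## Pseudomode identification

For each mode I the translational and rotational contributions are
T_I = Σₖ |v_I·t_k|² and R_I = Σₖ |v_I·r_k|², where {t_k, r_k} are the rigid
translation vectors and rotation vectors about the core's center of mass,
orthonormalized by modified Gram–Schmidt (translations first; rotation
vectors with pre-normalization norm below 1e-8 are dropped, reducing n_rot
for linear cores).

Two metrics are offered:

- `cartesian` (default): overlaps between unit-normalized Cartesian
  displacement images of the eigenvectors and Cartesian rigid-body vectors.
  Both factors are normalized, so each contribution is bounded by 1
  (Bessel), but because the Cartesian images of mass-weighted eigenvectors
  are not mutually orthogonal for unequal masses, the totals summed over
  modes exceed 3 + n_rot and true vibrations of hydrogen-rich cores can
  show overlaps of a few tenths.
- `mass_weighted`: overlaps taken directly with the orthonormal eigenvectors
  against √m-scaled rigid-body vectors. Here Parseval holds exactly: totals
  sum to 3 + n_rot, and in the decoupled limit every true vibration has
  total 0 to machine precision. The two metrics coincide for equal masses
  (tested). Exactness identities in the test suite and acceptance script use
  this metric.

Filtering is an ensemble decision: the per-label mean of T+R over all
snapshots is compared with a threshold τ (default 0.1), because a mode's
pseudo character varies strongly with configuration and single-snapshot
filtering is unstable. A `fixed_count` rule (discard the n lowest-frequency
labels) is available when the pseudomode count is known. Modes are aligned
across snapshots by descending-frequency rank — adequate when kept modes are
spectrally separated, unreliable across curve crossings (a known limitation
shared with any label-by-rank scheme).

## Intensities and units

Internally all tensors are in Hartree atomic units with masses in Da;
geometries in Å; wavenumbers in cm⁻¹. Constants come from
`scipy.constants` (current CODATA adjustment).

- IR: A_I = N_A/(12 ε₀ c²)·|dμ/dQ_I|², reported in km/mol. The conversion is
  pinned by the classic factor 1 (D Å⁻¹ amu⁻¹ᐟ²)² → 42.256 km/mol, which the
  test suite recomputes from constants through an independent path. Spectral
  profiles divide by ln 10 to give the molar **decadic** attenuation
  coefficient ε in L mol⁻¹ cm⁻¹.
- Raman: invariants a′ = tr(dα/dQ)/3 and the anisotropy γ′²; activity
  S = 45a′² + 7γ′². The absolute differential Stokes cross section is
  σ′_I = h/(8π²cν̃_I) · (2π)⁴/45 · (ν̃_in−ν̃_I)⁴ · S_I · [1−exp(−hcν̃_I/k_BT)]⁻¹
  (SI inside; output in C⁴ s² m⁻² J⁻¹ kg⁻¹), defaults 514.5 nm and 300 K.
  Whether a particular convention includes the Boltzmann factor and the
  45-fold normalization varies in the literature; this choice is isolated in
  `raman_cross_section` and any constant-prefactor difference rescales all
  intensities uniformly, cancelling in normalized or difference spectra.
  σ′ requires strictly positive band centers — a deliberate guard that
  forces pseudomode filtering before Raman evaluation.

## Ensemble statistics

- Outliers: absolute Z-score Z = |x−μ|/σ per snapshot, mode and property
  (frequency, IR, Raman), with sample (n−1) standard deviation; a snapshot
  is discarded if any Z exceeds the threshold (default 5); σ = 0 columns
  never flag. Note the hard bound Z ≤ (n−1)/√n for a single outlier: with
  fewer than ~27 snapshots a threshold of 5 cannot trigger, which is why the
  planted-outlier tests use 40 snapshots.
- Window errors: for window size n and step s, subwindows offset by s are
  drawn from the reference series (snapshots inside a window spaced s
  apart); per-mode window means are compared with reference means,
  |μ_ij − μ_ref,j|, mode-averaged per window, then summarized as mean ±
  std (max) over windows. Relative errors divide per-mode deviations by the
  reference mean before mode-averaging (percent). The window count for a
  T-snapshot reference at stride m = s/Δt is N = T//m − n; an offset of one
  base interval instead of one step is available (`offset="base"`). After
  outlier removal the retained series has gaps; windowing then proceeds on
  the stored sequence at the nominal (median) interval with a warning.
- Sampling law: for i.i.d. Gaussian data the expected per-mode window error
  is σ√(2/(πn)) (half-normal mean of a sample-mean deviation), slightly
  reduced by window/reference overlap, √(1 − n·m/T). The acceptance script
  verifies the empirical δ̄ against this closed form at n = 25 and 100 and
  the monotone decrease of δ̄ over n ∈ {25, 50, 125, 250, 500} on a
  2890-snapshot, 2 ps-step grid (which yields the window counts
  945/1195/1320/1395/1420).

## Spectra

Cauchy–Lorentz profile f(ν̄; ν̃_I, γ) = π⁻¹γ/((ν̃_I−ν̄)²+γ²), HWHM γ = 3.0 cm⁻¹
for all modes by default; default grid 0–4000 cm⁻¹ at 0.5 cm⁻¹ (≥6 points
per HWHM). An empirical scaling factor (e.g. 0.96) multiplies band centers
only, never intensities. Difference spectra are pointwise subtractions on
identical axes. Peak normalization against experimental spectra of unknown
absolute scale exists (`normalize_to_peak`) but is off by default.

## The synthetic generator

`phvaspec.synthetic` emulates the inputs a quantum-chemistry backend would
provide, with every quantity analytic:

- Geometry/Hessian: the solute is a connected network of central-force
  springs (each spring contributes k·ûûᵀ blocks with the ± sign pattern).
  Rigid translations *and* rotations are exact zero modes of this form at
  any geometry, so the decoupled core has an exact 3+n_rot-dimensional
  rigid kernel — ideal for oracle tests. The acetone-like preset (10 atoms:
  C₃O skeleton + 6 H) uses bond springs, geminal (1-3) springs, 1-4 H···O
  springs and two cross-methyl H···H springs; the last two groups are needed
  because bond+geminal networks alone leave methyl-torsion and concerted
  counter-torsion mechanisms (floppy extra zero modes). Environment atoms
  (water-mass points on a reproducible random shell at 3.5–7 Å) couple to
  their nearest core atom with constant k_c ≥ 0; k_c = 0 recovers the
  isolated core exactly, and increasing k_c raises PHVA eigenvalues
  monotonically (Loewner order) and leaks rigid-body weight into the
  vibrational block monotonically.
- Dipole gradients: fixed point charges, ∂μ_j/∂x_{a,i} = q_a δ_ij.
- Polarizability gradients: bond-polarizability stretching term with
  longitudinal/transverse derivative parameters per core bond —
  rotation-covariant and symmetric by construction.
- Snapshots: seeded Gaussian displacements of all atoms (σ = 0.05 Bohr
  default) emulate configurational diversity; timestamps at a base interval
  (1 ps default); optional Hessian scaling of chosen snapshots plants
  detectable outliers. Seeds are explicit arguments, never global state.

What this does *not* emulate: anharmonic sampling, solvent reorganization,
polarization response, realistic intensity magnitudes, or mode-crossing
statistics of a real solute. Passing tests therefore validate the
*mathematics* of the workflow (transformations, filtering identities,
statistics, unit chains), not the spectroscopy of any real system.

## Numerical choices

- Symmetry: Hessians/polarizability tensors with relative asymmetry below
  1e-8 are symmetrized with a warning, above it rejected; eigenanalysis
  rejects asymmetry above 1e-10 relative.
- Degenerate eigenvalues: any orthonormal basis of a degenerate block is
  acceptable; only basis-invariant quantities (frequencies, block intensity
  sums, subspace projections) are asserted in tests.
- Zero modes of exact-kernel Hessians carry O(ε‖H‖) eigenvalue noise, i.e.
  ~1e-4 cm⁻¹ wavenumber noise; comparisons on them use absolute tolerances.
- Gram–Schmidt drop tolerance 1e-8 for linear-core detection; ties in
  frequency sorting broken stably (stable argsort).
- Default problem sizes (20 environment atoms, 6–40 snapshots in tests,
  2890-snapshot Gaussian references for window statistics) were chosen as
  the smallest ensembles on which each statistical identity is
  well-resolved; all are regenerated programmatically at run time.
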