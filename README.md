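# phvaspec

Partial-Hessian vibrational analysis (PHVA) and ensemble IR/Raman spectra
for a solute embedded in a fixed molecular environment.

## The problem

Vibrational spectra of a solvated molecule computed from molecular-dynamics
snapshots require, per frame, only the block of the Hessian belonging to the
solute ("core") atoms — the core–environment and environment–environment
blocks are discarded. This truncation is cheap and accurate for genuine core
vibrations, but it manufactures artifacts: because the environment is frozen,
some normal modes describe the core translating or rotating against its
solvent cage. These *pseudotranslations/pseudorotations* carry unphysical
frequencies and intensities and must be identified and removed before the
ensemble spectrum is assembled. `phvaspec` implements the post-processing
chain around this idea for people who already have (or want to emulate)
per-snapshot Hessians and property gradients:

1. **Droplet partitioning** — assign solvent molecules to an inner
   (polarizable) shell, an outer (charge-only) shell, or removal, by distance
   from the core (defaults 16 / 30 Å).
2. **PHVA** — mass-weight and diagonalize the core Hessian block:
   ν̃_I = sign(λ_I)·(2πc)⁻¹·√|λ_I|, modes labeled 1..3N in descending
   frequency.
3. **Pseudomode filtering** — score each mode by the squared overlaps
   T_I = Σₖ|v_I·t_k|², R_I = Σₖ|v_I·r_k|² with orthonormalized rigid
   translation/rotation vectors of the core, average over all snapshots, and
   discard labels with mean T+R above a threshold (default 0.1) or a fixed
   count of lowest-frequency labels.
4. **Intensities** — transform partial dipole/polarizability gradients to
   normal-coordinate derivatives; A_I = N_A/(12ε₀c²)·|dμ/dQ_I|² (km/mol) for
   IR, and the absolute differential Stokes Raman cross section
   σ′_I ∝ ν̃_I⁻¹(ν̃_in−ν̃_I)⁴·(45a′²+7γ′²)·[1−exp(−hcν̃_I/k_BT)]⁻¹ at a given
   laser wavelength (default 514.5 nm) and temperature (default 300 K).
5. **Ensemble statistics** — reject snapshots whose frequency or intensity
   has absolute Z-score |x−μ|/σ above 5; estimate configurational convergence
   by comparing per-mode means of subwindows (n snapshots spaced s ps apart)
   against the full-reference means (average window error δ̄).
6. **Spectra** — Cauchy–Lorentz broadening f(ν̄;ν̃_I,γ) = π⁻¹γ/((ν̃_I−ν̄)²+γ²)
   with HWHM 3.0 cm⁻¹, snapshot averaging, optional empirical frequency
   scaling (e.g. 0.96), and difference spectra between solvent models.

A synthetic-cluster generator (`phvaspec.synthetic`) builds solutes as
connected central-force spring networks weakly coupled to a frozen
environment shell, with analytic Hessians, point-charge dipole gradients and
bond-polarizability Raman gradients — so the entire pipeline runs and is
validated without any quantum-chemistry software.

## Worked example

```python
from phvaspec import acetone_like_spec, make_ensemble, zscore_outliers
from phvaspec.pipeline import analyze_ensemble

spec = acetone_like_spec(n_env=20, k_c=0.01)       # 10-atom solute, 20 env atoms
records = make_ensemble(spec, n_snapshots=10, seed=7)
result = analyze_ensemble(records, metric="mass_weighted")
print(result.pseudo_report.tail(8).round(3).to_string(index=False))
print("kept:", [int(k) for k in result.kept_labels])
```

prints

```
 label  mean_wavenumber  mean_T  mean_R  mean_total  std_total  max_total
    23          508.113   0.002   0.028       0.030      0.002      0.033
    24          329.046   0.129   0.199       0.328      0.020      0.358
    25          257.602   0.092   0.875       0.966      0.008      0.978
    26          243.576   0.076   0.689       0.765      0.019      0.793
    27          188.339   0.828   0.049       0.877      0.010      0.893
    28          148.707   0.305   0.665       0.970      0.002      0.973
    29          123.908   0.720   0.275       0.995      0.000      0.995
    30           82.182   0.831   0.156       0.987      0.001      0.988
kept: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22, 23]
```

Labels 24–30 have large mean rigid-body overlap (0.33–0.99): they are the
pseudomodes created by the frozen environment and are excluded; the 23 kept
labels are genuine core vibrations whose IR/Raman intensities then populate
`result.table` for outlier rejection, window-error analysis and spectrum
composition. The `examples/` directory walks through every capability
(partitioning, pseudomode profiles, intensities, convergence, spectra); each
script prints its numbers with a line on what they mean. A thin CLI
(`phvaspec synth|partition|analyze|spectrum|converge`) wraps the same calls
for shell use.

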