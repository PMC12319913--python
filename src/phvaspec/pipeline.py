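"""End-to-end drivers: snapshot analysis and ensemble assembly.

The per-snapshot sequence is: mass-weight the partial Hessian,
diagonalize, build rigid-body reference vectors for the core, score
every mode's pseudotranslational/pseudorotational character.  At the
ensemble level the pseudo profiles of all snapshots decide — jointly —
which mode labels are kept; intensities are then evaluated for the kept
modes of every snapshot and collected into an
:class:`~phvaspec.ensemble.EnsembleTable`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import intensity as _intensity
from . import phva
from .ensemble import EnsembleTable, build_table
from .model_io import SnapshotRecord


@dataclass
class SnapshotAnalysis:
    """PHVA result of one snapshot."""

    record: SnapshotRecord
    modes: phva.NormalModeSet
    basis: phva.TransRotBasis
    profile: phva.PseudoProfile


@dataclass
class EnsembleResult:
    """Aligned ensemble table plus the filtering evidence."""

    table: EnsembleTable
    kept_labels: np.ndarray
    pseudo_report: pd.DataFrame
    analyses: list[SnapshotAnalysis]


def analyze_snapshot(record: SnapshotRecord,
                     metric: phva.Metric = "cartesian") -> SnapshotAnalysis:
    """Diagonalize one snapshot's partial Hessian and score pseudo modes."""
    modes = phva.eigenanalyze(phva.mass_weight(record.H_partial,
                                               record.core_masses))
    basis = phva.trans_rot_basis(record.core_coords, record.core_masses,
                                 metric=metric)
    profile = phva.pseudo_contributions(modes, basis)
    return SnapshotAnalysis(record=record, modes=modes, basis=basis,
                            profile=profile)


def analyze_ensemble(records: Sequence[SnapshotRecord],
                     rule: phva.ModeFilterRule | None = None,
                     metric: phva.Metric = "cartesian",
                     wavelength_nm: float = _intensity.DEFAULT_WAVELENGTH_NM,
                     temperature: float = _intensity.DEFAULT_TEMPERATURE_K
                     ) -> EnsembleResult:
    """Full ensemble workflow from snapshot records to an aligned table.

    Pseudomode filtering uses the whole snapshot set (their mean pseudo
    contribution per label); IR and Raman intensities are evaluated for
    the kept modes only, since pseudomodes carry unphysical frequencies
    and would poison the Raman Boltzmann/scattering factors.
    """
    analyses = [analyze_snapshot(r, metric=metric) for r in records]
    kept = phva.filter_modes([a.profile for a in analyses], rule)
    mean_nu = np.mean([a.modes.wavenumbers for a in analyses], axis=0)
    report = phva.pseudo_report([a.profile for a in analyses], mean_nu)
    results = []
    for a in analyses:
        grads = _intensity.transform_gradients(
            a.record.D_mu, a.record.D_alpha, a.modes, a.record.core_masses,
            kept_labels=kept)
        nu = a.modes.wavenumbers[kept - 1]
        ir = _intensity.ir_intensity(grads)
        inv = _intensity.raman_invariants(grads)
        raman = _intensity.raman_cross_section(
            inv, nu, wavelength_nm=wavelength_nm, temperature=temperature)
        results.append({"wavenumbers": nu, "ir": ir, "raman": raman,
                        "time_ps": a.record.time_ps,
                        "snapshot_id": a.record.snapshot_id})
    table = build_table(results, kept_labels=kept)
    return EnsembleResult(table=table, kept_labels=kept,
                          pseudo_report=report, analyses=analyses)
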