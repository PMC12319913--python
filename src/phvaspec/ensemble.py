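"""Ensemble statistics across MD snapshots.

Per-snapshot PHVA results are collected into an :class:`EnsembleTable`
(snapshots x modes arrays of frequency, IR intensity and Raman
intensity), cleaned with an absolute Z-score criterion, and probed for
configurational convergence with a subwindow error analysis: subwindows
of n snapshots spaced by a step s are carved out of the full reference
set, per-mode means inside each window are compared with the reference
means, and the absolute deviations are averaged over modes and windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PROPERTIES = ("frequency", "ir", "raman")


@dataclass
class EnsembleTable:
    """Snapshot x mode arrays of the three spectroscopic properties.

    Mode labels run 1..M in descending order of frequency (within each
    snapshot row, frequency is non-increasing with label).
    """

    labels: np.ndarray
    times_ps: np.ndarray
    frequency: np.ndarray
    ir: np.ndarray
    raman: np.ndarray
    snapshot_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        S, M = self.frequency.shape
        if self.ir.shape != (S, M) or self.raman.shape != (S, M):
            raise ValueError("property arrays must share shape")
        if len(self.labels) != M or len(self.times_ps) != S:
            raise ValueError("labels/times length mismatch")
        if self.snapshot_ids is None:
            self.snapshot_ids = np.arange(S)

    @property
    def n_snapshots(self) -> int:
        return self.frequency.shape[0]

    @property
    def n_modes(self) -> int:
        return self.frequency.shape[1]

    def property_array(self, name: str) -> np.ndarray:
        if name not in PROPERTIES:
            raise KeyError(name)
        return getattr(self, {"frequency": "frequency", "ir": "ir",
                              "raman": "raman"}[name])

    def subset(self, mask: np.ndarray) -> "EnsembleTable":
        """Rows where ``mask`` is False removed (True = drop)."""
        keep = ~np.asarray(mask, dtype=bool)
        return EnsembleTable(labels=self.labels,
                             times_ps=self.times_ps[keep],
                             frequency=self.frequency[keep],
                             ir=self.ir[keep], raman=self.raman[keep],
                             snapshot_ids=np.asarray(self.snapshot_ids)[keep])

    def to_frame(self) -> pd.DataFrame:
        """Long-form DataFrame (snapshot, time_ps, label, property columns)."""
        S, M = self.frequency.shape
        return pd.DataFrame({
            "snapshot": np.repeat(np.asarray(self.snapshot_ids), M),
            "time_ps": np.repeat(self.times_ps, M),
            "label": np.tile(self.labels, S),
            "frequency": self.frequency.ravel(),
            "ir": self.ir.ravel(),
            "raman": self.raman.ravel(),
        })


@dataclass
class OutlierReport:
    """Absolute Z-scores and the resulting discard mask.

    ``zscores`` maps property name -> (snapshots x modes) array of
    Z = |x - mu| / sigma; a snapshot is discarded when any property at
    any mode exceeds ``threshold``.
    """

    zscores: dict[str, np.ndarray]
    threshold: float
    discard_mask: np.ndarray
    counts_by_property: dict[str, int] = field(default_factory=dict)

    @property
    def n_discarded(self) -> int:
        return int(self.discard_mask.sum())


@dataclass
class WindowSpec:
    """Subwindow geometry: n snapshots spaced step_ps apart."""

    step_ps: float
    n: int
    offset: Literal["step", "base"] = "step"

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("window must contain at least one snapshot")
        if self.step_ps <= 0:
            raise ValueError("step must be positive")


@dataclass
class WindowErrorReport:
    """Window-error statistics per property.

    For each property: overall mean absolute error over windows
    (``delta``), its std and max over windows, and the relative
    counterparts in percent (per-mode deviations divided by the
    reference mean, then mode-averaged).
    """

    per_property: dict[str, dict[str, float]]
    n_windows: int
    spec: WindowSpec

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_property).T


def build_table(snapshot_results: Sequence[dict],
                kept_labels: np.ndarray | None = None) -> EnsembleTable:
    """Assemble per-snapshot results into an aligned ensemble table.

    Each element of ``snapshot_results`` is a mapping with keys
    ``wavenumbers``, ``ir``, ``raman`` (aligned per-mode arrays, already
    restricted to kept modes) and optionally ``time_ps``/``snapshot_id``.
    Modes are matched across snapshots by descending-frequency rank;
    snapshots with a deviant mode count are excluded with a logged
    reason.
    """
    if not snapshot_results:
        raise ValueError("no snapshot results")
    counts = [len(np.asarray(r["wavenumbers"])) for r in snapshot_results]
    M = max(set(counts), key=counts.count)
    rows_f, rows_i, rows_r, times, ids = [], [], [], [], []
    n_excluded = 0
    for s, r in enumerate(snapshot_results):
        nu = np.asarray(r["wavenumbers"], dtype=float)
        if len(nu) != M:
            n_excluded += 1
            logger.warning("snapshot %s excluded: %d modes, expected %d",
                           r.get("snapshot_id", s), len(nu), M)
            continue
        order = np.argsort(-nu, kind="stable")
        rows_f.append(nu[order])
        rows_i.append(np.asarray(r["ir"], dtype=float)[order])
        rows_r.append(np.asarray(r["raman"], dtype=float)[order])
        times.append(float(r.get("time_ps", s)))
        ids.append(int(r.get("snapshot_id", s)))
    if not rows_f:
        raise ValueError("every snapshot was excluded")
    if n_excluded:
        logger.info("excluded %d snapshots with deviant mode counts", n_excluded)
    labels = (np.asarray(kept_labels, dtype=int) if kept_labels is not None
              else np.arange(1, M + 1))
    if len(labels) != M:
        raise ValueError("kept label count does not match mode count")
    return EnsembleTable(labels=labels, times_ps=np.array(times),
                         frequency=np.array(rows_f), ir=np.array(rows_i),
                         raman=np.array(rows_r), snapshot_ids=np.array(ids))


def zscore_outliers(table: EnsembleTable, threshold: float = 5.0) -> OutlierReport:
    """Flag snapshots by absolute Z-score, Z = |x - mu| / sigma.

    mu and sigma are the per-mode sample mean and sample (n-1) standard
    deviation over snapshots, computed separately for frequency, IR
    intensity and Raman intensity.  A snapshot is flagged when any
    property at any mode exceeds ``threshold``; constant columns
    (sigma = 0) produce no flags.
    """
    if table.n_snapshots < 3:
        raise ValueError("need at least 3 snapshots for outlier statistics")
    zscores: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    mask = np.zeros(table.n_snapshots, dtype=bool)
    for prop in PROPERTIES:
        x = table.property_array(prop)
        mu = x.mean(0)
        sigma = x.std(0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(x - mu) / sigma
        z[:, sigma == 0] = 0.0
        zscores[prop] = z
        flagged = (z > threshold).any(1)
        counts[prop] = int(flagged.sum())
        mask |= flagged
    return OutlierReport(zscores=zscores, threshold=threshold,
                         discard_mask=mask, counts_by_property=counts)


def base_interval_ps(times_ps: np.ndarray) -> float:
    """Nominal spacing of the stored snapshot times.

    After outlier removal the retained series has gaps; windows are then
    defined on the stored sequence at the nominal (median) interval, as
    in the reference-window convention, with a warning.
    """
    import warnings

    times_ps = np.asarray(times_ps, dtype=float)
    if len(times_ps) < 2:
        return 1.0
    diffs = np.diff(times_ps)
    if np.any(diffs <= 0):
        raise ValueError("snapshot times must be strictly increasing")
    dt = float(np.median(diffs))
    if not np.allclose(diffs, dt, rtol=1e-6, atol=1e-9):
        warnings.warn("snapshot times are not uniformly spaced (discarded "
                      "snapshots?); windows are defined on the stored "
                      f"sequence at the nominal interval {dt} ps",
                      stacklevel=2)
    return dt


def count_windows(n_reference: int, stride: int, n: int,
                  offset: Literal["step", "base"] = "step") -> int:
    """Number of subwindows of n snapshots at the given stride.

    With windows shifted by the step itself (default), a reference of T
    base-interval snapshots supports T // stride - n windows; with
    base-interval shifts the windows advance one base snapshot at a
    time.
    """
    fits = (n - 1) * stride <= n_reference - 1
    if not fits:
        raise ValueError(
            f"window of {n} snapshots at stride {stride} does not fit in a "
            f"{n_reference}-snapshot reference")
    if offset == "step":
        nw = n_reference // stride - n
    else:
        nw = n_reference - (n - 1) * stride
    return max(nw, 1)


def window_errors(table: EnsembleTable, spec: WindowSpec,
                  reference: EnsembleTable | None = None) -> WindowErrorReport:
    """Windowed configurational-convergence error analysis.

    Subwindows of ``spec.n`` snapshots, spaced ``spec.step_ps`` apart and
    offset from one another by the step (or by the base interval when
    ``spec.offset == 'base'``), are drawn from the reference table.  For
    every property the per-mode window means are compared with the
    reference means, |mu_ij - mu_ref_j|; these absolute deviations are
    averaged over modes per window and then summarized (mean, std, max)
    over windows.  Relative errors divide each per-mode deviation by the
    reference mean before mode-averaging and are reported in percent.
    """
    ref = reference if reference is not None else table
    dt = base_interval_ps(ref.times_ps)
    stride_f = spec.step_ps / dt
    stride = int(round(stride_f))
    if abs(stride_f - stride) > 1e-6 or stride < 1:
        raise ValueError("step must be a positive integer multiple of the "
                         "base snapshot interval")
    T = ref.n_snapshots
    n = spec.n
    nw = count_windows(T, stride, n, spec.offset)
    starts = (np.arange(nw) * stride if spec.offset == "step"
              else np.arange(nw))
    idx = starts[:, None] + np.arange(n)[None, :] * stride  # (nw, n)
    per_property: dict[str, dict[str, float]] = {}
    for prop in PROPERTIES:
        x = ref.property_array(prop)
        mu_ref = x.mean(0)  # (M,)
        win_means = x[idx].mean(1)  # (nw, M)
        dev = np.abs(win_means - mu_ref)
        per_window = dev.mean(1)  # mode-average per window
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(mu_ref != 0, dev / np.abs(mu_ref), 0.0)
        rel_per_window = rel.mean(1) * 100.0
        per_property[prop] = {
            "delta": float(per_window.mean()),
            "delta_std": float(per_window.std(ddof=1)) if nw > 1 else 0.0,
            "delta_max": float(per_window.max()),
            "rel_delta": float(rel_per_window.mean()),
            "rel_delta_std": float(rel_per_window.std(ddof=1)) if nw > 1 else 0.0,
            "rel_delta_max": float(rel_per_window.max()),
        }
    return WindowErrorReport(per_property=per_property, n_windows=nw, spec=spec)


def convergence_table(table: EnsembleTable, step_ps: float,
                      n_values: Sequence[int],
                      offset: Literal["step", "base"] = "step") -> pd.DataFrame:
    """Window errors for several window sizes, one column per n.

    Rows are '<property>' and '<property>_rel' summaries formatted as
    ``mean ± std (max)``, plus the window count — the shape of a
    configurational-convergence benchmark table.
    """
    cols = {}
    for n in n_values:
        rep = window_errors(table, WindowSpec(step_ps=step_ps, n=n, offset=offset))
        col = {}
        for prop, d in rep.per_property.items():
            col[prop] = f"{d['delta']:.3g} ± {d['delta_std']:.3g} ({d['delta_max']:.3g})"
            col[prop + "_rel"] = (f"{d['rel_delta']:.3g} ± {d['rel_delta_std']:.3g} "
                                  f"({d['rel_delta_max']:.3g})")
        col["n_windows"] = rep.n_windows
        cols[n] = col
    return pd.DataFrame(cols)
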