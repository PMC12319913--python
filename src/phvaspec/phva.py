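"""Partial-Hessian vibrational analysis (PHVA).

Only the core block of the cluster Hessian is diagonalized; the
core-environment and environment-environment blocks are discarded.
Because the environment is held fixed, the analysis yields 3N modes for
an N-atom core, of which several resemble rigid translations/rotations
of the core against the frozen surroundings ("pseudotranslations" and
"pseudorotations").  Such modes are poorly described in this
approximation and are identified — via squared overlaps with rigid-body
reference vectors — and discarded before intensities are evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from . import units

logger = logging.getLogger(__name__)

SYM_TOL = 1e-10
LINEAR_DROP_TOL = 1e-8  # Gram-Schmidt norm below which a rotation vector is dropped

Metric = Literal["cartesian", "mass_weighted"]


@dataclass
class MassWeightedHessian:
    """Hessian with element ((a,i),(b,j)) divided by sqrt(m_a m_b)."""

    matrix: np.ndarray
    masses: np.ndarray


@dataclass
class NormalModeSet:
    """Result of diagonalizing a mass-weighted partial Hessian.

    Modes are labeled 1..3N in descending order of wavenumber (label 1 is
    the highest-frequency mode).  Negative wavenumbers encode imaginary
    frequencies.  ``eigenvectors`` are orthonormal columns in
    mass-weighted coordinates; ``cartesian_displacements`` are the
    un-mass-weighted images, each column renormalized to unit length.
    """

    wavenumbers: np.ndarray
    eigenvectors: np.ndarray
    cartesian_displacements: np.ndarray
    masses: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.wavenumbers)

    @property
    def labels(self) -> np.ndarray:
        return np.arange(1, self.n_modes + 1)


@dataclass
class TransRotBasis:
    """Orthonormal rigid-body reference vectors of the core region."""

    vectors: np.ndarray  # (3N, 3 + n_rot), columns orthonormal
    metric: Metric
    n_rot: int

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[1]


@dataclass
class PseudoProfile:
    """Per-mode squared overlaps with the rigid-body subspace."""

    translational: np.ndarray
    rotational: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.translational + self.rotational


@dataclass
class ModeFilterRule:
    """How pseudomodes are selected for removal.

    ``threshold`` discards every mode label whose ensemble-mean total
    pseudo contribution exceeds ``tau``; ``fixed_count`` discards the
    ``n_lowest`` lowest-frequency labels outright.
    """

    kind: Literal["threshold", "fixed_count"] = "threshold"
    tau: float = 0.1
    n_lowest: int = 6

    def __post_init__(self) -> None:
        if self.kind == "threshold" and not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must lie in (0, 1]")
        if self.kind == "fixed_count" and self.n_lowest < 1:
            raise ValueError("n_lowest must be positive")


def mass_weight(H: np.ndarray, masses: Sequence[float]) -> MassWeightedHessian:
    """Mass-weight a partial Hessian (Hartree/Bohr^2, masses in Da)."""
    H = np.asarray(H, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    if H.shape != (3 * len(masses),) * 2:
        raise ValueError(f"Hessian shape {H.shape} inconsistent with "
                         f"{len(masses)} atoms")
    w = 1.0 / np.sqrt(np.repeat(masses, 3))
    return MassWeightedHessian(matrix=H * np.outer(w, w), masses=masses)


def eigenanalyze(Hmw: MassWeightedHessian) -> NormalModeSet:
    """Diagonalize a mass-weighted Hessian into wavenumbers and modes.

    Eigenvalues are mapped to signed wavenumbers in cm^-1 and modes are
    sorted in descending order of wavenumber.
    """
    M = Hmw.matrix
    scale = max(np.abs(M).max(), 1.0)
    if np.abs(M - M.T).max() / scale > SYM_TOL:
        raise ValueError("mass-weighted Hessian is not symmetric")
    evals, evecs = scipy.linalg.eigh(0.5 * (M + M.T))
    nu = units.eigenvalue_to_wavenumber(evals)
    order = np.argsort(-nu, kind="stable")
    nu = nu[order]
    evecs = evecs[:, order]
    w = 1.0 / np.sqrt(np.repeat(Hmw.masses, 3))
    cart = evecs * w[:, None]
    norms = np.linalg.norm(cart, axis=0)
    cart = cart / np.where(norms > 0, norms, 1.0)
    return NormalModeSet(wavenumbers=nu, eigenvectors=evecs,
                         cartesian_displacements=cart, masses=Hmw.masses)


def trans_rot_basis(core_geometry: np.ndarray,
                    masses: Sequence[float],
                    metric: Metric = "cartesian") -> TransRotBasis:
    """Orthonormal rigid translation/rotation vectors of the core.

    Translations are uniform axis shifts of every core atom; rotations
    are ``e_k x (R_a - R_com)`` about the core's center of mass.  In the
    ``mass_weighted`` metric every atomic component is additionally
    scaled by sqrt(m_a).  The six (five for a linear core) vectors are
    orthonormalized by modified Gram-Schmidt, rotations after
    translations; rotation vectors that collapse (pre-normalization norm
    below 1e-8, e.g. about the axis of a linear core) are dropped.
    """
    R = np.asarray(core_geometry, dtype=float)
    masses = np.asarray(masses, dtype=float)
    n = R.shape[0]
    if n < 2:
        raise ValueError("need at least two core atoms")
    span = np.abs(R - R[0]).max()
    if span < 1e-12:
        raise ValueError("all core atoms coincide")
    com = (masses[:, None] * R).sum(0) / masses.sum()
    rel = R - com
    sqm = np.sqrt(masses) if metric == "mass_weighted" else np.ones(n)
    raw = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        raw.append((t * sqm[:, None]).ravel())
    for k in range(3):
        e = np.zeros(3)
        e[k] = 1.0
        r = np.cross(np.broadcast_to(e, rel.shape), rel)
        raw.append((r * sqm[:, None]).ravel())
    vectors: list[np.ndarray] = []
    n_rot = 0
    for i, v in enumerate(raw):
        nv0 = np.linalg.norm(v)
        if nv0 < LINEAR_DROP_TOL:
            if i < 3:
                raise ValueError("degenerate translational vector")
            continue  # linear core: rotation about the axis vanishes
        v = v / nv0
        for u in vectors:
            v = v - (u @ v) * u
        nv = np.linalg.norm(v)
        if nv < LINEAR_DROP_TOL:
            if i < 3:
                raise ValueError("degenerate translational vector")
            continue
        vectors.append(v / nv)
        if i >= 3:
            n_rot += 1
    return TransRotBasis(vectors=np.column_stack(vectors), metric=metric,
                         n_rot=n_rot)


def pseudo_contributions(modes: NormalModeSet,
                         basis: TransRotBasis) -> PseudoProfile:
    """Squared overlaps of each normal mode with the rigid-body basis.

    For mode I, T_I = sum_k |v_I . t_k|^2 and R_I = sum_k |v_I . r_k|^2
    with the mode vector taken in the basis metric: unit-normalized
    Cartesian displacements for ``cartesian``, the native orthonormal
    eigenvectors for ``mass_weighted``.  Each contribution lies in
    [0, 1]; in the mass-weighted metric the totals over all modes sum
    exactly to the rigid-body dimension 3 + n_rot.
    """
    V = (modes.cartesian_displacements if basis.metric == "cartesian"
         else modes.eigenvectors)
    if V.shape[0] != basis.vectors.shape[0]:
        raise ValueError("mode and basis dimensions differ")
    ov2 = (basis.vectors.T @ V) ** 2  # (3 + n_rot, n_modes)
    T = ov2[:3].sum(0)
    Rv = ov2[3:].sum(0) if basis.n_rot else np.zeros(modes.n_modes)
    return PseudoProfile(translational=T, rotational=Rv)


def pseudo_report(profiles: Sequence[PseudoProfile],
                  wavenumbers: np.ndarray | None = None) -> pd.DataFrame:
    """Ensemble statistics of total pseudo contributions per mode label."""
    totals = np.array([p.total for p in profiles])
    trans = np.array([p.translational for p in profiles])
    rot = np.array([p.rotational for p in profiles])
    df = pd.DataFrame({
        "label": np.arange(1, totals.shape[1] + 1),
        "mean_T": trans.mean(0),
        "mean_R": rot.mean(0),
        "mean_total": totals.mean(0),
        "std_total": totals.std(0, ddof=1) if len(profiles) > 1
        else np.zeros(totals.shape[1]),
        "max_total": totals.max(0),
    })
    if wavenumbers is not None:
        df.insert(1, "mean_wavenumber", np.asarray(wavenumbers, dtype=float))
    return df


def filter_modes(profiles: Sequence[PseudoProfile],
                 rule: ModeFilterRule | None = None) -> np.ndarray:
    """Kept mode labels after discarding pseudomodes over an ensemble.

    Profiles from all snapshots are aligned by mode label; the decision
    is made on the ensemble mean so that configuration-dependent
    pseudo character (which can be large in one snapshot and small in
    another) is judged across the whole set.
    """
    if rule is None:
        rule = ModeFilterRule()
    if not profiles:
        raise ValueError("no profiles given")
    n_modes = len(profiles[0].total)
    if any(len(p.total) != n_modes for p in profiles):
        raise ValueError("profiles have inconsistent mode counts")
    labels = np.arange(1, n_modes + 1)
    if rule.kind == "threshold":
        mean_total = np.mean([p.total for p in profiles], axis=0)
        kept = labels[mean_total <= rule.tau]
    else:
        kept = labels[: n_modes - rule.n_lowest]
    if kept.size == 0:
        raise ValueError("mode filter removed every mode")
    return kept
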