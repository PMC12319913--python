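"""Synthetic harmonic clusters with analytic Hessians and property gradients.

A solute ("core") is modeled as a connected network of central-force
springs; environment atoms are weakly spring-coupled to it and held
fixed during the vibrational analysis, mimicking a solute embedded in a
frozen solvent cage.  Every quantity the pipeline consumes is analytic:

* the full pair-spring Hessian (each spring contributes k u u^T blocks
  with the usual +/- sign pattern, so rigid translations and rotations
  are exact zero modes at any geometry);
* dipole gradients from fixed point charges, d mu_j / d x_{a,i} =
  q_a delta_ij;
* polarizability gradients from a bond-polarizability model with
  longitudinal and transverse derivative parameters per core bond.

This makes every downstream stage testable against closed forms and
against the full-Hessian oracle without any electronic-structure
software.  No chemical realism is claimed: the fixtures validate the
mathematics of the workflow, not the spectroscopy of any real solute.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from . import units
from .model_io import AtomSet, SnapshotRecord

DEFAULT_SIGMA_BOHR = 0.05  # per-snapshot Gaussian displacement, Bohr


@dataclass
class ClusterSpec:
    """Recipe for a solute-in-environment spring cluster.

    Spring constants are in Hartree/Bohr^2, charges in e, coordinates in
    angstrom.  ``core_springs`` must form a connected graph over the
    core atoms; ``coupling_springs`` tie core atoms to environment
    atoms with constant ``k_c >= 0``.
    """

    symbols: list[str]
    masses: np.ndarray
    coords: np.ndarray
    molecule_ids: np.ndarray
    core_indices: np.ndarray
    core_springs: list[tuple[int, int, float]]
    coupling_springs: list[tuple[int, int, float]] = field(default_factory=list)
    charges: np.ndarray | None = None
    bond_polarizabilities: list[tuple[int, int, float, float]] = field(
        default_factory=list)
    sigma_bohr: float = DEFAULT_SIGMA_BOHR

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.core_indices = np.asarray(self.core_indices, dtype=int)
        if self.charges is None:
            self.charges = np.zeros(len(self.symbols))
        self.charges = np.asarray(self.charges, dtype=float)
        if any(k <= 0 for _, _, k in self.core_springs):
            raise ValueError("core spring constants must be positive")
        if any(k < 0 for _, _, k in self.coupling_springs):
            raise ValueError("coupling spring constants must be non-negative")
        nc = len(self.core_indices)
        pos = {int(a): i for i, a in enumerate(self.core_indices)}
        rows, cols = [], []
        for a, b, _ in self.core_springs:
            rows.append(pos[a])
            cols.append(pos[b])
        graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(nc, nc))
        n_comp, _ = connected_components(graph, directed=False)
        if n_comp != 1:
            raise ValueError("core spring graph is not connected")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)


@dataclass
class FullSystemHessian:
    """Analytic pair-spring Hessian of the whole cluster (Hartree/Bohr^2)."""

    matrix: np.ndarray
    masses: np.ndarray

    def core_block(self, core_indices: np.ndarray) -> np.ndarray:
        comp = (3 * np.asarray(core_indices)[:, None]
                + np.arange(3)[None, :]).ravel()
        return self.matrix[np.ix_(comp, comp)]


def pair_spring_hessian(coords_bohr: np.ndarray,
                        springs: Sequence[tuple[int, int, float]]) -> np.ndarray:
    """Central-force Hessian: each spring adds k u u^T diagonal blocks and
    -k u u^T off-diagonal blocks along the instantaneous bond direction."""
    n = coords_bohr.shape[0]
    H = np.zeros((3 * n, 3 * n))
    for a, b, k in springs:
        r = coords_bohr[b] - coords_bohr[a]
        d = np.linalg.norm(r)
        if d < 1e-10:
            raise ValueError(f"spring {a}-{b} connects coincident atoms")
        u = r / d
        blk = k * np.outer(u, u)
        sa, sb = slice(3 * a, 3 * a + 3), slice(3 * b, 3 * b + 3)
        H[sa, sa] += blk
        H[sb, sb] += blk
        H[sa, sb] -= blk
        H[sb, sa] -= blk
    return H


def dipole_gradient_point_charges(charges_core: np.ndarray) -> np.ndarray:
    """Point-charge dipole model: d mu_j / d x_{a,i} = q_a delta_ij."""
    n = len(charges_core)
    D = np.zeros((3 * n, 3))
    for a, q in enumerate(charges_core):
        for i in range(3):
            D[3 * a + i, i] = q
    return D


def polarizability_gradient_bonds(coords_core_bohr: np.ndarray,
                                  bonds: Sequence[tuple[int, int, float, float]]
                                  ) -> np.ndarray:
    """Bond-polarizability gradients (stretching term).

    Each core bond (a, b) with longitudinal/transverse derivatives
    (a_par, a_perp) contributes, per unit displacement of atom b along
    the bond, d alpha_jk = a_perp delta_jk + (a_par - a_perp) u_j u_k;
    atom a gets the opposite sign.  Rotation-covariant and symmetric in
    (j, k) by construction.
    """
    n = coords_core_bohr.shape[0]
    D = np.zeros((3 * n, 3, 3))
    eye = np.eye(3)
    for a, b, a_par, a_perp in bonds:
        r = coords_core_bohr[b] - coords_core_bohr[a]
        u = r / np.linalg.norm(r)
        dalpha = a_perp * eye + (a_par - a_perp) * np.outer(u, u)
        for i in range(3):
            D[3 * b + i] += u[i] * dalpha
            D[3 * a + i] -= u[i] * dalpha
    return D


def closed_form_diatomic_wavenumber(k: float, m1: float, m2: float) -> float:
    """Harmonic diatomic: nu = (1/2 pi c) sqrt(k/mu), in cm^-1."""
    mu = m1 * m2 / (m1 + m2)
    return float(np.sqrt(k / mu) * units.WAVENUMBER_PER_SQRT_EIGVAL)


def spring_constant_from_wavenumber(nu_cm: float, m1: float, m2: float) -> float:
    """Invert the diatomic closed form: k = mu (2 pi c nu)^2, in a.u."""
    mu = m1 * m2 / (m1 + m2)
    return float(mu * (nu_cm / units.WAVENUMBER_PER_SQRT_EIGVAL) ** 2)


def make_diatomic(k: float, m1: float, m2: float,
                  bond_length_angstrom: float = 1.0,
                  charge: float = 0.3) -> tuple[SnapshotRecord, float]:
    """Homonuclear-style diatomic fixture with its closed-form wavenumber.

    Both atoms are core; charges +/-``charge`` give a nonzero IR stick
    and the bond-polarizability derivatives (1.0, 0.3) a nonzero Raman
    stick for the stretching mode.
    """
    if k < 0 or m1 <= 0 or m2 <= 0:
        raise ValueError("need k >= 0 and positive masses")
    coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, bond_length_angstrom]])
    atoms = AtomSet(symbols=["X", "X"], masses=np.array([m1, m2]),
                    coords=coords, molecule_ids=np.zeros(2, dtype=int))
    coords_bohr = units.angstrom_to_bohr(coords)
    springs = [(0, 1, k)] if k > 0 else []
    H = pair_spring_hessian(coords_bohr, springs) if springs else np.zeros((6, 6))
    D_mu = dipole_gradient_point_charges(np.array([charge, -charge]))
    D_alpha = (polarizability_gradient_bonds(coords_bohr, [(0, 1, 1.0, 0.3)])
               if k > 0 else np.zeros((6, 3, 3)))
    record = SnapshotRecord(atoms=atoms, core_indices=np.array([0, 1]),
                            H_partial=H, D_mu=D_mu, D_alpha=D_alpha)
    return record, closed_form_diatomic_wavenumber(k, m1, m2) if k > 0 else 0.0


def make_cluster(spec: ClusterSpec,
                 seed: int | np.random.Generator | None = None,
                 snapshot_id: int = 0,
                 time_ps: float = 0.0
                 ) -> tuple[SnapshotRecord, FullSystemHessian]:
    """One snapshot: perturbed geometry, full Hessian, core tensors.

    The template geometry is displaced by isotropic Gaussian noise of
    width ``spec.sigma_bohr`` (seeded; pass ``seed=None`` for the
    unperturbed template) and all tensors are evaluated analytically at
    the displaced geometry.  The snapshot's ``H_partial`` is the core
    block of the full Hessian — exactly the PHVA truncation.
    """
    coords = spec.coords.copy()
    if seed is not None and spec.sigma_bohr > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(
            0.0, units.bohr_to_angstrom(spec.sigma_bohr), coords.shape)
    atoms = AtomSet(symbols=list(spec.symbols), masses=spec.masses.copy(),
                    coords=coords, molecule_ids=spec.molecule_ids.copy())
    coords_bohr = units.angstrom_to_bohr(coords)
    springs = list(spec.core_springs) + [
        (a, b, k) for a, b, k in spec.coupling_springs if k > 0]
    H_full = FullSystemHessian(matrix=pair_spring_hessian(coords_bohr, springs),
                               masses=spec.masses.copy())
    core = spec.core_indices
    core_pos = {int(a): i for i, a in enumerate(core)}
    D_mu = dipole_gradient_point_charges(spec.charges[core])
    bonds_local = [(core_pos[a], core_pos[b], ap, at)
                   for a, b, ap, at in spec.bond_polarizabilities]
    D_alpha = polarizability_gradient_bonds(coords_bohr[core], bonds_local)
    record = SnapshotRecord(atoms=atoms, core_indices=core,
                            H_partial=H_full.core_block(core),
                            D_mu=D_mu, D_alpha=D_alpha,
                            snapshot_id=snapshot_id, time_ps=time_ps)
    return record, H_full


def make_ensemble(spec: ClusterSpec, n_snapshots: int,
                  base_interval_ps: float = 1.0,
                  seed: int = 0,
                  outlier_hessian_scale: dict[int, float] | None = None
                  ) -> list[SnapshotRecord]:
    """Seeded sequence of perturbed cluster snapshots.

    ``outlier_hessian_scale`` multiplies selected snapshots' partial
    Hessians (scaling all their frequencies by the square root of the
    factor) to plant detectable statistical outliers.
    """
    if n_snapshots < 1:
        raise ValueError("need at least one snapshot")
    children = np.random.SeedSequence(seed).spawn(n_snapshots)
    records = []
    for s, child in enumerate(children):
        rec, _ = make_cluster(spec, seed=np.random.default_rng(child),
                              snapshot_id=s, time_ps=s * base_interval_ps)
        if outlier_hessian_scale and s in outlier_hessian_scale:
            rec = SnapshotRecord(atoms=rec.atoms, core_indices=rec.core_indices,
                                 H_partial=rec.H_partial
                                 * outlier_hessian_scale[s],
                                 D_mu=rec.D_mu, D_alpha=rec.D_alpha,
                                 snapshot_id=rec.snapshot_id,
                                 time_ps=rec.time_ps)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# presets

_ACETONE_LIKE_COORDS = np.array([
    [0.000, 0.000, 0.000],    # C (carbonyl)
    [0.000, 1.215, 0.000],    # O
    [1.285, -0.765, 0.000],   # C (methyl)
    [-1.285, -0.765, 0.000],  # C (methyl)
    [2.150, -0.110, 0.050],   # H
    [1.330, -1.400, 0.885],   # H
    [1.330, -1.430, -0.870],  # H
    [-2.150, -0.110, -0.050],  # H
    [-1.330, -1.400, -0.885],  # H
    [-1.330, -1.430, 0.870],  # H
])


def acetone_like_spec(n_env: int = 20,
                      k_c: float = 0.01,
                      sigma_bohr: float = DEFAULT_SIGMA_BOHR,
                      env_seed: int = 1234,
                      r_env: tuple[float, float] = (3.5, 7.0)) -> ClusterSpec:
    """Ten-atom solute (acetone-like topology) in a shell of point solvents.

    The core is a C3O skeleton with six hydrogens, rigidified by bond
    springs plus geminal (1-3) springs so that the isolated core has
    exactly six zero modes.  ``n_env`` water-mass point atoms are placed
    on a random shell (radius drawn in ``r_env`` angstrom, seeded by
    ``env_seed`` so the cage is reproducible across snapshots) and each
    is coupled to its nearest core atom with constant ``k_c``.
    """
    nc = _ACETONE_LIKE_COORDS.shape[0]
    symbols = ["C", "O", "C", "C", "H", "H", "H", "H", "H", "H"]
    masses = [12.011, 15.999, 12.011, 12.011] + [1.008] * 6
    bonds = [(0, 1, 0.90), (0, 2, 0.45), (0, 3, 0.45)]
    bonds += [(2, h, 0.50) for h in (4, 5, 6)]
    bonds += [(3, h, 0.50) for h in (7, 8, 9)]
    geminal = [(1, 2, 0.08), (1, 3, 0.08), (2, 3, 0.08)]
    for c, hs in ((2, (4, 5, 6)), (3, (7, 8, 9))):
        geminal += [(0, h, 0.08) for h in hs]
        geminal += [(hs[i], hs[j], 0.08) for i in range(3) for j in range(i + 1, 3)]
    # 1-4 springs to the carbonyl O block the methyl torsion mechanisms,
    # so the isolated core has exactly six zero modes
    torsional = [(1, h, 0.03) for h in range(4, 10)]
    torsional += [(5, 9, 0.02), (6, 8, 0.02)]  # blocks concerted counter-torsion
    springs = bonds + geminal + torsional
    charges = np.array([0.5, -0.5, -0.3, -0.3, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
    bond_polar = [(a, b, {0.90: 2.0, 0.45: 1.0, 0.50: 0.8}[k],
                   {0.90: 0.5, 0.45: 0.3, 0.50: 0.2}[k]) for a, b, k in bonds]
    rng = np.random.default_rng(env_seed)
    env_coords = []
    com = _ACETONE_LIKE_COORDS.mean(0)
    while len(env_coords) < n_env:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        p = com + v * rng.uniform(*r_env)
        if np.linalg.norm(_ACETONE_LIKE_COORDS - p, axis=1).min() > 2.2:
            env_coords.append(p)
    coords = (np.vstack([_ACETONE_LIKE_COORDS] + [np.array(env_coords)])
              if n_env else _ACETONE_LIKE_COORDS.copy())
    coupling = []
    for j in range(n_env):
        d = np.linalg.norm(_ACETONE_LIKE_COORDS - env_coords[j], axis=1)
        coupling.append((int(np.argmin(d)), nc + j, k_c))
    return ClusterSpec(
        symbols=symbols + ["O"] * n_env,
        masses=np.array(masses + [18.015] * n_env),
        coords=coords,
        molecule_ids=np.array([0] * nc + list(range(1, n_env + 1))),
        core_indices=np.arange(nc),
        core_springs=springs,
        coupling_springs=coupling,
        charges=np.concatenate([charges, np.zeros(n_env)]),
        bond_polarizabilities=bond_polar,
        sigma_bohr=sigma_bohr,
    )


def with_coupling(spec: ClusterSpec, k_c: float) -> ClusterSpec:
    """Same cluster with every core-environment spring set to ``k_c``."""
    return replace(spec, coupling_springs=[(a, b, k_c)
                                           for a, b, _ in spec.coupling_springs])
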