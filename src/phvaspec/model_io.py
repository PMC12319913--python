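"""Data model, geometry/tensor file I/O, and droplet partitioning.

A solute-in-environment calculation is organised around three objects:

* :class:`AtomSet` — the geometry of the whole cluster, with atoms grouped
  into molecules;
* :class:`RegionPartition` — the droplet assignment of every molecule to
  the core, an inner (polarizable) shell, an outer (charge-only) shell,
  or removal;
* :class:`SnapshotRecord` — one frame's geometry together with the
  core-block property tensors (partial Hessian, partial dipole gradient,
  partial polarizability gradient) produced by an electronic-structure
  backend or by :mod:`phvaspec.synthetic`.

Geometries are in angstrom; tensors are in Hartree atomic units with the
core-atom Cartesian components ordered (atom0_x, atom0_y, atom0_z,
atom1_x, ...).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Standard atomic weights (Da), most common isotopic mixture.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.002602, "Li": 6.94, "Be": 9.0121831, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998403163, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815385, "Si": 28.085,
    "P": 30.973761998, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.0983, "Ca": 40.078, "Sc": 44.955908, "Ti": 47.867,
    "V": 50.9415, "Cr": 51.9961, "Mn": 54.938044, "Fe": 55.845,
    "Co": 58.933194, "Ni": 58.6934, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.921595, "Se": 78.971,
    "Br": 79.904, "Kr": 83.798, "I": 126.90447, "Xe": 131.293,
}

SYMMETRY_WARN_TOL = 1e-8  # symmetrize with warning below, error above


class ParseError(ValueError):
    """Raised for malformed geometry or tensor files."""


@dataclass
class AtomSet:
    """Atoms of one cluster frame.

    Attributes
    ----------
    symbols : element labels, one per atom.
    masses : atomic masses in Da.
    coords : Cartesian coordinates in angstrom, shape (n_atoms, 3).
    molecule_ids : integer molecule membership, one per atom.
    """

    symbols: list[str]
    masses: np.ndarray
    coords: np.ndarray
    molecule_ids: np.ndarray

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        n = len(self.symbols)
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if self.masses.shape != (n,) or self.molecule_ids.shape != (n,):
            raise ValueError("masses/molecule_ids length mismatch")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def molecule_index(self) -> dict[int, np.ndarray]:
        """Map molecule id -> atom indices."""
        out: dict[int, np.ndarray] = {}
        for mid in np.unique(self.molecule_ids):
            out[int(mid)] = np.flatnonzero(self.molecule_ids == mid)
        return out


Region = Literal["core", "inner", "outer", "removed"]


@dataclass
class RegionPartition:
    """Droplet assignment of molecules around the core."""

    regions: dict[int, Region]
    r_inner: float
    r_outer: float
    criterion: str

    def molecules(self, region: Region) -> list[int]:
        return sorted(m for m, r in self.regions.items() if r == region)


@dataclass
class SnapshotRecord:
    """One frame's geometry plus core-block property tensors.

    ``H_partial`` is the 3N_core x 3N_core core block of the Hessian in
    Hartree/Bohr^2; ``D_mu`` holds dipole gradients (rows: core Cartesian
    components, columns: dipole xyz) in units of e; ``D_alpha`` holds
    polarizability gradients, shape (3N_core, 3, 3), symmetric in the
    last two axes, in atomic units.
    """

    atoms: AtomSet
    core_indices: np.ndarray
    H_partial: np.ndarray
    D_mu: np.ndarray
    D_alpha: np.ndarray
    snapshot_id: int = 0
    time_ps: float = 0.0

    def __post_init__(self) -> None:
        self.core_indices = np.asarray(self.core_indices, dtype=int)
        self.H_partial = np.asarray(self.H_partial, dtype=float)
        self.D_mu = np.asarray(self.D_mu, dtype=float)
        self.D_alpha = np.asarray(self.D_alpha, dtype=float)
        n3 = 3 * len(self.core_indices)
        if self.H_partial.shape != (n3, n3):
            raise ValueError(
                f"H_partial shape {self.H_partial.shape} inconsistent with "
                f"{len(self.core_indices)} core atoms"
            )
        if self.D_mu.shape != (n3, 3):
            raise ValueError(f"D_mu shape {self.D_mu.shape} != ({n3}, 3)")
        if self.D_alpha.shape != (n3, 3, 3):
            raise ValueError(f"D_alpha shape {self.D_alpha.shape} != ({n3}, 3, 3)")
        for name, arr in (("H_partial", self.H_partial),
                          ("D_mu", self.D_mu), ("D_alpha", self.D_alpha)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
        self.H_partial = _enforce_symmetry(self.H_partial, "H_partial")
        self.D_alpha = _enforce_symmetry(
            self.D_alpha, "D_alpha", axes=(0, 2, 1))

    @property
    def core_masses(self) -> np.ndarray:
        return self.atoms.masses[self.core_indices]

    @property
    def core_coords(self) -> np.ndarray:
        return self.atoms.coords[self.core_indices]

    @property
    def n_core(self) -> int:
        return len(self.core_indices)


def _enforce_symmetry(arr: np.ndarray, name: str,
                      axes: tuple[int, ...] | None = None) -> np.ndarray:
    """Symmetrize ``arr`` if its asymmetry is tiny, error otherwise."""
    t = arr.T if axes is None else np.transpose(arr, axes)
    scale = max(np.abs(arr).max(), 1.0)
    asym = np.abs(arr - t).max() / scale
    if asym == 0.0:
        return arr
    if asym > SYMMETRY_WARN_TOL:
        raise ValueError(f"{name} asymmetry {asym:.3e} exceeds {SYMMETRY_WARN_TOL:g}")
    warnings.warn(f"{name} asymmetry {asym:.3e}; symmetrizing", stacklevel=3)
    return 0.5 * (arr + t)


# ---------------------------------------------------------------------------
# geometry I/O

def read_geometry(path: str | Path,
                  molecule_spec: Sequence[int] | None = None,
                  mass_overrides: dict[str, float] | None = None) -> AtomSet:
    """Read a standard XYZ file into an :class:`AtomSet`.

    Parameters
    ----------
    path : XYZ file (count line, comment line, then ``element x y z`` rows,
        coordinates in angstrom).
    molecule_spec : atoms-per-molecule counts in file order, e.g.
        ``[10, 3, 3]`` for a 10-atom solute followed by two waters.  When
        omitted all atoms form a single molecule.
    mass_overrides : per-element mass replacements in Da (e.g. isotopes).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}, line 1: expected an atom count") from exc
    body = lines[2:2 + n]
    if len(body) < n:
        raise ParseError(
            f"{path}: header promises {n} atoms, found {len(body)} atom rows")
    symbols: list[str] = []
    coords = np.empty((n, 3))
    for i, raw in enumerate(body):
        parts = raw.split()
        if len(parts) < 4:
            raise ParseError(f"{path}, line {i + 3}: expected 'element x y z'")
        symbols.append(parts[0])
        try:
            coords[i] = [float(p) for p in parts[1:4]]
        except ValueError as exc:
            raise ParseError(f"{path}, line {i + 3}: bad coordinate") from exc
    masses = np.empty(n)
    for i, sym in enumerate(symbols):
        if mass_overrides and sym in mass_overrides:
            masses[i] = mass_overrides[sym]
        elif sym in ATOMIC_WEIGHTS:
            masses[i] = ATOMIC_WEIGHTS[sym]
        else:
            raise ParseError(
                f"{path}: unknown element '{sym}' and no mass override given")
    if molecule_spec is None:
        mids = np.zeros(n, dtype=int)
    else:
        if sum(molecule_spec) != n:
            raise ParseError(
                f"molecule_spec sums to {sum(molecule_spec)}, file has {n} atoms")
        mids = np.repeat(np.arange(len(molecule_spec)), molecule_spec)
    return AtomSet(symbols=symbols, masses=masses, coords=coords,
                   molecule_ids=mids)


def write_geometry(path: str | Path, atoms: AtomSet, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{atoms.n_atoms}\n{comment}\n")
        for sym, (x, y, z) in zip(atoms.symbols, atoms.coords):
            fh.write(f"{sym} {x:.10f} {y:.10f} {z:.10f}\n")


# ---------------------------------------------------------------------------
# tensor I/O — plain text ("key rows cols" header blocks) and HDF5

def write_snapshot(path: str | Path, record: SnapshotRecord) -> None:
    """Write the core tensors of a snapshot.

    ``.h5``/``.hdf5`` suffixes select the HDF5 container (datasets
    /hessian, /dipole_gradient, /polarizability_gradient, /core_indices);
    anything else selects the plain-text block format, one ``key rows
    cols`` header per tensor followed by ``%.16e`` rows.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            fh["hessian"] = record.H_partial
            fh["dipole_gradient"] = record.D_mu
            fh["polarizability_gradient"] = record.D_alpha
            fh["core_indices"] = record.core_indices
            fh.attrs["snapshot_id"] = record.snapshot_id
            fh.attrs["time_ps"] = record.time_ps
        return
    n3 = record.H_partial.shape[0]
    with open(path, "w") as fh:
        fh.write(f"# phvaspec tensors, snapshot {record.snapshot_id}, "
                 f"t={record.time_ps} ps\n")
        fh.write(f"core_indices 1 {record.n_core}\n")
        fh.write(" ".join(str(i) for i in record.core_indices) + "\n")
        for key, arr in (("hessian", record.H_partial),
                         ("dipole_gradient", record.D_mu),
                         ("polarizability_gradient",
                          record.D_alpha.reshape(n3, 9))):
            fh.write(f"{key} {arr.shape[0]} {arr.shape[1]}\n")
            for row in arr:
                fh.write(" ".join(f"{v:.16e}" for v in row) + "\n")


def _read_tensor_text(path: Path) -> dict[str, np.ndarray]:
    blocks: dict[str, np.ndarray] = {}
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.lstrip().startswith("#")]
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) != 3:
            raise ParseError(f"{path}: expected 'key rows cols' header, got "
                             f"{lines[i]!r}")
        key, rows, cols = parts[0], int(parts[1]), int(parts[2])
        data = [lines[i + 1 + r].split() for r in range(rows)]
        blocks[key] = np.array(data, dtype=float).reshape(rows, cols)
        i += 1 + rows
    return blocks


def read_snapshot(geometry: AtomSet,
                  core_selection: Sequence[int],
                  tensor_path: str | Path,
                  snapshot_id: int = 0,
                  time_ps: float = 0.0) -> SnapshotRecord:
    """Load core tensors for ``geometry`` from a tensor file.

    Validates dimensions against ``3 * len(core_selection)``, rejects
    NaNs, and enforces symmetry of the Hessian and of the last two axes
    of the polarizability gradient (symmetrize with a warning below
    1e-8 relative asymmetry, error above).
    """
    tensor_path = Path(tensor_path)
    core = np.asarray(core_selection, dtype=int)
    n3 = 3 * len(core)
    if tensor_path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(tensor_path, "r") as fh:
            H = fh["hessian"][()]
            D_mu = fh["dipole_gradient"][()]
            D_alpha = fh["polarizability_gradient"][()]
            if "snapshot_id" in fh.attrs:
                snapshot_id = int(fh.attrs["snapshot_id"])
            if "time_ps" in fh.attrs:
                time_ps = float(fh.attrs["time_ps"])
    else:
        import re

        m = re.search(r"snapshot\s+(\d+),\s*t=([0-9.eE+-]+)\s*ps",
                      tensor_path.read_text(), flags=re.MULTILINE)
        if m:
            snapshot_id, time_ps = int(m.group(1)), float(m.group(2))
        blocks = _read_tensor_text(tensor_path)
        try:
            H = blocks["hessian"]
            D_mu = blocks["dipole_gradient"]
            D_alpha = blocks["polarizability_gradient"]
        except KeyError as exc:
            raise ParseError(f"{tensor_path}: missing tensor block {exc}") from exc
    D_alpha = np.asarray(D_alpha, dtype=float).reshape(-1, 3, 3)
    if H.shape != (n3, n3):
        raise ValueError(f"hessian shape {H.shape} does not match "
                         f"{len(core)} core atoms")
    return SnapshotRecord(atoms=geometry, core_indices=core, H_partial=H,
                          D_mu=D_mu, D_alpha=D_alpha,
                          snapshot_id=snapshot_id, time_ps=time_ps)


# ---------------------------------------------------------------------------
# droplet partitioning

def partition_droplet(atoms: AtomSet,
                      core_molecules: Sequence[int],
                      r_inner: float,
                      r_outer: float,
                      criterion: str = "min_atom_distance") -> RegionPartition:
    """Assign every non-core molecule to inner/outer/removed by distance.

    Distances are measured from each environment molecule to the core
    atoms: under ``min_atom_distance`` the minimum over all (molecule
    atom, core atom) pairs, under ``center_of_mass`` from the molecule's
    mass-weighted centroid to the nearest core atom.  A molecule is
    ``inner`` if its distance is <= ``r_inner``, ``outer`` if
    <= ``r_outer``, else ``removed``.
    """
    if r_inner > r_outer:
        raise ValueError("r_inner must not exceed r_outer")
    if criterion not in ("min_atom_distance", "center_of_mass"):
        raise ValueError(f"unknown criterion {criterion!r}")
    core_set = set(int(m) for m in core_molecules)
    if not core_set:
        raise ValueError("core molecule list is empty")
    mol_atoms = atoms.molecule_index
    missing = core_set - set(mol_atoms)
    if missing:
        raise ValueError(f"core molecules {sorted(missing)} not present")
    core_idx = np.concatenate([mol_atoms[m] for m in sorted(core_set)])
    core_xyz = atoms.coords[core_idx]
    regions: dict[int, Region] = {m: "core" for m in core_set}
    for mid, idx in mol_atoms.items():
        if mid in core_set:
            continue
        if criterion == "min_atom_distance":
            d = np.linalg.norm(
                atoms.coords[idx][:, None, :] - core_xyz[None, :, :], axis=-1
            ).min()
        else:
            w = atoms.masses[idx]
            com = (w[:, None] * atoms.coords[idx]).sum(0) / w.sum()
            d = np.linalg.norm(core_xyz - com, axis=-1).min()
        if d <= r_inner:
            regions[mid] = "inner"
        elif d <= r_outer:
            regions[mid] = "outer"
        else:
            regions[mid] = "removed"
    return RegionPartition(regions=regions, r_inner=r_inner,
                           r_outer=r_outer, criterion=criterion)
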