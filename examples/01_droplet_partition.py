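"""Partition a solvated cluster into droplet regions around the core.

Builds a small cluster (one diatomic solute, solvent molecules at
increasing distances) and assigns each solvent molecule to the inner
polarizable shell, the outer charge-only shell, or removal, using the
production radii of 16 and 30 angstrom.
"""

import numpy as np

from phvaspec import partition_droplet
from phvaspec.model_io import AtomSet

distances = [4.0, 10.0, 18.0, 25.0, 40.0]
symbols = ["C", "C"] + ["O"] * len(distances)
coords = [[0.0, 0.0, 0.0], [1.2, 0.0, 0.0]]
coords += [[0.0, d, 0.0] for d in distances]
atoms = AtomSet(symbols=symbols,
                masses=np.array([12.011, 12.011] + [15.999] * len(distances)),
                coords=np.array(coords),
                molecule_ids=np.array([0, 0] + list(range(1, 6))))

part = partition_droplet(atoms, core_molecules=[0], r_inner=16.0, r_outer=30.0)
for mol, d in zip(range(1, 6), distances):
    print(f"solvent molecule {mol} at {d:5.1f} A -> {part.regions[mol]}")

# Molecules within 16 A become part of the polarizable inner region,
# those within 30 A keep only their charges, the rest are dropped.
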