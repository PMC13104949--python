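"""Measure the nitro-N to Tyr-OH oxygen distance in a deposited structure.

Usage:  python examples/cryoem_distance.py path/to/structure.pdb

For the fluetonitazene-μOR cryo-EM structure (PDB 9O36, download it
yourself, e.g. from https://files.rcsb.org/download/9O36.pdb), the distance
between the ligand's nitro nitrogen and the hydroxyl oxygen of Tyr1.39 is
expected to be 3.0 Å — the geometric signature of a π-hole bond.
"""

import sys

import numpy as np
import MDAnalysis as mda

if len(sys.argv) != 2:
    sys.exit(__doc__)

u = mda.Universe(sys.argv[1])
lig = u.select_atoms("not protein and not resname HOH NA CL")
nitro = None
for n_atom in lig.select_atoms("element N or name N*"):
    near_o = lig.select_atoms(
        f"(element O or name O*) and around 1.6 index {n_atom.index}")
    if len(near_o) >= 2:
        nitro = n_atom
        break
if nitro is None:
    sys.exit("no nitro group (N bonded to two O) found in the ligand")

oh = u.select_atoms("protein and resname TYR and name OH")
d = np.linalg.norm(oh.positions - nitro.position, axis=1)
k = d.argmin()
res = oh[k].residue
print(f"nitro N ({nitro.resname}) ... {res.resname}{res.resid} OH: "
      f"{d[k]:.1f} A")
print("a distance near 3.0 A indicates a pi-hole bond between the "
      "electron-poor nitro nitrogen and the tyrosine hydroxyl oxygen")
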