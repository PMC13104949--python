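"""Light containers for receptor-ligand structures and trajectories.

The package's contact machinery works on plain numpy coordinate arrays plus a
:class:`Topology` describing atom identities, the ligand/receptor partition,
Ballesteros-Weinstein (BW) residue labels and orthosteric subpocket
membership. Converters to/from MDAnalysis handle the standard structural
formats (PDB topology, DCD/XTC coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

_HEAVY = np.vectorize(lambda e: e.upper() != "H")


@dataclass
class Topology:
    """Atom-level description of a receptor-ligand system.

    ``bw_map`` maps residue ids to Ballesteros-Weinstein labels such as
    ``"1.39"`` (helix.position); ``subpockets`` maps subpocket names (SP1/SP2/
    SP3) to sets of residue ids forming the orthosteric cavity regions.
    """

    names: np.ndarray            # atom names
    elements: np.ndarray         # element symbols
    resids: np.ndarray           # residue ids (int)
    resnames: np.ndarray
    ligand_mask: np.ndarray      # bool, True for ligand atoms
    bw_map: Dict[int, str] = field(default_factory=dict)
    subpockets: Dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        self.names = np.asarray(self.names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.ligand_mask = np.asarray(self.ligand_mask, dtype=bool)
        n = len(self.names)
        for arr in (self.elements, self.resids, self.resnames, self.ligand_mask):
            if len(arr) != n:
                raise ValueError("all per-atom arrays must have equal length")
        labels = [v for v in self.bw_map.values()]
        if len(labels) != len(set(labels)):
            raise ValueError("bw_map must be injective (duplicate BW labels)")
        pockets = list(self.subpockets.values())
        for i in range(len(pockets)):
            for j in range(i + 1, len(pockets)):
                if set(pockets[i]) & set(pockets[j]):
                    raise ValueError("subpocket residue sets must be disjoint")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def heavy_mask(self) -> np.ndarray:
        return _HEAVY(self.elements.astype(str))

    @property
    def ligand_heavy(self) -> np.ndarray:
        """Indices of ligand heavy atoms."""
        return np.flatnonzero(self.ligand_mask & self.heavy_mask)

    def receptor_heavy(self, restrict_resids=None) -> np.ndarray:
        """Indices of receptor heavy atoms, optionally within given residues."""
        mask = (~self.ligand_mask) & self.heavy_mask
        if restrict_resids is not None:
            mask &= np.isin(self.resids, list(restrict_resids))
        return np.flatnonzero(mask)

    def subpocket_resids(self, name: str) -> frozenset:
        if name not in self.subpockets:
            raise KeyError(f"unknown subpocket {name!r}; "
                           f"have {sorted(self.subpockets)}")
        return self.subpockets[name]

    def resid_of_bw(self, label: str) -> int:
        for resid, bw in self.bw_map.items():
            if bw == label:
                return resid
        raise KeyError(f"BW label {label!r} not in bw_map")

    def backbone_indices(self) -> np.ndarray:
        """Receptor backbone heavy atoms (N, CA, C, O) for alignment."""
        bb = np.isin(self.names.astype(str), ["N", "CA", "C", "O"])
        return np.flatnonzero(bb & ~self.ligand_mask & self.heavy_mask)


@dataclass
class Trajectory:
    """Frames of coordinates (Å), shape (n_frames, n_atoms, 3)."""

    coords: np.ndarray
    time_ns: Optional[np.ndarray] = None
    box: Optional[np.ndarray] = None    # orthorhombic box lengths (Å), if any

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one frame")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.n_frames


# ------------------------------------------------------------ MDAnalysis I/O

def to_mdanalysis(topo: Topology, traj: Trajectory):
    """Build an MDAnalysis Universe (in memory) from a Topology+Trajectory."""
    import MDAnalysis as mda

    n = topo.n_atoms
    resids_unique, res_index = np.unique(topo.resids, return_inverse=True)
    n_res = len(resids_unique)
    resnames = np.empty(n_res, dtype=object)
    for i, rid in enumerate(resids_unique):
        resnames[i] = topo.resnames[topo.resids == rid][0]
    u = mda.Universe.empty(n, n_residues=n_res, atom_resindex=res_index,
                           residue_segindex=np.zeros(n_res, dtype=int),
                           trajectory=True)
    u.add_TopologyAttr("names", topo.names.astype(str))
    u.add_TopologyAttr("elements", topo.elements.astype(str))
    u.add_TopologyAttr("resids", resids_unique.astype(int))
    u.add_TopologyAttr("resnames", resnames.astype(str))
    u.load_new(traj.coords.astype(np.float32), format="memory")
    return u


def write_pdb_dcd(topo: Topology, traj: Trajectory, pdb_path, dcd_path) -> None:
    """Write topology as PDB (first frame) and coordinates as DCD."""
    import MDAnalysis as mda

    u = to_mdanalysis(topo, traj)
    u.trajectory[0]
    u.atoms.write(str(pdb_path))
    with mda.Writer(str(dcd_path), n_atoms=topo.n_atoms) as w:
        for _ in u.trajectory:
            w.write(u.atoms)


def from_mdanalysis(universe, ligand_selection: str,
                    bw_map: Optional[Dict[int, str]] = None,
                    subpockets: Optional[Dict[str, Sequence[int]]] = None
                    ) -> tuple:
    """Convert an MDAnalysis Universe into (Topology, Trajectory).

    ``ligand_selection`` is an MDAnalysis selection string (e.g.
    ``"resname LIG"``). BW labels and subpocket residue lists are supplied
    externally (config tables); no automatic GPCR numbering is attempted.
    """
    lig = universe.select_atoms(ligand_selection)
    if lig.n_atoms == 0:
        raise ValueError(f"ligand selection {ligand_selection!r} is empty")
    lig_mask = np.zeros(universe.atoms.n_atoms, dtype=bool)
    lig_mask[lig.indices] = True
    try:
        elements = universe.atoms.elements
    except Exception:
        # fall back to first letter of the atom name (PDB without elements)
        elements = np.array([nm.strip("0123456789")[:1] or "X"
                             for nm in universe.atoms.names], dtype=object)
    topo = Topology(
        names=universe.atoms.names, elements=elements,
        resids=universe.atoms.resids, resnames=universe.atoms.resnames,
        ligand_mask=lig_mask, bw_map=dict(bw_map or {}),
        subpockets={k: frozenset(v) for k, v in (subpockets or {}).items()},
    )
    coords = np.array([universe.atoms.positions.copy()
                       for _ in universe.trajectory], dtype=float)
    box = None
    if universe.dimensions is not None and np.any(universe.dimensions[:3] > 0):
        box = np.asarray(universe.dimensions[:3], dtype=float)
    return topo, Trajectory(coords=coords, box=box)
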