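"""Receptor-ligand contact counting, interaction geometry, and pose clustering.

An atomic contact is a (ligand heavy atom, receptor heavy atom) pair whose
Euclidean distance does not exceed the cutoff (4.5 Å by default; the boundary
is inclusive). Waters/ions are excluded by construction of the topology's
ligand/receptor partition. Per-residue contact frequency is binary per frame:
a residue "contacts" the ligand in a frame if at least one of its heavy atoms
is within the cutoff of any ligand heavy atom.

Geometric interaction detectors cover the three hallmark contacts of
nitro-bearing opioids in the μOR orthosteric pocket: the π-hole bond between
an electron-poor nitro nitrogen and an electron-rich hydroxyl oxygen
(Tyr1.39), the amine-carboxylate salt bridge (Asp3.32), and conventional
hydrogen bonds. All detectors are purely geometric.

Pose clustering uses greedy leader clustering on ligand heavy-atom RMSD after
rigid Kabsch alignment of each frame to the first on receptor backbone atoms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist

from .structure import Topology, Trajectory

DEFAULT_CUTOFF = 4.5  # Å, boundary inclusive


# ------------------------------------------------------------------ counts

def _pair_indices(topo: Topology, restrict=None):
    lig = topo.ligand_heavy
    if restrict is None:
        rec = topo.receptor_heavy()
    else:
        resids = restrict if not isinstance(restrict, str) \
            else topo.subpocket_resids(restrict)
        rec = topo.receptor_heavy(resids)
    if len(lig) == 0 or len(rec) == 0:
        raise ValueError("empty ligand or receptor heavy-atom selection")
    return lig, rec


def count_contacts(frame: np.ndarray, topo: Topology,
                   cutoff: float = DEFAULT_CUTOFF,
                   restrict=None) -> int:
    """Number of ligand-receptor heavy-atom pairs with distance ≤ cutoff.

    ``restrict`` limits receptor atoms to a subpocket (name or residue-id
    iterable). The boundary is inclusive: a pair at exactly the cutoff counts.
    """
    lig, rec = _pair_indices(topo, restrict)
    d = cdist(frame[lig], frame[rec])
    return int(np.count_nonzero(d <= cutoff))


@dataclass
class ContactSeries:
    """Per-frame integer contact counts along a trajectory."""

    counts: np.ndarray
    cutoff: float
    restrict: Optional[str] = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("contact counts must be non-negative")

    def __len__(self):
        return len(self.counts)


def contact_series(traj: Trajectory, topo: Topology,
                   cutoff: float = DEFAULT_CUTOFF,
                   restrict=None) -> ContactSeries:
    """Apply :func:`count_contacts` to every frame."""
    _check_pbc(traj, topo)
    counts = np.array([count_contacts(traj.coords[i], topo, cutoff, restrict)
                       for i in range(traj.n_frames)])
    name = restrict if isinstance(restrict, str) else None
    return ContactSeries(counts=counts, cutoff=cutoff, restrict=name)


def _check_pbc(traj: Trajectory, topo: Topology) -> None:
    # inputs are assumed whole/imaged; warn if a distance exceeds box/2
    if traj.box is None:
        return
    lig = traj.coords[:, topo.ligand_heavy].mean(axis=1)
    rec = traj.coords[:, topo.receptor_heavy()].mean(axis=1)
    if np.any(np.abs(lig - rec) > traj.box / 2.0):
        warnings.warn("receptor-ligand separation exceeds half the box; "
                      "coordinates may need re-imaging", stacklevel=3)


# ------------------------------------------------------ residue frequencies

@dataclass
class ResidueContactProfile:
    """Residue → contact frequency ∈ [0, 1], keyed by BW label when mapped."""

    frequencies: dict           # resid → frequency
    bw_labels: dict             # resid → BW label (may be partial)
    cutoff: float
    n_frames: int

    def by_bw(self) -> dict:
        return {self.bw_labels.get(r, str(r)): f
                for r, f in self.frequencies.items()}

    def filtered(self, min_freq: float = 0.5) -> dict:
        """Residues with frequency ≥ min_freq (boundary inclusive)."""
        return {r: f for r, f in self.frequencies.items() if f >= min_freq}

    def to_csv(self, path) -> None:
        import pandas as pd
        rows = sorted(self.frequencies)
        pd.DataFrame({
            "resid": rows,
            "bw_label": [self.bw_labels.get(r, "") for r in rows],
            "contact_frequency": [self.frequencies[r] for r in rows],
        }).to_csv(path, index=False)


def residue_contact_frequency(traj: Union[Trajectory, Sequence[Trajectory]],
                              topo: Topology,
                              cutoff: float = DEFAULT_CUTOFF
                              ) -> ResidueContactProfile:
    """Fraction of frames in which each receptor residue touches the ligand.

    Accepts a single trajectory or a list (combined trajectories are pooled
    frame-weighted, i.e. equivalent to concatenation). Apply
    ``.filtered(min_freq)`` for the ≥50 %-persistence rule.
    """
    trajs = [traj] if isinstance(traj, Trajectory) else list(traj)
    if not trajs or sum(t.n_frames for t in trajs) < 1:
        raise ValueError("need at least one frame")
    lig = topo.ligand_heavy
    rec = topo.receptor_heavy()
    rec_resids = topo.resids[rec]
    unique_resids = np.unique(rec_resids)
    hits = {int(r): 0 for r in unique_resids}
    total = 0
    for t in trajs:
        for i in range(t.n_frames):
            d = cdist(t.coords[i][lig], t.coords[i][rec])
            in_contact = (d <= cutoff).any(axis=0)
            for r in np.unique(rec_resids[in_contact]):
                hits[int(r)] += 1
            total += 1
    freqs = {r: hits[r] / total for r in hits}
    return ResidueContactProfile(frequencies=freqs, bw_labels=dict(topo.bw_map),
                                 cutoff=cutoff, n_frames=total)


# ------------------------------------------------------------ interactions

@dataclass
class InteractionGeometry:
    """One detected geometric interaction in a frame (or its absence)."""

    kind: str                    # pi_hole | salt_bridge | hbond
    present: bool
    distance: Optional[float] = None     # Å
    atoms: tuple = ()
    angle: Optional[float] = None        # degrees, hbond only
    occupancy: Optional[float] = None    # fraction of frames, when aggregated
    reason: str = ""


def find_nitro_nitrogen(topo: Topology, frame: np.ndarray,
                        bond_cutoff: float = 1.6) -> Optional[int]:
    """Ligand nitrogen bonded to two oxygens (a nitro group), else None."""
    lig = np.flatnonzero(topo.ligand_mask)
    els = topo.elements.astype(str)
    n_idx = [i for i in lig if els[i].upper() == "N"]
    o_idx = [i for i in lig if els[i].upper() == "O"]
    for ni in n_idx:
        d = np.linalg.norm(frame[o_idx] - frame[ni], axis=1) if o_idx else []
        if np.count_nonzero(np.asarray(d) <= bond_cutoff) >= 2:
            return ni
    return None


def detect_pi_hole(frame: np.ndarray, topo: Topology, acceptor_O: int,
                   nitro_N: Optional[int] = None,
                   max_dist: float = 3.5) -> InteractionGeometry:
    """π-hole bond: nitro nitrogen within ``max_dist`` of an oxygen lone pair.

    If ``nitro_N`` is not given it is located from the topology (ligand N
    bonded to two O); a nitro-less ligand yields an absent result with a
    reason rather than an error.
    """
    if nitro_N is None:
        nitro_N = find_nitro_nitrogen(topo, frame)
        if nitro_N is None:
            return InteractionGeometry("pi_hole", present=False,
                                       reason="ligand has no nitro group")
    d = float(np.linalg.norm(frame[nitro_N] - frame[acceptor_O]))
    return InteractionGeometry("pi_hole", present=d <= max_dist, distance=d,
                               atoms=(nitro_N, acceptor_O))


def detect_salt_bridge(frame: np.ndarray, ligand_N: int,
                       carboxylate_Os: Iterable[int],
                       max_dist: float = 4.0) -> InteractionGeometry:
    """Salt bridge: basic amine N vs the nearer carboxylate oxygen."""
    os_ = list(carboxylate_Os)
    if not os_:
        raise ValueError("need at least one carboxylate oxygen")
    d = float(np.min(np.linalg.norm(frame[os_] - frame[ligand_N], axis=1)))
    return InteractionGeometry("salt_bridge", present=d <= max_dist,
                               distance=d, atoms=(ligand_N, tuple(os_)))


def detect_hbond(frame: np.ndarray, donor: int, hydrogen: Optional[int],
                 acceptor: int, max_dist: float = 3.5,
                 min_angle: float = 120.0) -> InteractionGeometry:
    """Hydrogen bond by donor-acceptor distance and (when the hydrogen is
    resolved) D-H···A angle; heavy-atom-only mode ignores the angle."""
    d = float(np.linalg.norm(frame[donor] - frame[acceptor]))
    angle = None
    ok = d <= max_dist
    if hydrogen is not None:
        v1 = frame[donor] - frame[hydrogen]
        v2 = frame[acceptor] - frame[hydrogen]
        cosa = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = float(np.degrees(np.arccos(np.clip(cosa, -1.0, 1.0))))
        ok = ok and angle >= min_angle
    return InteractionGeometry("hbond", present=ok, distance=d,
                               atoms=(donor, hydrogen, acceptor), angle=angle)


def interaction_occupancy(traj: Trajectory, detector, *args, **kwargs
                          ) -> InteractionGeometry:
    """Occupancy of an interaction over a trajectory (fraction of frames)."""
    hits = 0
    last = None
    for i in range(traj.n_frames):
        res = detector(traj.coords[i], *args, **kwargs)
        hits += bool(res.present)
        last = res
    out = InteractionGeometry(last.kind, present=hits > 0,
                              distance=last.distance, atoms=last.atoms,
                              angle=last.angle,
                              occupancy=hits / traj.n_frames,
                              reason=last.reason)
    return out


# ------------------------------------------------------------- superposition

def align_kabsch(mobile: np.ndarray, reference: np.ndarray,
                 selection: Optional[np.ndarray] = None):
    """Optimal rigid superposition (Kabsch/SVD) of mobile onto reference.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile[selection] @ rotation.T + translation ≈ reference[selection]``;
    the rotation is proper (det = +1). RMSD is over the selection.
    """
    sel = np.arange(len(mobile)) if selection is None else np.asarray(selection)
    if len(sel) < 3:
        raise ValueError("need at least 3 atoms for alignment")
    P = mobile[sel]
    Q = reference[sel]
    if P.shape != Q.shape:
        raise ValueError("selection shapes differ between structures")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-10 * max(S[0], 1e-30):
        raise ValueError("degenerate (collinear) alignment selection")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def ligand_rmsd(a: np.ndarray, b: np.ndarray, lig_idx: np.ndarray) -> float:
    """Plain (no re-fit) RMSD between two frames over ligand atoms."""
    d = a[lig_idx] - b[lig_idx]
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


# ---------------------------------------------------------------- clustering

@dataclass
class PoseCluster:
    members: List[int]           # frame indices (into the analysis window)
    medoid: int                  # representative frame index
    threshold: float             # Å

    @property
    def size(self) -> int:
        return len(self.members)


def cluster_poses(traj: Trajectory, topo: Topology,
                  rmsd_threshold: float = 2.0,
                  window: Optional[slice] = None) -> List[PoseCluster]:
    """Greedy leader clustering of ligand poses.

    Each frame in the window is first aligned to the window's first frame on
    receptor backbone atoms; frames join the first existing cluster whose
    leader is within ``rmsd_threshold`` ligand heavy-atom RMSD, else found a
    new cluster. Clusters are returned largest-first with the medoid (member
    minimizing total intra-cluster RMSD) as representative; frame indices are
    absolute trajectory indices.
    """
    frames = np.arange(traj.n_frames)[window] if window is not None \
        else np.arange(traj.n_frames)
    if len(frames) == 0:
        raise ValueError("empty frame window")
    bb = topo.backbone_indices()
    lig = topo.ligand_heavy
    ref = traj.coords[frames[0]]
    aligned = []
    for fi in frames:
        R, t, _ = align_kabsch(traj.coords[fi], ref, bb)
        aligned.append(traj.coords[fi] @ R.T + t)

    leaders: List[int] = []      # positions within `frames`
    members: List[List[int]] = []
    for k, fi in enumerate(frames):
        placed = False
        for ci, leader in enumerate(leaders):
            if ligand_rmsd(aligned[k], aligned[leader], lig) <= rmsd_threshold:
                members[ci].append(k)
                placed = True
                break
        if not placed:
            leaders.append(k)
            members.append([k])

    clusters = []
    for mem in members:
        if len(mem) == 1:
            medoid = mem[0]
        else:
            tot = [sum(ligand_rmsd(aligned[i], aligned[j], lig)
                       for j in mem if j != i) for i in mem]
            medoid = mem[int(np.argmin(tot))]
        clusters.append(PoseCluster(members=[int(frames[i]) for i in mem],
                                    medoid=int(frames[medoid]),
                                    threshold=rmsd_threshold))
    clusters.sort(key=lambda c: -c.size)
    return clusters


# ---------------------------------------------------------------- distances

def measure_atom_distance(structure, atom_spec_a, atom_spec_b) -> float:
    """Distance between two atoms of a PDB structure, reported to 0.1 Å.

    ``structure`` is a path to a PDB file or an MDAnalysis Universe; atom
    specs are ``(chain_or_segid, resid, atom_name)`` tuples or strings
    ``"A:123:OH"`` (chain may be empty).
    """
    import MDAnalysis as mda

    u = structure if isinstance(structure, mda.Universe) \
        else mda.Universe(str(structure))

    def resolve(spec):
        if isinstance(spec, str):
            chain, resid, name = spec.split(":")
        else:
            chain, resid, name = spec
        sel = f"resid {int(resid)} and name {name}"
        if chain:
            sel = f"(segid {chain} or chainID {chain}) and " + sel
        try:
            atoms = u.select_atoms(sel)
        except Exception:
            atoms = u.select_atoms(f"segid {chain} and resid {int(resid)} "
                                   f"and name {name}")
        if atoms.n_atoms == 0:
            raise ValueError(f"atom spec {spec!r} resolves to no atom")
        if atoms.n_atoms > 1:
            raise ValueError(f"atom spec {spec!r} is ambiguous "
                             f"({atoms.n_atoms} atoms)")
        return atoms.positions[0]

    a = resolve(atom_spec_a)
    b = resolve(atom_spec_b)
    return round(float(np.linalg.norm(a - b)), 1)
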