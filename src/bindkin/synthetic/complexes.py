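"""Toy receptor-ligand trajectories with designed contact ground truth.

The generator builds a minimal receptor of point-residue clusters arranged
around a binding pocket, labels residues with Ballesteros-Weinstein-style
identifiers and subpocket membership (SP1/SP2/SP3), and moves a small ligand
according to a chosen motion model:

- ``bound_harmonic``: ligand jitters around the pocket center, keeping every
  pocket residue in permanent contact (frequency 1.0) and every distal
  residue out of contact (frequency 0.0);
- ``escaping``: the ligand translates monotonically away along +z, ending
  > 20 Å from the receptor (zero contacts in the final frame);
- ``two_pose``: frames split between two ligand poses a fixed RMSD apart
  (default 5 Å), for pose-clustering checks.

The ligand includes a nitro group (N bonded to two O) so interaction
detectors can be exercised on the toy system.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from ..structure import Topology, Trajectory

_SP2_BW = ("1.39", "2.61", "2.64", "7.35", "7.38")
_SP3_BW = ("5.39", "5.42", "5.43", "6.51", "6.52", "6.55", "6.56")

MOTION_MODELS = ("bound_harmonic", "escaping", "two_pose")


@dataclass
class ToySystemSpec:
    """Layout and motion parameters of a toy receptor-ligand complex."""

    n_receptor_residues: int = 16
    subpocket_assignment: Optional[Dict[int, str]] = None  # resid → SP1/SP2/SP3/none
    n_ligand_atoms: int = 8
    pocket_geometry: Optional[np.ndarray] = None  # residue anchors (Å)
    ligand_motion_model: str = "bound_harmonic"
    n_frames: int = 50
    seed: int = 0
    pocket_radius: float = 3.5       # distance of pocket residue anchors (Å)
    distal_radius: float = 16.0      # distance of non-pocket anchors (Å)
    jitter_sigma: float = 0.15       # ligand positional noise (Å)
    escape_distance: float = 30.0    # final ligand displacement (Å)
    pose_separation: float = 5.0     # two_pose RMSD between poses (Å)

    def __post_init__(self):
        if self.ligand_motion_model not in MOTION_MODELS:
            raise ValueError(f"motion model must be one of {MOTION_MODELS}")
        if self.n_frames < 1:
            raise ValueError("need n_frames >= 1")
        if self.n_ligand_atoms < 4:
            raise ValueError("need at least 4 ligand atoms (nitro + scaffold)")
        if self.subpocket_assignment is not None:
            seen: Dict[str, set] = {}
            for rid, sp in self.subpocket_assignment.items():
                if sp not in ("SP1", "SP2", "SP3", "none"):
                    raise ValueError(f"bad subpocket {sp!r} for residue {rid}")
                seen.setdefault(sp, set()).add(rid)


def _default_assignment(n_res: int) -> Dict[int, str]:
    out = {}
    for i in range(n_res):
        if i < len(_SP2_BW):
            out[i + 1] = "SP2"
        elif i < len(_SP2_BW) + len(_SP3_BW):
            out[i + 1] = "SP3"
        else:
            out[i + 1] = "none"
    return out


def _ligand_template(n_atoms: int) -> Tuple[np.ndarray, list, list]:
    """Compact ligand blob with a nitro group (N1 with O1, O2 at 1.2 Å)."""
    names = ["N1", "O1", "O2"]
    elements = ["N", "O", "O"]
    coords = [np.array([0.0, 0.0, 0.0]),
              np.array([1.1, 0.5, 0.0]),
              np.array([-1.1, 0.5, 0.0])]
    # remaining heavy atoms on a small spiral so the blob stays within ~1.5 Å
    for j in range(n_atoms - 3):
        ang = 2.399963 * j          # golden angle keeps points spread
        r = 1.0 + 0.05 * j
        coords.append(np.array([r * np.cos(ang), -0.6,
                                r * np.sin(ang)]))
        names.append(f"C{j + 1}")
        elements.append("C")
    c = np.array(coords)
    return c - c.mean(axis=0), names, elements

def _residue_atoms(anchor: np.ndarray):
    """Four backbone-like atoms per residue; N points toward the origin so a
    pocket residue at anchor distance d has its N at d − 0.8 Å from the
    ligand center (contact guaranteed by construction)."""
    norm = np.linalg.norm(anchor)
    u = anchor / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    w = np.cross(u, ref)
    w /= np.linalg.norm(w)
    z = np.cross(u, w)
    return (("N", "N", anchor - 0.8 * u),
            ("CA", "C", anchor),
            ("C", "C", anchor + 0.8 * w),
            ("O", "O", anchor + 0.8 * w + 0.9 * z))


def gen_toy_complex_trajectory(spec: ToySystemSpec
                               ) -> Tuple[Topology, Trajectory]:
    """Build (Topology, Trajectory) with known per-residue contact truth.

    Pocket residues (SP1/SP2/SP3) are anchored ``pocket_radius`` Å from the
    ligand center with their N atom pointing inward, so in every bound frame
    each pocket residue has at least one heavy-atom pair within a 4.5 Å
    cutoff of the ligand. Distal residues stay beyond ``distal_radius``.
    """
    rng = np.random.default_rng(spec.seed)
    assign = spec.subpocket_assignment or _default_assignment(
        spec.n_receptor_residues)

    lig_xyz, lig_names, lig_elements = _ligand_template(spec.n_ligand_atoms)

    pocket_ids = sorted(r for r, sp in assign.items() if sp != "none")
    distal_ids = sorted(r for r, sp in assign.items() if sp == "none")

    anchors = {}
    if spec.pocket_geometry is not None:
        geo = np.asarray(spec.pocket_geometry, dtype=float)
        for k, rid in enumerate(sorted(assign)):
            anchors[rid] = geo[k]
    else:
        for k, rid in enumerate(pocket_ids):
            ang = 2.0 * np.pi * k / max(len(pocket_ids), 1)
            anchors[rid] = spec.pocket_radius * np.array(
                [np.cos(ang), np.sin(ang), 0.0])
        for k, rid in enumerate(distal_ids):
            ang = 2.0 * np.pi * (k + 0.5) / max(len(distal_ids), 1)
            anchors[rid] = spec.distal_radius * np.array(
                [np.cos(ang), np.sin(ang), -0.5])

    names, elements, resids, resnames = [], [], [], []
    rec_xyz = []
    for rid in sorted(assign):
        for nm, el, pos in _residue_atoms(anchors[rid]):
            names.append(nm)
            elements.append(el)
            resids.append(rid)
            resnames.append("ALA")
            rec_xyz.append(pos)
    rec_xyz = np.array(rec_xyz)
    n_rec = len(rec_xyz)

    lig_resid = max(assign) + 1
    names += lig_names
    elements += lig_elements
    resids += [lig_resid] * len(lig_names)
    resnames += ["LIG"] * len(lig_names)

    bw_map = {}
    extra = 0
    for rid in sorted(assign):
        sp = assign[rid]
        if sp == "SP2":
            k = [r for r in pocket_ids if assign[r] == "SP2"].index(rid)
            bw_map[rid] = _SP2_BW[k % len(_SP2_BW)]
        elif sp == "SP3":
            k = [r for r in pocket_ids if assign[r] == "SP3"].index(rid)
            bw_map[rid] = _SP3_BW[k % len(_SP3_BW)]
        else:
            bw_map[rid] = f"3.{30 + extra}"
            extra += 1
    # de-duplicate if wrapping occurred (bw_map must stay injective)
    seen = {}
    for rid, lab in list(bw_map.items()):
        if lab in seen:
            bw_map[rid] = f"{lab}x{rid}"
        seen[bw_map[rid]] = rid

    subpockets = {}
    for sp in ("SP1", "SP2", "SP3"):
        members = frozenset(r for r, v in assign.items() if v == sp)
        if members:
            subpockets[sp] = members

    ligand_mask = np.zeros(n_rec + len(lig_names), dtype=bool)
    ligand_mask[n_rec:] = True
    topo = Topology(names=np.array(names, dtype=object),
                    elements=np.array(elements, dtype=object),
                    resids=np.array(resids),
                    resnames=np.array(resnames, dtype=object),
                    ligand_mask=ligand_mask,
                    bw_map=bw_map, subpockets=subpockets)

    n_atoms = topo.n_atoms
    coords = np.empty((spec.n_frames, n_atoms, 3))
    for fi in range(spec.n_frames):
        if spec.ligand_motion_model == "bound_harmonic":
            disp = spec.jitter_sigma * rng.standard_normal(3)
        elif spec.ligand_motion_model == "escaping":
            frac = fi / max(spec.n_frames - 1, 1)
            disp = np.array([0.0, 0.0, frac * spec.escape_distance])
            disp += spec.jitter_sigma * rng.standard_normal(3) * 0.1
        else:  # two_pose
            disp = np.zeros(3)
            if fi >= spec.n_frames // 2:
                disp = np.array([spec.pose_separation, 0.0, 0.0])
            disp += 0.05 * rng.standard_normal(3)
        coords[fi, :n_rec] = rec_xyz
        coords[fi, n_rec:] = lig_xyz + disp
    time_ns = np.arange(spec.n_frames, dtype=float)
    return topo, Trajectory(coords=coords, time_ns=time_ns)
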