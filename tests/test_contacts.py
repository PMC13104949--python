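"""Contact counting vs brute force, persistence filter, detectors, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bindkin import contacts as ca
from bindkin.structure import Topology, Trajectory
from bindkin.synthetic import ToySystemSpec, gen_toy_complex_trajectory


def _two_atom_system(d):
    """One ligand atom at origin, one receptor atom at distance d on x."""
    topo = Topology(names=np.array(["C1", "CA"], dtype=object),
                    elements=np.array(["C", "C"], dtype=object),
                    resids=np.array([2, 1]),
                    resnames=np.array(["LIG", "ALA"], dtype=object),
                    ligand_mask=np.array([True, False]))
    frame = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    return topo, frame


def brute_force_contacts(frame, lig_idx, rec_idx, cutoff):
    n = 0
    for i in lig_idx:
        for j in rec_idx:
            if np.linalg.norm(frame[i] - frame[j]) <= cutoff:
                n += 1
    return n


def test_cutoff_boundary_inclusive():
    topo, frame = _two_atom_system(4.5)
    assert ca.count_contacts(frame, topo, cutoff=4.5) == 1
    topo, frame = _two_atom_system(4.5000001)
    assert ca.count_contacts(frame, topo, cutoff=4.5) == 0
    topo, frame = _two_atom_system(50.0)
    assert ca.count_contacts(frame, topo, cutoff=4.5) == 0


@given(seed=st.integers(0, 10_000))
@settings(max_examples=60, deadline=None, derandomize=True)
def test_count_matches_brute_force_on_random_geometries(seed):
    rng = np.random.default_rng(seed)
    n_lig, n_rec = 15, 15
    topo = Topology(
        names=np.array([f"L{i}" for i in range(n_lig)]
                       + [f"R{i}" for i in range(n_rec)], dtype=object),
        elements=np.array(["C"] * n_lig + ["C"] * n_rec, dtype=object),
        resids=np.array([99] * n_lig + list(range(1, n_rec + 1))),
        resnames=np.array(["LIG"] * n_lig + ["ALA"] * n_rec, dtype=object),
        ligand_mask=np.array([True] * n_lig + [False] * n_rec))
    frame = rng.uniform(-6, 6, size=(n_lig + n_rec, 3))
    got = ca.count_contacts(frame, topo, cutoff=4.5)
    want = brute_force_contacts(frame, np.arange(n_lig),
                                np.arange(n_lig, n_lig + n_rec), 4.5)
    assert got == want
    # monotone in cutoff
    assert ca.count_contacts(frame, topo, cutoff=6.0) >= got


def test_hydrogens_excluded():
    topo, frame = _two_atom_system(1.0)
    topo.elements[1] = "H"
    with pytest.raises(ValueError):   # no receptor heavy atoms left
        ca.count_contacts(frame, topo)


def test_contact_series_bound_and_escaping(bound_complex, escaping_complex):
    topo, traj = bound_complex
    cs = ca.contact_series(traj, topo)
    assert cs.counts.min() > 0
    # subpocket restriction never exceeds the total, frame by frame
    sp2 = ca.contact_series(traj, topo, restrict="SP2")
    sp3 = ca.contact_series(traj, topo, restrict="SP3")
    assert np.all(sp2.counts <= cs.counts)
    assert np.all(sp3.counts <= cs.counts)

    topo_e, traj_e = escaping_complex
    cs_e = ca.contact_series(traj_e, topo_e)
    assert cs_e.counts[0] > 0
    assert cs_e.counts[-1] == 0
    # final ligand position is far from every receptor atom
    last = traj_e.coords[-1]
    d = np.linalg.norm(last[topo_e.ligand_heavy][:, None]
                       - last[topo_e.receptor_heavy()][None], axis=-1)
    assert d.min() > 20.0


def test_residue_frequency_designed_truth(bound_complex):
    topo, traj = bound_complex
    prof = ca.residue_contact_frequency(traj, topo)
    pocket = set().union(*topo.subpockets.values())
    for r, f in prof.frequencies.items():
        assert f == (1.0 if r in pocket else 0.0)
    kept = prof.filtered(0.5)
    assert set(kept) == pocket


def test_persistence_filter_boundary():
    # 49% contact is dropped at the 50% rule; exactly 50% is retained
    topo = Topology(names=np.array(["C1", "CA"], dtype=object),
                    elements=np.array(["C", "C"], dtype=object),
                    resids=np.array([2, 1]),
                    resnames=np.array(["LIG", "ALA"], dtype=object),
                    ligand_mask=np.array([True, False]))
    n = 100
    coords = np.zeros((n, 2, 3))
    coords[:, 1, 0] = 3.0
    coords[49:, 1, 0] = 30.0          # in contact for frames 0..48 → 49%
    prof = ca.residue_contact_frequency(Trajectory(coords), topo)
    assert prof.frequencies[1] == pytest.approx(0.49)
    assert prof.filtered(0.5) == {}
    coords[49, 1, 0] = 3.0            # now exactly 50%
    prof = ca.residue_contact_frequency(Trajectory(coords), topo)
    assert prof.filtered(0.5) == {1: pytest.approx(0.5)}


def test_multi_trajectory_pooling_equals_concatenation(bound_complex):
    topo, traj = bound_complex
    a = Trajectory(traj.coords[:20])
    b = Trajectory(traj.coords[20:])
    pooled = ca.residue_contact_frequency([a, b], topo)
    concat = ca.residue_contact_frequency(traj, topo)
    assert pooled.frequencies == concat.frequencies


# ------------------------------------------------------------- detectors

def test_pi_hole_detection_and_nitroless_absence(bound_complex):
    topo, traj = bound_complex
    frame = traj.coords[0].copy()
    nN = ca.find_nitro_nitrogen(topo, frame)
    assert topo.names[nN] == "N1"
    accO = topo.receptor_heavy()[0]
    frame[accO] = frame[nN] + np.array([3.0, 0.0, 0.0])
    res = ca.detect_pi_hole(frame, topo, acceptor_O=accO, max_dist=3.5)
    assert res.present and res.distance == pytest.approx(3.0)
    frame[accO] = frame[nN] + np.array([5.0, 0.0, 0.0])
    assert not ca.detect_pi_hole(frame, topo, acceptor_O=accO).present

    # nitro-less ligand: absent with an explicit reason, not an error
    topo_nl = Topology(names=topo.names.copy(), elements=topo.elements.copy(),
                       resids=topo.resids, resnames=topo.resnames,
                       ligand_mask=topo.ligand_mask,
                       bw_map=topo.bw_map, subpockets=topo.subpockets)
    lig_o = np.flatnonzero(topo.ligand_mask
                           & (topo.elements.astype(str) == "O"))
    for i in lig_o:
        topo_nl.elements[i] = "C"
    res = ca.detect_pi_hole(traj.coords[0], topo_nl, acceptor_O=accO)
    assert not res.present and "nitro" in res.reason


def test_salt_bridge_min_over_oxygens_symmetric():
    frame = np.array([[0.0, 0.0, 0.0],    # amine N
                      [2.8, 0.0, 0.0],    # carboxylate O1
                      [0.0, 6.0, 0.0]])   # carboxylate O2
    r1 = ca.detect_salt_bridge(frame, 0, [1, 2], max_dist=4.0)
    r2 = ca.detect_salt_bridge(frame, 0, [2, 1], max_dist=4.0)
    assert r1.present and r1.distance == pytest.approx(2.8)
    assert r2.distance == r1.distance
    far = ca.detect_salt_bridge(frame, 0, [2], max_dist=4.0)
    assert not far.present


def test_hbond_angle_criterion():
    # donor O, hydrogen, acceptor N at 2.9 Å with a ~180° D-H...A geometry
    frame = np.array([[0.0, 0.0, 0.0],     # donor
                      [1.0, 0.0, 0.0],     # hydrogen
                      [2.9, 0.0, 0.0]])    # acceptor
    ok = ca.detect_hbond(frame, 0, 1, 2, max_dist=3.5, min_angle=120.0)
    assert ok.present and ok.angle == pytest.approx(180.0)
    bent = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0]])
    assert not ca.detect_hbond(bent, 0, 1, 2).present      # 90° angle
    # heavy-atom-only fallback ignores the angle entirely
    assert ca.detect_hbond(bent, 0, None, 2).present


def test_interaction_occupancy(bound_complex):
    topo, traj = bound_complex
    accO = topo.receptor_heavy()[0]
    res = ca.interaction_occupancy(traj, ca.detect_pi_hole, topo,
                                   acceptor_O=accO, max_dist=200.0)
    assert res.occupancy == 1.0


# ------------------------------------------------------------ superposition

def _quaternion_rmsd(P, Q):
    """Independent oracle: Horn's quaternion method for optimal RMSD."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    lam = np.linalg.eigvalsh(K)[-1]
    e0 = (P0 ** 2).sum() + (Q0 ** 2).sum()
    msd = max((e0 - 2.0 * lam) / len(P), 0.0)
    return np.sqrt(msd)


def test_kabsch_identity_and_rigid_motion(rng):
    P = rng.normal(size=(12, 3))
    R, t, rmsd = ca.align_kabsch(P, P)
    assert rmsd == pytest.approx(0.0, abs=1e-12)
    ang = 1.1
    R0 = np.array([[np.cos(ang), -np.sin(ang), 0],
                   [np.sin(ang), np.cos(ang), 0], [0, 0, 1]])
    Q = P @ R0.T + np.array([3.0, -2.0, 5.0])
    R, t, rmsd = ca.align_kabsch(P, Q)
    assert rmsd == pytest.approx(0.0, abs=1e-9)
    np.testing.assert_allclose(R, R0, atol=1e-9)
    assert np.linalg.det(R) == pytest.approx(1.0)


def test_kabsch_matches_quaternion_oracle(rng):
    for _ in range(10):
        P = rng.normal(size=(10, 3))
        Q = rng.normal(size=(10, 3))
        _, _, rmsd = ca.align_kabsch(P, Q)
        assert rmsd == pytest.approx(_quaternion_rmsd(P, Q), abs=1e-8)


def test_kabsch_degenerate_selection_rejected():
    P = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="collinear|degenerate"):
        ca.align_kabsch(P, P.copy())


# ---------------------------------------------------------------- clustering

def test_cluster_poses_two_designed_poses():
    topo, traj = gen_toy_complex_trajectory(
        ToySystemSpec(ligand_motion_model="two_pose", seed=3))
    clusters = ca.cluster_poses(traj, topo, rmsd_threshold=2.0)
    assert len(clusters) == 2
    assert sorted(c.size for c in clusters) == [traj.n_frames // 2,
                                                traj.n_frames - traj.n_frames // 2]
    # members partition the frames; every member within threshold of medoid
    all_members = sorted(m for c in clusters for m in c.members)
    assert all_members == list(range(traj.n_frames))
    lig = topo.ligand_heavy
    for c in clusters:
        for m in c.members:
            assert ca.ligand_rmsd(traj.coords[m], traj.coords[c.medoid],
                                  lig) <= c.threshold


def test_cluster_poses_limits(bound_complex):
    topo, traj = bound_complex
    one = ca.cluster_poses(traj, topo, rmsd_threshold=1e9)
    assert len(one) == 1 and one[0].size == traj.n_frames
    frames = Trajectory(np.repeat(traj.coords[:1], 5, axis=0))
    ident = ca.cluster_poses(frames, topo, rmsd_threshold=2.0)
    assert len(ident) == 1 and ident[0].size == 5
    with pytest.raises(ValueError):
        ca.cluster_poses(traj, topo, window=slice(0, 0))


def test_cluster_order_sensitivity_bounded():
    # greedy leader clustering is order-dependent; a designed two-pose system
    # must give the same partition after frame shuffling
    topo, traj = gen_toy_complex_trajectory(
        ToySystemSpec(ligand_motion_model="two_pose", seed=7, n_frames=40))
    rng = np.random.default_rng(0)
    perm = rng.permutation(traj.n_frames)
    shuffled = Trajectory(traj.coords[perm])
    assert len(ca.cluster_poses(shuffled, topo, 2.0)) == 2


# ---------------------------------------------------------------- distances

def test_measure_atom_distance_pdb(tmp_path, bound_complex):
    from bindkin.structure import write_pdb_dcd
    topo, traj = bound_complex
    pdb = tmp_path / "toy.pdb"
    write_pdb_dcd(topo, traj, pdb, tmp_path / "toy.dcd")
    lig_resid = int(topo.resids[topo.ligand_mask][0])
    d_same = ca.measure_atom_distance(pdb, ("", lig_resid, "N1"),
                                      ("", lig_resid, "N1"))
    assert d_same == 0.0
    # nitro N to one of its oxygens is a covalent ~1.2 Å, reported to 0.1 Å
    d_no = ca.measure_atom_distance(pdb, ("", lig_resid, "N1"),
                                    ("", lig_resid, "O1"))
    assert d_no == pytest.approx(1.2, abs=0.11)
    with pytest.raises(ValueError):
        ca.measure_atom_distance(pdb, ("", 999, "XX"), ("", lig_resid, "N1"))
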