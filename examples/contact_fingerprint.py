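"""Contact fingerprint of a toy receptor-ligand complex.

Builds a bound complex whose pocket residues (subpockets SP2/SP3, labeled
with Ballesteros-Weinstein identifiers) are in permanent contact with the
ligand, then computes total and per-subpocket contact counts, the
≥50%-persistence residue fingerprint, the π-hole detector on the ligand's
nitro group, and ligand-pose clusters at a 2.0 Å RMSD threshold.
"""

from bindkin import contacts as ca
from bindkin.synthetic import ToySystemSpec, gen_toy_complex_trajectory

topo, traj = gen_toy_complex_trajectory(ToySystemSpec(seed=0))

total = ca.contact_series(traj, topo, cutoff=4.5)
sp2 = ca.contact_series(traj, topo, restrict="SP2")
sp3 = ca.contact_series(traj, topo, restrict="SP3")
print(f"contacts/frame: total {total.counts.mean():.0f}, "
      f"SP2 {sp2.counts.mean():.0f}, SP3 {sp3.counts.mean():.0f}")

prof = ca.residue_contact_frequency(traj, topo)
kept = prof.filtered(0.5)
print(f"persistent residues (>=50% of {prof.n_frames} frames): "
      + ", ".join(sorted(prof.bw_labels[r] for r in kept)))

frame = traj.coords[0]
nitro = ca.find_nitro_nitrogen(topo, frame)
tyr = topo.resid_of_bw("1.39")
accO = topo.receptor_heavy([tyr])[-1]          # that residue's O atom
res = ca.detect_pi_hole(frame, topo, acceptor_O=accO, max_dist=3.5)
state = "present" if res.present else "absent"
print(f"pi-hole (nitro N ... Tyr1.39-region O): {state}, "
      f"d = {res.distance:.2f} A")

clusters = ca.cluster_poses(traj, topo, rmsd_threshold=2.0)
print(f"pose clusters at 2.0 A: {len(clusters)} "
      f"(largest {clusters[0].size}/{traj.n_frames} frames, "
      f"medoid frame {clusters[0].medoid})")
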